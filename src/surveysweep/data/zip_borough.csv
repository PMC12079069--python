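zip,borough
10001,Manhattan
10002,Manhattan
10003,Manhattan
10009,Manhattan
10011,Manhattan
10013,Manhattan
10016,Manhattan
10019,Manhattan
10021,Manhattan
10025,Manhattan
10027,Manhattan
10029,Manhattan
10032,Manhattan
10034,Manhattan
10038,Manhattan
10040,Manhattan
10451,Bronx
10452,Bronx
10453,Bronx
10455,Bronx
10457,Bronx
10458,Bronx
10460,Bronx
10462,Bronx
10463,Bronx
10466,Bronx
10467,Bronx
10468,Bronx
10469,Bronx
10472,Bronx
10473,Bronx
11201,Brooklyn
11203,Brooklyn
11205,Brooklyn
11206,Brooklyn
11207,Brooklyn
11209,Brooklyn
11211,Brooklyn
11213,Brooklyn
11215,Brooklyn
11217,Brooklyn
11219,Brooklyn
11221,Brooklyn
11223,Brooklyn
11226,Brooklyn
11229,Brooklyn
11230,Brooklyn
11233,Brooklyn
11235,Brooklyn
11237,Brooklyn
11238,Brooklyn
11101,Queens
11103,Queens
11106,Queens
11354,Queens
11355,Queens
11368,Queens
11372,Queens
11373,Queens
11375,Queens
11377,Queens
11385,Queens
11413,Queens
11420,Queens
11432,Queens
11434,Queens
11691,Queens
10301,Staten Island
10302,Staten Island
10304,Staten Island
10305,Staten Island
10306,Staten Island
10308,Staten Island
10310,Staten Island
10312,Staten Island
10314,Staten Island
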