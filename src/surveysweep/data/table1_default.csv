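platform,impressions,clicks,total_cost,completed_n
Meta (Facebook and Instagram),165751,1700,1153.26,79
X (formerly Twitter),161792,270,535,3
Reddit,50508,,0,48
Discord,,,0,3
Bluelight web forum,,,0,1
Friend referral,,,,39
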