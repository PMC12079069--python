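# Default synthetic cohort specification: a majority-fraud submission mix for
# an incentivized online survey, with per-category violation tallies matching
# the study conditions the package ships with (2560 submissions, 173
# legitimate, largest click-farm cluster of 42 near-identical records).
n_total: 2560
n_legitimate: 173
seed: 20230807
category_tallies:
  FOREIGN_IP: 279
  DUPLICATE_IP_EMAIL: 571
  FICTITIOUS_DRUG: 1095
  INVALID_ZIP: 400
  ZIP_BOROUGH_MISMATCH: 124
  IMPROBABLE_USE: 235
  OVERDOSE_OUTLIER: 232
  CLUSTER_DUPLICATE: 351
  SPEEDER: 76
  DEMOGRAPHIC_INCONSISTENCY: 32
  SUSPICIOUS_OPEN_TEXT: 116
  EMAIL_PATTERN: 15
cluster_sizes: [42, 36, 33, 30, 27, 24, 21, 18, 15, 12, 9,
                6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6]
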