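# surveysweep

Bot and fraud screening for incentivized internet surveys of hidden
populations.

Incentivized web surveys — here, a survey of people who use opioids in New
York City recruited through social media ads — attract automated bots,
click farms, and individual fraudsters chasing the completion incentive.
When the target population has no sampling frame, fraudulent submissions
can swamp the real signal: in the study conditions this package ships as
its default fixture, 93.2% of 2560 complete submissions are invalid.
`surveysweep` implements a multistep post hoc cleaning protocol for flat
(REDCap-style) survey exports, plus a labeled synthetic cohort generator so
the entire pipeline can be exercised and validated end to end without any
restricted participant data.

## What it does

**Rule filters** (each independent and idempotent):

- IP addresses resolving outside the US or Canada
- duplicate IP or email addresses (keep-first or drop-all policy)
- endorsement of a fictitious drug placed in the substance checklist
- invalid ZIP codes (e.g. 10048, the retired World Trade Center ZIP) and
  ZIP/borough mismatches, with an exemption for respondents reporting
  current homelessness
- impossible substance/route combinations (injecting alcohol, inhalants,
  or marijuana)
- more than 10 lifetime overdoses
- completion in under 7 minutes (below the fastest plausible reading time)
- demographic inconsistencies (Medicaid coverage with household income
  above eligibility)
- suspicious open-text answers (blocklisted generic phrases, or verbatim
  answer duplication across records)
- bot-pattern emails (letters-only local part ending in ≥ 5 digits)
- answered honeypot items (hidden questions only automation fills in),
  reported separately

**Click-farm detection**: targeted demographics and the substance-use grid
are one-hot encoded (numeric fields min–max scaled), and DBSCAN with a very
narrow radius (eps = 0.5, min_samples = 2, Euclidean) groups near-identical
response vectors; every member of a cluster with ≥ 6 records is flagged,
with the cluster's submission-time span attached for review.

**Cascade**: filters run in protocol order with two tally modes — marginal
(each category counted over all records; categories overlap) and
sequential (attrition-style, each excluded record attributed to the first
stage that fires). Both modes exclude the same records.

**Reporting**: sample description (frequencies, mean/SD), included-vs-
excluded comparisons (Pearson chi-square for categorical variables, Welch
unequal-variance *t* for ratio variables), and recruitment cost metrics
(cost per click, cost per completed record, overall cost per participant).

**Synthetic cohorts**: `generate_cohort` mixes legitimate NYC respondent
profiles with fraud archetypes injected at configurable per-category
tallies, emits a ground-truth label sidecar, and is byte-reproducible from
its seed. Because published tallies sum to more than the number of excluded
records, violations co-occur; `assign_overlaps` distributes the excess
while keeping per-category multiplicities exact.

## Worked example

```bash
surveysweep generate --out cohort.csv --labels labels.csv
surveysweep -v clean --in cohort.csv --mode marginal \
    --report report.json --included included.csv --excluded excluded.csv
```

prints the per-stage marginal tallies and the headline:

```
INFO stage foreign_ip                 flagged   279
INFO stage duplicates                 flagged   571
INFO stage fictitious_drug            flagged  1095
INFO stage zip                        flagged   510
INFO stage improbable_use             flagged   235
INFO stage overdose_outlier           flagged   232
INFO stage clusters                   flagged   351
INFO stage speeders                   flagged    76
INFO stage demographic_inconsistency  flagged    32
INFO stage open_text                  flagged   116
INFO stage email_pattern              flagged    15
2387 of 2560 records excluded (93.2%); 173 included
```

Each line is the number of records a filter fires on over all 2560
submissions (the `zip` stage combines 400 invalid ZIPs and 124 borough
mismatches; counts overlap across stages, which is why they sum to more
than 2387). On generator output the cascade recovers the injected labels
with sensitivity and specificity 1.0 — every flagged record is a planted
fraud and every legitimate record survives.

```bash
surveysweep report --included included.csv --excluded excluded.csv
```

reports, among other things, an overall advertising cost of $9.76 per
included participant (from the packaged platform recruitment table) and a
Welch test showing excluded records claim significantly more lifetime
overdoses than included ones (p < .001) — planted overdose outliers run as
high as 105.

The same operations are available as library calls
(`surveysweep.generate_cohort`, `run_cascade`, `compare_cohorts`, …).

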