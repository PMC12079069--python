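# Methods

## The screening problem

An incentivized, anonymous web survey of a hidden population cannot verify
respondents against any external frame. Fraud arrives in three broad forms:
automated bots (fast, careless, sometimes answering hidden items), click
farms (the same responder resubmitting a near-identical answer set many
times), and individual fraudsters (plausible-looking answers tuned to
perceived eligibility). No single signal separates these from genuine
respondents, so the protocol stacks many weak, rule-based signals and
treats any one violation as grounds for exclusion. The package implements
that cascade, and — because real screening data of this kind cannot be
shared — a synthetic cohort generator that reproduces the screening
conditions with ground-truth labels.

## Filters and their boundary conventions

Thresholds follow the protocol's wording strictly:

| rule | default | boundary |
|---|---|---|
| overdose outlier | > 10 lifetime overdoses | 10 passes, 11 fails |
| speeder | < 7.0 minutes | 7.0 passes, 6.99 fails |
| flagged cluster | ≥ 6 members | 5 passes, 6 fails |
| bot email | local part `^[A-Za-z]+[0-9]{5,}$` | 4 trailing digits pass |
| allowed IP countries | {US, CA} | missing country passes |

Missing data never flags. The one deliberate exception is an IP string that
does not parse as IPv4 at all, which is flagged conservatively as
unresolvable. The homelessness exemption (current homelessness excuses a
missing or invalid home ZIP) shows why tolerated missingness matters: the
same blank cell is benign in one context and suspicious in another, so the
loader keeps "missing" distinct from the empty string. ZIP checks apply
only when the reported borough is one of the five boroughs; a respondent
living outside the city may hold any ZIP the lookup cannot validate, so
that side is skipped rather than guessed at.

The Medicaid income cutoff is configuration (default: brackets at or above
US $50,000 are above eligibility; "Don't know" never flags) because no
authoritative dollar value is part of the protocol. Open-text screening is
deliberately modest: a normalized blocklist of known generic/suspicious
phrases plus exact cross-record duplication of answers of ≥ 12 characters.
No language-model scoring is attempted; flagging prose as "AI-generated"
beyond these two observable signals is not verifiable.

## Click-farm clustering

Features: gender, race/ethnicity, age, income bracket, education, and the
full substance-by-route indicator grid. Categorical fields one-hot encode;
numeric fields min–max scale to [0, 1]; complete cases only (records
missing a listed feature are returned as unclustered rather than imputed).
DBSCAN runs with Euclidean metric, eps = 0.5, min_samples = 2. In this
encoding a single categorical disagreement already costs √2 and a single
grid disagreement costs 1, both above eps, so only records identical on
every encoded feature (up to small numeric differences) can co-cluster —
the operational meaning of "nearly identical". Clusters of ≥ 6 flag all
members; smaller clusters are retained in the result but unflagged, since
small duplicate groups are plausible (household devices, resubmission after
a glitch). Submission-time spans are attached as review detail rather than
used as an automatic rule.

## Cascade semantics

Marginal mode answers "how many records does each rule hit?" over all
records — categories overlap, and their sum exceeds the excluded count.
Sequential mode answers "how many new exclusions does each stage add?"
under a fixed order. Both exclude exactly the records carrying ≥ 1
violation. Keep-first deduplication and density clustering read the whole
record set, so sequential per-stage counts are order-dependent; under the
default stage order the two modes provably agree on the included set for
generator output (see below). Summary fractions round half-up to one
decimal percent at presentation only.

## The synthetic cohort

Defaults are the packaged study conditions: 2560 submissions, 173
legitimate, per-category violation tallies
(279 / 571 / 1095 / 400 / 124 / 235 / 232 / 351 / 76 / 32 / 116 / 15), and
click-farm cluster sizes (42, 36, 33, 30, 27, 24, 21, 18, 15, 12, 9, and
fourteen 6s) summing to the 351-record cluster tally with one dominant
42-record cluster. Published accounts of this screening effort disagree
internally in two places — one summary gives 378 invalid ZIPs and 225
improbable-behavior records where the detailed tally table gives 400 and
235 (likely sequential vs marginal counting), and one platform's cost per
click is printed as 1.96 where the listed totals give 535/270 = 1.98. The
package follows the detailed table and computes costs from totals; both
discrepancies are surfaced here rather than resolved.

Legitimate respondents are drawn from configurable categorical margins
approximating the cleaned sample's published description (59% men, 44.5%
non-Hispanic Black, mean age 29.9, 52% prescription-opioid use, …); the
fraud profile skews the way excluded records did (more men, more white,
higher income, heavier and more varied use, faster completion). These
margins are configuration, not a fitted generative model: the generator
reproduces screening *structure* (who violates what, and how identities
collide), not the joint distribution of real answers, so passing tests
demonstrate filter correctness and tally accounting — not that the filters
would achieve the same yield on new field data, where legitimate records
can also trip rules (the false-positive rate on real respondents is
unidentifiable here by design; the noise-free fixture has specificity 1).

Construction guarantees, which make the cascade's label recovery exact:

- **Coverage and overlap.** Tallies sum to more than the fraud pool
  (3526 > 2387 by default, ≈ 1.48 violations per excluded record), so each
  non-cluster fraud record first receives one violation (coverage), then
  the excess mass is spread by seeded weighted sampling with exact
  per-category multiplicities. Infeasible specs fail loudly, naming the
  category.
- **Identity pools.** IPs, emails, and open-text answers are globally
  unique except where a violation requires sharing. Duplicate groups share
  the email (and, when no foreign-IP label is involved, the IP) of an
  "anchor" — an earlier fraudulent record that keep-first deduplication
  deliberately leaves unflagged. Anchors never carry foreign-IP or
  bot-email labels, so no stage that precedes deduplication can remove an
  anchor and no shared address cross-fires another filter.
- **Fingerprint uniqueness.** Every non-cluster record's categorical
  clustering fingerprint (gender, race, education, income, use grid) is
  unique cohort-wide, so distinct records sit ≥ 1 apart in the encoded
  space and only planted clusters can co-cluster. Cluster members copy all
  clustering features from their seed and carry no other violations: the
  violations that would mutate features would break within-cluster
  identity, and any violation handled by an earlier stage could shrink a
  cluster below the flagging size mid-sequence and break marginal/
  sequential agreement.
- **Timestamps.** Units (clusters, duplicate groups, singletons) get
  unique start times across a 110-day window; cluster members land within
  a short window (10–120 s gaps) and duplicate members strictly after
  their anchor. Records are emitted in submission order with sequential
  IDs, and the whole cohort is byte-reproducible from the seed.

## Statistics

Group comparisons use Pearson's chi-square test of independence without
continuity correction (a config toggle exists) and Welch's unequal-variance
t test with Welch–Satterthwaite degrees of freedom; p-values are two-sided
and unadjusted for multiple testing. Both are cross-checked in the test
suite against direct-formula evaluations to 1e-10 on random inputs, and
DBSCAN against a brute-force density-reachability closure on instances of
n ≤ 25. Cost metrics divide platform totals and round half-up to cents at
presentation only (1153.26 / 1700 = 0.6784 → 0.68).

## Problem sizes and degenerate inputs

The default cohort (2560 records, ~80 encoded feature columns) generates
and cleans in a few seconds on one CPU; tests use a 160-record cohort
exercising every category where full scale is not the point. Degenerate
inputs are defined: an all-legitimate spec yields an empty cascade; an
empty record collection round-trips as a header-only CSV; an empty roster
describes without division by zero; zero recruitment denominators report
missing rather than infinite costs.

## Known limitations

- The generator does not model real bot software, CAPTCHA solving,
  platform ad delivery, or adversarial adaptation to the filters.
- Open-text screening cannot detect novel fluent machine-generated prose.
- IP-based rules inherit the usual caveats (VPN/Tor, provider geolocation);
  the country resolver is pluggable and no live GeoIP database is bundled.
- Human adjudication of flagged clusters ("review records submitted within
  a short time frame") is supported by attached detail but not modeled.
- Sequential-mode attrition counts depend on stage order by nature; only
  the default order carries the mode-equivalence guarantee on generator
  output.
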