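"""Labeled synthetic cohort generator.

Emulates the submission mix of an incentivized online survey of people who
use opioids that was overrun by bots and malicious responders: a small
minority of legitimate NYC respondents plus fraud archetypes injected at
configurable per-category tallies (foreign IPs, duplicate IP/email groups,
fictitious-drug endorsement, invalid or mismatched ZIPs, impossible use
routes, overdose outliers, click-farm clusters of near-identical records,
speeders, Medicaid/income inconsistencies, suspicious open text, and
bulk-creator email patterns), with a ground-truth label sidecar.

The generator is constructed so the cleaning cascade recovers the injected
labels *exactly* on its output: every legitimate record passes every filter
by construction, every fraudulent record violates precisely the filters it
is labeled with, and identity pools (IPs, emails, open-text answers,
clustering-feature fingerprints) are globally unique except where a
violation requires sharing. Violations co-occur on fraudulent records
because published per-category tallies sum to more than the number of
excluded records; :func:`assign_overlaps` distributes that excess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import yaml

from .config import (
    CleaningConfig,
    DEFAULT_MEDICAID_FLAGGED_BRACKETS,
    INCOME_BRACKETS,
    default_cohort_spec_path,
)
from .records import (
    BOROUGHS,
    CURRENTLY_HOMELESS,
    HOMELESSNESS_STATUSES,
    OUTSIDE_NYC,
    ConfigurationError,
    GroundTruthLabel,
    RespondentRecord,
    ViolationCategory,
)

V = ViolationCategory

#: Violation tallies of the packaged default study conditions
#: (2560 total complete records, 2387 excluded).
DEFAULT_CATEGORY_TALLIES = {
    V.FOREIGN_IP: 279,
    V.DUPLICATE_IP_EMAIL: 571,
    V.FICTITIOUS_DRUG: 1095,
    V.INVALID_ZIP: 400,
    V.ZIP_BOROUGH_MISMATCH: 124,
    V.IMPROBABLE_USE: 235,
    V.OVERDOSE_OUTLIER: 232,
    V.CLUSTER_DUPLICATE: 351,
    V.SPEEDER: 76,
    V.DEMOGRAPHIC_INCONSISTENCY: 32,
    V.SUSPICIOUS_OPEN_TEXT: 116,
    V.EMAIL_PATTERN: 15,
}

#: Click-farm cluster sizes: one dominant 42-record cluster, a tail down to
#: the minimum flagged size of 6; sums to the CLUSTER_DUPLICATE tally (351).
DEFAULT_CLUSTER_SIZES = (42, 36, 33, 30, 27, 24, 21, 18, 15, 12, 9) + (6,) * 14

#: Fields that must be identical within a click-farm cluster (the
#: clustering feature set; substance_use expands to the use-grid block).
CLUSTER_FEATURE_FIELDS = (
    "gender", "race_ethnicity", "age_years", "income_bracket", "education",
    "substance_use",
)

FOREIGN_COUNTRIES = ("GB", "NG", "IN", "CN", "RU", "BR", "PK", "ID")

INVALID_ZIPS = ("10048", "00000", "99999", "14201")
_INVALID_ZIP_WEIGHTS = (0.4, 0.2, 0.2, 0.2)

#: Plausible routes per substance (impossible combinations excluded).
ALLOWED_ROUTES = {
    "prescription opioids": ("oral", "snort", "smoke", "inject"),
    "heroin": ("snort", "smoke", "inject", "oral"),
    "fentanyl": ("oral", "snort", "smoke", "inject"),
    "other opioids": ("oral", "snort", "smoke", "inject"),
    "alcohol": ("oral",),
    "marijuana": ("oral", "smoke"),
    "cocaine": ("snort", "smoke", "inject"),
    "benzodiazepines": ("oral", "snort"),
    "methamphetamine": ("oral", "snort", "smoke", "inject"),
    "MDMA": ("oral", "snort"),
    "ketamine": ("oral", "snort", "inject"),
    "amphetamines": ("oral", "snort"),
    "hallucinogens": ("oral",),
    "synthetic cannabinoids": ("oral", "smoke"),
    "xylazine": ("snort", "smoke", "inject"),
    "inhalants": ("snort", "smoke"),
}

OPIOIDS = ("prescription opioids", "heroin", "fentanyl", "other opioids")

_LOW_INCOME_BRACKETS = tuple(
    b for b in INCOME_BRACKETS if b not in DEFAULT_MEDICAID_FLAGGED_BRACKETS
)

_FIRST = ("alex", "jordan", "taylor", "morgan", "casey", "riley", "jamie",
          "avery", "quinn", "skyler", "devon", "reese", "kendall", "rowan",
          "emerson", "finley", "harper", "logan", "parker", "sawyer")
_LAST = ("rivera", "chen", "okafor", "smith", "garcia", "nguyen", "patel",
         "johnson", "lee", "brown", "martin", "lopez", "kim", "walker",
         "young", "scott", "reyes", "cruz", "diaz", "bell")
_DOMAINS = ("example.com", "example.org", "example.net", "mail.example")

_TEXT_TEMPLATES = (
    "They checked my arms and gave me clean needles",
    "I got naloxone and they showed me how to use it",
    "The nurse talked to me about wound care",
    "Picked up fentanyl test strips and some supplies",
    "They took my blood pressure and asked about my use",
    "Got a works kit and spoke with a counselor",
    "I asked about detox options and they gave me a referral",
    "They bandaged a sore on my leg and gave me water",
)

_START = datetime(2023, 8, 7, 9, 0, 0)
_PERIOD_SECONDS = 110 * 86400  # collection window, early Aug to late Nov


# ---------------------------------------------------------------------------
# cohort specification


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    n_total: int = 2560
    n_legitimate: int = 173
    category_tallies: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_TALLIES))
    cluster_sizes: tuple = DEFAULT_CLUSTER_SIZES
    seed: int = 20230807

    @property
    def n_fraud(self) -> int:
        return self.n_total - self.n_legitimate

    def validate(self, min_cluster_size: int = 6) -> None:
        if self.n_legitimate > self.n_total:
            raise ConfigurationError("n_legitimate exceeds n_total")
        for cat, tally in self.category_tallies.items():
            if not isinstance(cat, ViolationCategory):
                raise ConfigurationError(f"unknown violation category {cat!r}")
            if cat is V.HONEYPOT:
                raise ConfigurationError("HONEYPOT is not an injectable tally")
            if tally < 0:
                raise ConfigurationError(f"negative tally for {cat.name}")
            if tally > self.n_fraud:
                raise ConfigurationError(
                    f"tally for {cat.name} ({tally}) exceeds the fraudulent "
                    f"pool ({self.n_fraud})")
        cluster_tally = self.category_tallies.get(V.CLUSTER_DUPLICATE, 0)
        sizes = tuple(self.cluster_sizes) if cluster_tally else ()
        if sum(sizes) != cluster_tally:
            raise ConfigurationError(
                f"cluster_sizes sum to {sum(sizes)}, CLUSTER_DUPLICATE tally "
                f"is {cluster_tally}")
        if any(s < max(2, min_cluster_size) for s in sizes):
            raise ConfigurationError(
                f"every cluster size must be >= {max(2, min_cluster_size)}")
        n_noncluster = self.n_fraud - cluster_tally
        noncluster_sum = sum(t for c, t in self.category_tallies.items()
                             if c is not V.CLUSTER_DUPLICATE)
        if n_noncluster < 0:
            raise ConfigurationError(
                "CLUSTER_DUPLICATE tally exceeds the fraudulent pool")
        for cat, tally in self.category_tallies.items():
            if cat is not V.CLUSTER_DUPLICATE and tally > n_noncluster:
                raise ConfigurationError(
                    f"tally for {cat.name} ({tally}) exceeds the non-cluster "
                    f"fraudulent pool ({n_noncluster})")
        if n_noncluster > 0 and noncluster_sum < n_noncluster:
            raise ConfigurationError(
                f"category tallies sum to {noncluster_sum} but "
                f"{n_noncluster} non-cluster fraudulent records each need at "
                "least one violation")
        dup = self.category_tallies.get(V.DUPLICATE_IP_EMAIL, 0)
        anchor_pool = (n_noncluster - dup
                       - self.category_tallies.get(V.EMAIL_PATTERN, 0)
                       - self.category_tallies.get(V.FOREIGN_IP, 0))
        if dup and anchor_pool < (dup + 2) // 3:
            raise ConfigurationError(
                "DUPLICATE_IP_EMAIL tally leaves too few anchor records")

    @classmethod
    def from_yaml(cls, path=None) -> "CohortSpec":
        source = path if path is not None else default_cohort_spec_path()
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        tallies = {
            ViolationCategory[name]: int(count)
            for name, count in raw.get("category_tallies", {}).items()
        }
        return cls(
            n_total=int(raw["n_total"]),
            n_legitimate=int(raw["n_legitimate"]),
            category_tallies=tallies,
            cluster_sizes=tuple(raw.get("cluster_sizes", ())),
            seed=int(raw.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# respondent profiles


@dataclass
class RespondentProfile:
    """Marginal categorical distributions a respondent archetype is drawn
    from. The legitimate defaults approximate the published description of
    the clean final sample; the fraud profile skews the way the study's
    excluded records did (more men, more white, higher income, heavier and
    more varied reported use, faster completion)."""

    gender: dict
    race_ethnicity: dict
    sexual_orientation: dict
    education: dict
    income_bracket: dict
    homelessness: dict
    home_borough: dict
    insured_p: float
    insurance_type: dict
    referral: dict
    substance_p: dict
    extra_route_p: float
    age_mean: float
    age_sd: float
    duration_log_mean: float
    duration_log_sd: float
    min_duration: float
    overdose_dist: dict
    works_in_nyc_p: float
    counting_correct_p: float


def legitimate_profile() -> RespondentProfile:
    return RespondentProfile(
        gender={"Man": 0.5896, "Woman": 0.3584, "Transgender": 0.0231,
                "Nonbinary": 0.0231, "Prefer not to say": 0.0058},
        race_ethnicity={"Non-Hispanic White": 0.3931, "Non-Hispanic Black": 0.4451,
                        "Hispanic": 0.0751, "Asian": 0.0405,
                        "Mixed race": 0.0347, "Other": 0.0116},
        sexual_orientation={"Heterosexual": 0.815, "Bisexual": 0.104,
                            "Homosexual or queer": 0.0636,
                            "Prefer not to say": 0.0173},
        education={"Less than a high school diploma": 0.0116,
                   "High school diploma or GED": 0.1214,
                   "Some college or 2-year degree": 0.3410,
                   "4-year college degree": 0.4277,
                   "Postgraduate work": 0.0983},
        income_bracket=dict(zip(INCOME_BRACKETS,
                                (0.1965, 0.1503, 0.052, 0.1272,
                                 0.1156, 0.2081, 0.1098, 0.0405))),
        homelessness=dict(zip(HOMELESSNESS_STATUSES,
                              (0.5896, 0.2659, 0.0867, 0.0578))),
        home_borough={"Manhattan": 0.2308, "Brooklyn": 0.3373, "Bronx": 0.1716,
                      "Queens": 0.1538, "Staten Island": 0.071,
                      OUTSIDE_NYC: 0.0355},
        insured_p=0.7861,
        insurance_type={"Medicaid": 0.45, "Medicare": 0.08,
                        "Private": 0.37, "Other": 0.10},
        referral={"Meta": 0.457, "Reddit": 0.278, "Friend referral": 0.225,
                  "X": 0.017, "Discord": 0.017, "Bluelight": 0.006},
        substance_p={"prescription opioids": 0.518, "heroin": 0.1942,
                     "fentanyl": 0.241, "other opioids": 0.0468,
                     "alcohol": 0.7688, "marijuana": 0.5202,
                     "cocaine": 0.1908, "benzodiazepines": 0.2948,
                     "methamphetamine": 0.1272, "MDMA": 0.2081,
                     "ketamine": 0.0983, "amphetamines": 0.1965,
                     "hallucinogens": 0.104, "synthetic cannabinoids": 0.1503,
                     "xylazine": 0.0578, "inhalants": 0.0694},
        extra_route_p=0.3,
        age_mean=29.86, age_sd=6.52,
        duration_log_mean=float(np.log(28.0)), duration_log_sd=0.35,
        min_duration=8.0,
        overdose_dist={0: 0.5665, 1: 0.20, 2: 0.11, 3: 0.06, 4: 0.035,
                       5: 0.018, 6: 0.0105},
        works_in_nyc_p=0.55,
        counting_correct_p=1.0,
    )


def fraud_profile() -> RespondentProfile:
    base = legitimate_profile()
    base.gender = {"Man": 0.65, "Woman": 0.30, "Transgender": 0.02,
                   "Nonbinary": 0.02, "Prefer not to say": 0.01}
    base.race_ethnicity = {"Non-Hispanic White": 0.49,
                           "Non-Hispanic Black": 0.445, "Hispanic": 0.03,
                           "Asian": 0.015, "Mixed race": 0.015, "Other": 0.005}
    base.education = {"Less than a high school diploma": 0.05,
                      "High school diploma or GED": 0.30,
                      "Some college or 2-year degree": 0.35,
                      "4-year college degree": 0.25,
                      "Postgraduate work": 0.05}
    base.income_bracket = dict(zip(INCOME_BRACKETS,
                                   (0.08, 0.08, 0.06, 0.14,
                                    0.14, 0.25, 0.22, 0.03)))
    base.referral = {"Meta": 0.60, "Reddit": 0.15, "Friend referral": 0.08,
                     "X": 0.10, "Discord": 0.05, "Bluelight": 0.02}
    base.substance_p = {"prescription opioids": 0.70, "heroin": 0.45,
                        "fentanyl": 0.50, "other opioids": 0.15,
                        "alcohol": 0.85, "marijuana": 0.70,
                        "cocaine": 0.40, "benzodiazepines": 0.45,
                        "methamphetamine": 0.30, "MDMA": 0.35,
                        "ketamine": 0.25, "amphetamines": 0.35,
                        "hallucinogens": 0.25, "synthetic cannabinoids": 0.30,
                        "xylazine": 0.15, "inhalants": 0.18}
    base.extra_route_p = 0.45
    base.duration_log_mean = float(np.log(14.0))
    base.duration_log_sd = 0.4
    base.min_duration = 7.1
    base.overdose_dist = {0: 0.30, 1: 0.20, 2: 0.15, 3: 0.12, 4: 0.09,
                          5: 0.06, 6: 0.04, 7: 0.025, 8: 0.015}
    base.counting_correct_p = 0.8
    return base


#: Kept for discoverability: the profile the minority of genuine NYC
#: respondents is drawn from.
LegitimateProfileModel = RespondentProfile


def _pick(rng: np.random.Generator, dist: dict):
    values = list(dist)
    probs = np.array([dist[v] for v in values], dtype=float)
    probs /= probs.sum()
    return values[int(rng.choice(len(values), p=probs))]


class _Pools:
    """Globally unique identity pools plus the clustering-feature
    fingerprint registry (categorical tuple; two distinct fingerprints are
    always >= 1 apart in the encoded space, so only injected clusters can
    co-cluster under the default narrow radius)."""

    def __init__(self) -> None:
        self._ip = 0
        self._foreign_ip = 0
        self._email = 0
        self._pattern_email = 0
        self._text = 0
        self.fingerprints: set = set()

    def next_ip(self) -> str:
        n = self._ip
        self._ip += 1
        return f"66.{(n // 65536) % 256}.{(n // 256) % 256}.{n % 256}"

    def next_foreign_ip(self) -> str:
        n = self._foreign_ip
        self._foreign_ip += 1
        return f"81.{(n // 65536) % 256}.{(n // 256) % 256}.{n % 256}"

    def next_email(self, rng: np.random.Generator) -> str:
        n = self._email
        self._email += 1
        first = _FIRST[int(rng.integers(len(_FIRST)))]
        last = _LAST[int(rng.integers(len(_LAST)))]
        domain = _DOMAINS[int(rng.integers(len(_DOMAINS)))]
        sep = "." if rng.random() < 0.4 else ""
        return f"{first}{sep}{last}{n}@{domain}"

    def next_pattern_email(self, rng: np.random.Generator) -> str:
        n = self._pattern_email
        self._pattern_email += 1
        letters = "".join(
            chr(ord("a") + int(rng.integers(26))) for _ in range(7))
        return f"{letters}{10000 + n}@{_DOMAINS[int(rng.integers(len(_DOMAINS)))]}"

    def next_text(self, rng: np.random.Generator) -> str:
        n = self._text
        self._text += 1
        template = _TEXT_TEMPLATES[int(rng.integers(len(_TEXT_TEMPLATES)))]
        return f"{template} (visit {n})"


def fingerprint(record: RespondentRecord) -> tuple:
    return (record.gender, record.race_ethnicity, record.education,
            record.income_bracket, record.substance_use)


def _zips_by_borough(lookup: dict) -> dict:
    out: dict[str, list] = {b: [] for b in BOROUGHS}
    for zip_code, borough in lookup.items():
        out[borough].append(zip_code)
    return {b: sorted(z) for b, z in out.items()}


def _sample_base(profile: RespondentProfile, rng: np.random.Generator,
                 zips: dict, pools: _Pools,
                 flagged_brackets) -> RespondentRecord:
    """Draw one record that passes every filter."""
    substances = [s for s in ALLOWED_ROUTES if rng.random() < profile.substance_p[s]]
    if not any(s in OPIOIDS for s in substances):
        substances.append("prescription opioids")  # eligibility: opioid use
    use = set()
    for substance in substances:
        routes = ALLOWED_ROUTES[substance]
        k = 1 + (rng.random() < profile.extra_route_p and len(routes) > 1)
        chosen = rng.choice(len(routes), size=int(k), replace=False)
        for j in chosen:
            use.add((substance, routes[int(j)]))

    income = _pick(rng, profile.income_bracket)
    insured = rng.random() < profile.insured_p
    insurance_type = _pick(rng, profile.insurance_type) if insured else None
    if insurance_type == "Medicaid" and income in flagged_brackets:
        insurance_type = "Private"  # keep the record internally consistent

    home_borough = _pick(rng, profile.home_borough)
    homelessness = _pick(rng, profile.homelessness)
    lives_in_nyc = home_borough != OUTSIDE_NYC
    works_in_nyc = (rng.random() < profile.works_in_nyc_p) or not lives_in_nyc
    if home_borough == OUTSIDE_NYC:
        home_zip = None
    elif homelessness == CURRENTLY_HOMELESS and rng.random() < 0.6:
        home_zip = None
    else:
        home_zip = zips[home_borough][int(rng.integers(len(zips[home_borough])))]
    if works_in_nyc:
        work_borough = BOROUGHS[int(rng.integers(len(BOROUGHS)))]
        work_zip = zips[work_borough][int(rng.integers(len(zips[work_borough])))]
    else:
        work_borough = None
        work_zip = None

    duration = max(profile.min_duration,
                   float(rng.lognormal(profile.duration_log_mean,
                                       profile.duration_log_sd)))
    return RespondentRecord(
        record_id="pending",
        submitted_at=_START,
        duration_minutes=round(duration, 2),
        ip_address=pools.next_ip(),
        ip_country="CA" if rng.random() < 0.03 else "US",
        email=pools.next_email(rng),
        age_years=int(np.clip(round(rng.normal(profile.age_mean,
                                               profile.age_sd)), 18, 63)),
        gender=_pick(rng, profile.gender),
        race_ethnicity=_pick(rng, profile.race_ethnicity),
        sexual_orientation=_pick(rng, profile.sexual_orientation),
        education=_pick(rng, profile.education),
        income_bracket=income,
        insurance_status="Yes" if insured else "No",
        insurance_type=insurance_type,
        lives_in_nyc=lives_in_nyc,
        works_in_nyc=works_in_nyc,
        home_borough=home_borough,
        work_borough=work_borough,
        home_zip=home_zip,
        work_zip=work_zip,
        homelessness_status=homelessness,
        substance_use=frozenset(use),
        lifetime_overdoses=_pick(rng, profile.overdose_dist),
        open_text={"services": pools.next_text(rng)},
        honeypot_answered=False,
        counting_check_correct=rng.random() < profile.counting_correct_p,
        referral_source=_pick(rng, profile.referral),
    )


# ---------------------------------------------------------------------------
# violation machinery


#: Violations that mutate clustering features; never assigned to click-farm
#: cluster members, whose features must stay identical within the cluster.
FEATURE_MUTATING = (V.FICTITIOUS_DRUG, V.IMPROBABLE_USE,
                    V.DEMOGRAPHIC_INCONSISTENCY)


def assign_overlaps(n_records: int, tallies: dict,
                    rng: Optional[np.random.Generator] = None,
                    incompatible: Sequence = ()) -> list[frozenset]:
    """Distribute per-category violation tallies over ``n_records`` records.

    Every record receives at least one violation (coverage first), then the
    remaining tally mass is spread by seeded weighted sampling; per-category
    multiplicities match ``tallies`` exactly and pairs listed in
    ``incompatible`` are never co-assigned.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    remaining = {}
    for cat, tally in tallies.items():
        tally = int(tally)
        if tally < 0:
            raise ConfigurationError(f"negative tally for {cat}")
        if tally > n_records:
            raise ConfigurationError(
                f"tally for {cat} ({tally}) exceeds the record pool "
                f"({n_records})")
        if tally:
            remaining[cat] = tally
    if n_records == 0:
        if remaining:
            raise ConfigurationError("tallies given for an empty record pool")
        return []
    if sum(remaining.values()) < n_records:
        raise ConfigurationError(
            f"tallies sum to {sum(remaining.values())} < {n_records}: some "
            "record would carry no violation")

    partners: dict = {}
    for pair in incompatible:
        a, b = tuple(pair)
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    sets: list[set] = [set() for _ in range(n_records)]
    cats = sorted(remaining, key=str)

    # coverage pass: one violation per record, drawn with probability
    # proportional to the remaining tally mass
    for idx in rng.permutation(n_records):
        probs = np.array([remaining[c] for c in cats], dtype=float)
        cat = cats[int(rng.choice(len(cats), p=probs / probs.sum()))]
        sets[int(idx)].add(cat)
        remaining[cat] -= 1
        if remaining[cat] == 0:
            del remaining[cat]
            cats.remove(cat)

    # spread the excess mass, tightest category first
    for cat in sorted(remaining, key=lambda c: (-remaining[c], str(c))):
        blocked = partners.get(cat, set())
        eligible = [i for i in range(n_records)
                    if cat not in sets[i] and not (sets[i] & blocked)]
        if len(eligible) < remaining[cat]:
            raise ConfigurationError(
                f"cannot place {remaining[cat]} extra {cat} violations "
                f"({len(eligible)} eligible records)")
        for j in rng.choice(len(eligible), size=remaining[cat], replace=False):
            sets[eligible[int(j)]].add(cat)
    return [frozenset(s) for s in sets]


def inject_violation(record: RespondentRecord, category: ViolationCategory,
                     rng: np.random.Generator, *,
                     config: Optional[CleaningConfig] = None,
                     partner: Optional[RespondentRecord] = None,
                     pools: Optional[_Pools] = None,
                     side: str = "home") -> RespondentRecord:
    """Mutate ``record`` in place so it violates exactly ``category``.

    ``partner`` is the record whose identity/features are shared for
    DUPLICATE_IP_EMAIL and CLUSTER_DUPLICATE; ``side`` selects the home or
    work ZIP for the ZIP categories.
    """
    config = config or CleaningConfig()
    pools = pools or _Pools()
    if category is V.FOREIGN_IP:
        record.ip_address = pools.next_foreign_ip()
        record.ip_country = FOREIGN_COUNTRIES[
            int(rng.integers(len(FOREIGN_COUNTRIES)))]
    elif category is V.DUPLICATE_IP_EMAIL:
        if partner is None:
            raise ValueError("DUPLICATE_IP_EMAIL needs a partner record")
        record.email = partner.email
        if record.ip_country in ("US", "CA") and partner.ip_country in ("US", "CA"):
            record.ip_address = partner.ip_address
            record.ip_country = partner.ip_country
    elif category is V.FICTITIOUS_DRUG:
        from .records import ROUTES
        route = ROUTES[int(rng.integers(len(ROUTES)))]
        record.substance_use = record.substance_use | {
            (config.fictitious_drug, route)}
    elif category is V.INVALID_ZIP:
        zip_code = str(rng.choice(INVALID_ZIPS, p=_INVALID_ZIP_WEIGHTS))
        _set_zip_violation(record, rng, side, zip_code=zip_code)
    elif category is V.ZIP_BOROUGH_MISMATCH:
        _set_zip_violation(record, rng, side, lookup=config.zip_lookup())
    elif category is V.IMPROBABLE_USE:
        pairs = sorted(config.impossible_pairs())
        record.substance_use = record.substance_use | {
            pairs[int(rng.integers(len(pairs)))]}
    elif category is V.OVERDOSE_OUTLIER:
        record.lifetime_overdoses = int(rng.integers(11, 106))
    elif category is V.CLUSTER_DUPLICATE:
        if partner is None:
            raise ValueError("CLUSTER_DUPLICATE needs a cluster seed partner")
        for field_name in CLUSTER_FEATURE_FIELDS:
            setattr(record, field_name, getattr(partner, field_name))
        if (record.insurance_type == "Medicaid"
                and record.income_bracket in config.medicaid_flagged_brackets):
            record.insurance_type = "Private"
    elif category is V.SPEEDER:
        record.duration_minutes = round(float(rng.uniform(2.0, 6.9)), 2)
    elif category is V.DEMOGRAPHIC_INCONSISTENCY:
        record.insurance_status = "Yes"
        record.insurance_type = "Medicaid"
        brackets = config.medicaid_flagged_brackets
        record.income_bracket = brackets[int(rng.integers(len(brackets)))]
    elif category is V.SUSPICIOUS_OPEN_TEXT:
        phrases = config.suspicious_phrases()
        record.open_text = dict(record.open_text)
        record.open_text["services"] = phrases[int(rng.integers(len(phrases)))]
    elif category is V.EMAIL_PATTERN:
        record.email = pools.next_pattern_email(rng)
    else:
        raise ValueError(f"unknown violation category {category!r}")
    return record


def _set_zip_violation(record: RespondentRecord, rng: np.random.Generator,
                       side: str, zip_code: Optional[str] = None,
                       lookup: Optional[dict] = None) -> None:
    """Install an invalid (zip_code given) or mismatched (lookup given) ZIP
    on the requested side; lift the homelessness exemption for home-side."""
    borough = BOROUGHS[int(rng.integers(len(BOROUGHS)))]
    if zip_code is None:
        others = sorted(z for z, b in lookup.items() if b != borough)
        zip_code = others[int(rng.integers(len(others)))]
    if side == "home":
        record.home_borough = borough
        record.home_zip = zip_code
        record.lives_in_nyc = True
        if record.homelessness_status == CURRENTLY_HOMELESS:
            record.homelessness_status = HOMELESSNESS_STATUSES[0]
    else:
        record.works_in_nyc = True
        record.work_borough = borough
        record.work_zip = zip_code


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(spec: Optional[CohortSpec] = None,
                    config: Optional[CleaningConfig] = None
                    ) -> tuple[list[RespondentRecord], list[GroundTruthLabel]]:
    """Generate a labeled cohort under ``spec``.

    Fully reproducible from ``spec.seed``; per-category label counts equal
    ``spec.category_tallies`` exactly, the cleaning cascade recovers the
    labels perfectly, and records are returned in submission-time order with
    sequential record IDs.
    """
    spec = spec or CohortSpec()
    config = config or CleaningConfig()
    spec.validate(config.min_cluster_size)
    rng = np.random.default_rng(spec.seed)
    pools = _Pools()
    lookup = config.zip_lookup()
    zips = _zips_by_borough(lookup)
    flagged_brackets = config.medicaid_flagged_brackets
    legit = legitimate_profile()
    fraud = fraud_profile()

    cluster_tally = spec.category_tallies.get(V.CLUSTER_DUPLICATE, 0)
    noncluster_tallies = {c: t for c, t in spec.category_tallies.items()
                          if c is not V.CLUSTER_DUPLICATE and t > 0}
    n_noncluster = spec.n_fraud - cluster_tally

    violation_sets = (
        assign_overlaps(
            n_noncluster, noncluster_tallies, rng,
            incompatible=[frozenset({V.EMAIL_PATTERN, V.DUPLICATE_IP_EMAIL})])
        if n_noncluster else [])

    def draw_unique(profile, feature_cats=()):
        """Sample a base record, apply feature-mutating violations, and
        retry until the clustering fingerprint is globally unique."""
        for _ in range(500):
            rec = _sample_base(profile, rng, zips, pools, flagged_brackets)
            for cat in feature_cats:
                inject_violation(rec, cat, rng, config=config, pools=pools)
            fp = fingerprint(rec)
            if fp not in pools.fingerprints:
                pools.fingerprints.add(fp)
                return rec
        raise RuntimeError("could not draw a unique feature fingerprint")

    entries: list[dict] = []  # record, violations, cluster_id, unit, offset

    # legitimate minority
    for _ in range(spec.n_legitimate):
        entries.append({"record": draw_unique(legit),
                        "violations": frozenset(), "cluster_id": None})

    # non-cluster fraud
    fraud_entries = []
    for vset in violation_sets:
        feature_cats = sorted((c for c in vset if c in FEATURE_MUTATING),
                              key=lambda c: c.name)
        rec = draw_unique(fraud, feature_cats)
        for cat in sorted(vset, key=lambda c: c.name):
            if cat in FEATURE_MUTATING or cat is V.DUPLICATE_IP_EMAIL:
                continue
            if cat is V.ZIP_BOROUGH_MISMATCH:
                side = "work" if V.INVALID_ZIP in vset else "home"
                inject_violation(rec, cat, rng, config=config, pools=pools,
                                 side=side)
            else:
                inject_violation(rec, cat, rng, config=config, pools=pools)
        entry = {"record": rec, "violations": vset, "cluster_id": None}
        entries.append(entry)
        fraud_entries.append(entry)

    # duplicate IP/email groups: the earliest member (anchor) is an already
    # fraudulent record that is not itself flagged under keep-first
    dup_entries = [e for e in fraud_entries
                   if V.DUPLICATE_IP_EMAIL in e["violations"]]
    anchor_pool = [e for e in fraud_entries
                   if not (e["violations"]
                           & {V.DUPLICATE_IP_EMAIL, V.EMAIL_PATTERN,
                              V.FOREIGN_IP})]
    groups: list[list] = []
    queue = list(rng.permutation(len(dup_entries)))
    while queue:
        size = int(rng.integers(1, 4))
        groups.append([dup_entries[int(i)] for i in queue[:size]])
        queue = queue[size:]
    if len(groups) > len(anchor_pool):
        raise ConfigurationError("too few duplicate-group anchor records")
    anchor_ids = rng.choice(len(anchor_pool), size=len(groups), replace=False)
    dup_units = []
    for group, a in zip(groups, anchor_ids):
        anchor = anchor_pool[int(a)]
        for member in group:
            inject_violation(member["record"], V.DUPLICATE_IP_EMAIL, rng,
                             config=config, partner=anchor["record"])
        dup_units.append([anchor] + group)

    # click-farm clusters: members share all clustering features with a seed
    cluster_units = []
    for cluster_id, size in enumerate(tuple(spec.cluster_sizes)
                                      if cluster_tally else ()):
        seed_rec = draw_unique(fraud)
        members = []
        first = {"record": seed_rec,
                 "violations": frozenset({V.CLUSTER_DUPLICATE}),
                 "cluster_id": cluster_id}
        entries.append(first)
        members.append(first)
        for _ in range(size - 1):
            rec = _sample_base(fraud, rng, zips, pools, flagged_brackets)
            inject_violation(rec, V.CLUSTER_DUPLICATE, rng, config=config,
                             partner=seed_rec)
            entry = {"record": rec,
                     "violations": frozenset({V.CLUSTER_DUPLICATE}),
                     "cluster_id": cluster_id}
            entries.append(entry)
            members.append(entry)
        cluster_units.append(members)

    # timestamps: one start per unit (cluster, duplicate group, or single
    # record); cluster members land in a short window, duplicate members
    # strictly after their anchor
    in_unit = {id(e) for unit in dup_units + cluster_units for e in unit}
    units: list[tuple[list, str]] = (
        [(unit, "dup") for unit in dup_units]
        + [(unit, "cluster") for unit in cluster_units]
        + [([e], "single") for e in entries if id(e) not in in_unit]
    )
    starts: set = set()
    for unit, kind in units:
        while True:
            start = int(rng.integers(0, _PERIOD_SECONDS))
            if start not in starts:
                starts.add(start)
                break
        offset = 0.0
        for j, entry in enumerate(unit):
            if kind == "cluster" and j > 0:
                offset += float(rng.uniform(10.0, 120.0))
            elif kind == "dup" and j > 0:
                offset += float(rng.uniform(120.0, 3600.0))
            entry["record"].submitted_at = _START + timedelta(
                seconds=start + offset)

    entries.sort(key=lambda e: e["record"].submitted_at)
    records, labels = [], []
    for i, entry in enumerate(entries):
        rid = f"R{i + 1:04d}"
        entry["record"].record_id = rid
        records.append(entry["record"])
        labels.append(GroundTruthLabel(
            record_id=rid,
            is_legitimate=not entry["violations"],
            injected_violations=entry["violations"],
            cluster_id=entry["cluster_id"],
        ))
    return records, labels
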