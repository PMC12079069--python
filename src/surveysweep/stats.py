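"""Descriptive and comparative statistics for the cleaned sample.

Included-vs-excluded comparisons use the Pearson chi-square test of
independence for categorical variables and the Welch unequal-variance t
test for ratio variables, unadjusted for multiple testing. Recruitment
cost metrics are computed from platform totals, with half-up rounding to
cents applied only at presentation (internal arithmetic is unrounded, so
1153.26 / 1700 = 0.6784 presents as 0.68).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import default_recruitment_table_path
from .records import RespondentRecord

RATIO_VARIABLES = frozenset({"age_years", "lifetime_overdoses",
                             "duration_minutes"})

CATEGORICAL_VARIABLES = (
    "gender", "race_ethnicity", "sexual_orientation", "home_borough",
    "homelessness_status", "income_bracket", "education",
    "insurance_status", "referral_source",
)


@dataclass
class RecruitmentRow:
    """One advertising platform's recruitment counts and cost."""

    platform: str
    impressions: Optional[int] = None
    clicks: Optional[int] = None
    total_cost: Optional[float] = None
    completed_n: int = 0

    def __post_init__(self) -> None:
        if self.completed_n < 0:
            raise ValueError(f"{self.platform}: completed_n must be >= 0")
        if self.total_cost is not None and self.total_cost < 0:
            raise ValueError(f"{self.platform}: total_cost must be >= 0")


@dataclass
class ComparisonResult:
    variable: str
    test: str                     # "chi-square" | "welch-t"
    statistic: float
    df: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.test == "chi-square" and self.statistic < 0:
            raise ValueError("chi-square statistic must be >= 0")


def _round_cents(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"),
                                               rounding=ROUND_HALF_UP))


def load_recruitment_table(path=None) -> list[RecruitmentRow]:
    """Read a recruitment table CSV (packaged default if no path given)."""
    source = path if path is not None else default_recruitment_table_path()
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    rows = []
    for _, row in frame.iterrows():
        rows.append(RecruitmentRow(
            platform=row["platform"],
            impressions=int(row["impressions"]) if row["impressions"] else None,
            clicks=int(row["clicks"]) if row["clicks"] else None,
            total_cost=float(row["total_cost"]) if row["total_cost"] else None,
            completed_n=int(row["completed_n"]),
        ))
    return rows


def cost_per_click(row: RecruitmentRow) -> Optional[float]:
    """Ad spend per link click, in dollars rounded half-up to cents;
    missing where the platform had no (paid) clicks."""
    if not row.clicks or row.total_cost is None:
        return None
    return _round_cents(row.total_cost / row.clicks)


def cost_per_record(row: RecruitmentRow) -> Optional[float]:
    """Ad spend per completed record, rounded half-up to cents."""
    if not row.completed_n or row.total_cost is None:
        return None
    return _round_cents(row.total_cost / row.completed_n)


def overall_cost_per_participant(rows: Sequence[RecruitmentRow],
                                 final_n: int) -> float:
    """Total ad spend over all platforms divided by the final sample size."""
    if not rows:
        raise ValueError("no recruitment rows given")
    if final_n <= 0:
        raise ValueError("final_n must be positive")
    total = sum(row.total_cost for row in rows if row.total_cost is not None)
    return _round_cents(total / final_n)


def chi_square_independence(table) -> ComparisonResult:
    """Pearson chi-square test of independence on a two-way count table
    (no continuity correction)."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or (counts < 0).any():
        raise ValueError("table must be a 2-D nonnegative count table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be nonzero")
    result = sps.chi2_contingency(counts, correction=False)
    return ComparisonResult(
        variable="", test="chi-square",
        statistic=float(result.statistic), df=float(result.dof),
        p_value=float(result.pvalue),
    )


def welch_t(sample_a, sample_b) -> ComparisonResult:
    """Welch two-sample t test with Welch-Satterthwaite df, two-sided."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    result = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        variable="", test="welch-t",
        statistic=float(result.statistic), df=float(result.df),
        p_value=float(result.pvalue),
        group_summaries={
            "a": {"n": len(a), "mean": float(a.mean()),
                  "sd": float(a.std(ddof=1))},
            "b": {"n": len(b), "mean": float(b.mean()),
                  "sd": float(b.std(ddof=1))},
        },
    )


def _pct(n: int, total: int) -> float:
    if total == 0:
        return 0.0
    return float((Decimal(n) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


def describe_sample(records: Sequence[RespondentRecord]) -> dict:
    """Basic frequencies (counts, percents to two decimals) for categorical
    fields and mean (SD) for age and lifetime overdoses."""
    n = len(records)
    categorical = {}
    for variable in CATEGORICAL_VARIABLES:
        values = [getattr(r, variable) for r in records
                  if getattr(r, variable) is not None]
        table = {}
        for level in sorted(set(values)):
            count = sum(1 for v in values if v == level)
            table[level] = {"n": count, "pct": _pct(count, n)}
        categorical[variable] = table
    numeric = {}
    for variable in ("age_years", "lifetime_overdoses"):
        values = np.array([getattr(r, variable) for r in records
                           if getattr(r, variable) is not None], dtype=float)
        numeric[variable] = {
            "n": int(len(values)),
            "mean": float(values.mean()) if len(values) else None,
            "sd": float(values.std(ddof=1)) if len(values) > 1 else None,
        }
    return {"n": n, "categorical": categorical, "numeric": numeric}


def compare_cohorts(included: Sequence[RespondentRecord],
                    excluded: Sequence[RespondentRecord],
                    variables: Sequence[str]) -> list[ComparisonResult]:
    """Included-vs-excluded comparison per variable: chi-square for
    categorical variables, Welch t for ratio variables."""
    results = []
    for variable in variables:
        if variable not in RespondentRecord.__dataclass_fields__:
            raise ValueError(f"unknown variable {variable!r}")
        if variable in RATIO_VARIABLES:
            a = [getattr(r, variable) for r in included
                 if getattr(r, variable) is not None]
            b = [getattr(r, variable) for r in excluded
                 if getattr(r, variable) is not None]
            result = welch_t(a, b)
            result.group_summaries = {
                "included": result.group_summaries["a"],
                "excluded": result.group_summaries["b"],
            }
        else:
            inc = [getattr(r, variable) for r in included
                   if getattr(r, variable) is not None]
            exc = [getattr(r, variable) for r in excluded
                   if getattr(r, variable) is not None]
            levels = sorted(set(inc) | set(exc))
            table = [[sum(1 for v in inc if v == level),
                      sum(1 for v in exc if v == level)]
                     for level in levels]
            result = chi_square_independence(table)
            result.group_summaries = {
                "included": {level: row[0] for level, row in zip(levels, table)},
                "excluded": {level: row[1] for level, row in zip(levels, table)},
            }
        result.variable = variable
        results.append(result)
    return results
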