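"""Survey submission schema and flat CSV I/O.

A submission is one row of a REDCap-style flat export: identity signals
(IP, email, timestamps), geography (borough / ZIP / homelessness status),
a substance-by-route use grid, lifetime overdose count, open-text answers,
and recorded bot-trap outcomes (honeypot, counting-image check).

Missing values are empty cells on disk and ``None`` in memory; an empty
string is never used as a missing sentinel, because the cleaning rules
distinguish "left blank" (tolerated) from "answered badly" (flagged).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

import pandas as pd
from pandas.errors import ParserError


class SchemaError(ValueError):
    """A file or record violates the submission schema."""


class ConfigurationError(ValueError):
    """A configuration or cohort specification is inconsistent/infeasible."""


class ViolationCategory(enum.Enum):
    """Exclusion categories of the post hoc cleaning protocol.

    The first twelve mirror the published violation-tally rows
    (:data:`TABLE_CATEGORIES`); HONEYPOT records hidden-item answers, which
    are reported separately from the tally surface.
    """

    FOREIGN_IP = "FOREIGN_IP"
    DUPLICATE_IP_EMAIL = "DUPLICATE_IP_EMAIL"
    FICTITIOUS_DRUG = "FICTITIOUS_DRUG"
    INVALID_ZIP = "INVALID_ZIP"
    ZIP_BOROUGH_MISMATCH = "ZIP_BOROUGH_MISMATCH"
    IMPROBABLE_USE = "IMPROBABLE_USE"
    OVERDOSE_OUTLIER = "OVERDOSE_OUTLIER"
    CLUSTER_DUPLICATE = "CLUSTER_DUPLICATE"
    SPEEDER = "SPEEDER"
    DEMOGRAPHIC_INCONSISTENCY = "DEMOGRAPHIC_INCONSISTENCY"
    SUSPICIOUS_OPEN_TEXT = "SUSPICIOUS_OPEN_TEXT"
    EMAIL_PATTERN = "EMAIL_PATTERN"
    HONEYPOT = "HONEYPOT"


#: The twelve tally categories, in published row order.
TABLE_CATEGORIES: tuple[ViolationCategory, ...] = (
    ViolationCategory.FOREIGN_IP,
    ViolationCategory.DUPLICATE_IP_EMAIL,
    ViolationCategory.FICTITIOUS_DRUG,
    ViolationCategory.INVALID_ZIP,
    ViolationCategory.ZIP_BOROUGH_MISMATCH,
    ViolationCategory.IMPROBABLE_USE,
    ViolationCategory.OVERDOSE_OUTLIER,
    ViolationCategory.CLUSTER_DUPLICATE,
    ViolationCategory.SPEEDER,
    ViolationCategory.DEMOGRAPHIC_INCONSISTENCY,
    ViolationCategory.SUSPICIOUS_OPEN_TEXT,
    ViolationCategory.EMAIL_PATTERN,
)

BOROUGHS = ("Manhattan", "Bronx", "Brooklyn", "Queens", "Staten Island")
OUTSIDE_NYC = "Outside NYC"

ROUTES = ("oral", "snort", "smoke", "inject")

SUBSTANCES = (
    "prescription opioids",
    "heroin",
    "fentanyl",
    "other opioids",
    "alcohol",
    "marijuana",
    "cocaine",
    "benzodiazepines",
    "methamphetamine",
    "MDMA",
    "ketamine",
    "amphetamines",
    "hallucinogens",
    "synthetic cannabinoids",
    "xylazine",
    "inhalants",
)

#: Default name of the nonexistent checklist drug used as a validity trap.
DEFAULT_FICTITIOUS_DRUG = "cebranopadol-X"

CURRENTLY_HOMELESS = "Currently homeless"

HOMELESSNESS_STATUSES = (
    "Stably housed, no past homelessness",
    "Stably housed, past homelessness",
    CURRENTLY_HOMELESS,
    "Stably housed but worried about housing",
)


@dataclass
class RespondentRecord:
    """One survey submission."""

    record_id: str
    submitted_at: datetime
    duration_minutes: float
    ip_address: Optional[str] = None
    ip_country: Optional[str] = None
    email: Optional[str] = None
    age_years: Optional[int] = None
    gender: Optional[str] = None
    race_ethnicity: Optional[str] = None
    sexual_orientation: Optional[str] = None
    education: Optional[str] = None
    income_bracket: Optional[str] = None
    insurance_status: Optional[str] = None
    insurance_type: Optional[str] = None
    lives_in_nyc: Optional[bool] = None
    works_in_nyc: Optional[bool] = None
    home_borough: Optional[str] = None
    work_borough: Optional[str] = None
    home_zip: Optional[str] = None
    work_zip: Optional[str] = None
    homelessness_status: Optional[str] = None
    substance_use: frozenset = frozenset()
    lifetime_overdoses: Optional[int] = None
    open_text: dict = field(default_factory=dict)
    honeypot_answered: bool = False
    counting_check_correct: Optional[bool] = None
    referral_source: Optional[str] = None

    def __post_init__(self) -> None:
        self.substance_use = frozenset(self.substance_use)
        if self.duration_minutes is not None and self.duration_minutes <= 0:
            raise SchemaError(
                f"record {self.record_id!r}: duration_minutes must be positive"
            )
        if self.lifetime_overdoses is not None and self.lifetime_overdoses < 0:
            raise SchemaError(
                f"record {self.record_id!r}: lifetime_overdoses must be >= 0"
            )
        for zname in ("home_zip", "work_zip"):
            z = getattr(self, zname)
            if z is not None and not (len(z) == 5 and z.isdigit()):
                raise SchemaError(
                    f"record {self.record_id!r}: {zname} {z!r} is not a 5-digit ZIP"
                )


@dataclass
class GroundTruthLabel:
    """Generator sidecar: per-record validity and injected violation set."""

    record_id: str
    is_legitimate: bool
    injected_violations: frozenset = frozenset()
    cluster_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.injected_violations = frozenset(self.injected_violations)
        if self.is_legitimate != (len(self.injected_violations) == 0):
            raise SchemaError(
                f"label {self.record_id!r}: is_legitimate must mirror an empty "
                "injected-violation set"
            )


# --- CSV serialization -----------------------------------------------------

_MANDATORY_COLUMNS = ("record_id", "submitted_at", "duration_minutes")

_SCALAR_COLUMNS = (
    "record_id",
    "submitted_at",
    "duration_minutes",
    "ip_address",
    "ip_country",
    "email",
    "age_years",
    "gender",
    "race_ethnicity",
    "sexual_orientation",
    "education",
    "income_bracket",
    "insurance_status",
    "insurance_type",
    "lives_in_nyc",
    "works_in_nyc",
    "home_borough",
    "work_borough",
    "home_zip",
    "work_zip",
    "homelessness_status",
    "substance_use",
    "lifetime_overdoses",
    "honeypot_answered",
    "counting_check_correct",
    "referral_source",
)

_TEXT_PREFIX = "text_"  # open_text question columns: text_<question id>


def _fmt_bool(value: Optional[bool]) -> str:
    if value is None:
        return ""
    return "true" if value else "false"


def _parse_bool(cell: str, where: str) -> Optional[bool]:
    if cell == "":
        return None
    low = cell.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise SchemaError(f"{where}: cannot parse boolean {cell!r}")


def _fmt_substances(pairs: Iterable[tuple[str, str]]) -> str:
    return ";".join(f"{s}|{r}" for s, r in sorted(pairs))


def _parse_substances(cell: str, where: str, fictitious_drug: str) -> frozenset:
    if cell == "":
        return frozenset()
    vocab = set(SUBSTANCES) | {fictitious_drug}
    pairs = []
    for token in cell.split(";"):
        try:
            substance, route = token.split("|")
        except ValueError as exc:
            raise SchemaError(f"{where}: malformed substance token {token!r}") from exc
        if substance not in vocab or route not in ROUTES:
            raise SchemaError(
                f"{where}: substance/route pair {(substance, route)!r} outside "
                "the declared vocabulary"
            )
        pairs.append((substance, route))
    return frozenset(pairs)


def record_to_row(record: RespondentRecord) -> dict:
    row = {}
    for col in _SCALAR_COLUMNS:
        value = getattr(record, col)
        if col == "submitted_at":
            row[col] = value.isoformat() if value is not None else ""
        elif col == "substance_use":
            row[col] = _fmt_substances(value)
        elif col in ("lives_in_nyc", "works_in_nyc", "counting_check_correct"):
            row[col] = _fmt_bool(value)
        elif col == "honeypot_answered":
            row[col] = "true" if value else "false"
        elif col == "duration_minutes":
            row[col] = repr(float(value)) if value is not None else ""
        elif value is None:
            row[col] = ""
        else:
            row[col] = str(value)
    for qid in sorted(record.open_text):
        row[_TEXT_PREFIX + qid] = record.open_text[qid]
    return row


def _row_to_record(row: pd.Series, text_columns: Sequence[str],
                   fictitious_drug: str) -> RespondentRecord:
    rid = row["record_id"]
    where = f"record {rid!r}"

    def cell(col: str) -> Optional[str]:
        if col not in row.index:
            return None
        raw = row[col]
        return None if raw == "" else raw

    submitted = cell("submitted_at")
    if submitted is None:
        raise SchemaError(f"{where}: submitted_at is mandatory")
    duration = cell("duration_minutes")
    if duration is None:
        raise SchemaError(f"{where}: duration_minutes is mandatory")

    open_text = {}
    for col in text_columns:
        value = row[col]
        if value != "":
            open_text[col[len(_TEXT_PREFIX):]] = value

    def intcell(col: str) -> Optional[int]:
        raw = cell(col)
        return None if raw is None else int(raw)

    return RespondentRecord(
        record_id=rid,
        submitted_at=datetime.fromisoformat(submitted),
        duration_minutes=float(duration),
        ip_address=cell("ip_address"),
        ip_country=cell("ip_country"),
        email=cell("email"),
        age_years=intcell("age_years"),
        gender=cell("gender"),
        race_ethnicity=cell("race_ethnicity"),
        sexual_orientation=cell("sexual_orientation"),
        education=cell("education"),
        income_bracket=cell("income_bracket"),
        insurance_status=cell("insurance_status"),
        insurance_type=cell("insurance_type"),
        lives_in_nyc=_parse_bool(row.get("lives_in_nyc", ""), where),
        works_in_nyc=_parse_bool(row.get("works_in_nyc", ""), where),
        home_borough=cell("home_borough"),
        work_borough=cell("work_borough"),
        home_zip=cell("home_zip"),
        work_zip=cell("work_zip"),
        homelessness_status=cell("homelessness_status"),
        substance_use=_parse_substances(row.get("substance_use", ""), where,
                                        fictitious_drug),
        lifetime_overdoses=intcell("lifetime_overdoses"),
        open_text=open_text,
        honeypot_answered=_parse_bool(row.get("honeypot_answered", ""), where)
        or False,
        counting_check_correct=_parse_bool(row.get("counting_check_correct", ""),
                                           where),
        referral_source=cell("referral_source"),
    )


def _read_string_frame(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False,
                            encoding="utf-8")
    except ParserError as exc:
        raise SchemaError(f"malformed CSV {path}: {exc}") from exc
    return frame


def load_records(path, fictitious_drug: str = DEFAULT_FICTITIOUS_DRUG
                 ) -> list[RespondentRecord]:
    """Read a flat submission export, preserving row order.

    Raises :class:`SchemaError` on a missing mandatory column, malformed CSV,
    or duplicate record_id (duplicate IDs are a file defect — distinct from
    duplicate IPs/emails, which are data the filters act on).
    """
    frame = _read_string_frame(path)
    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    dupes = frame["record_id"][frame["record_id"].duplicated()]
    if not dupes.empty:
        raise SchemaError(f"{path}: duplicate record_id {dupes.iloc[0]!r}")
    text_columns = [c for c in frame.columns if c.startswith(_TEXT_PREFIX)]
    return [
        _row_to_record(row, text_columns, fictitious_drug)
        for _, row in frame.iterrows()
    ]


def write_records(records: Sequence[RespondentRecord], path) -> None:
    """Write records as RFC-4180 UTF-8 CSV (empty cell = missing)."""
    rows = [record_to_row(r) for r in records]
    text_cols = sorted({c for row in rows for c in row if c.startswith(_TEXT_PREFIX)})
    columns = list(_SCALAR_COLUMNS) + text_cols
    frame = pd.DataFrame(
        [{c: row.get(c, "") for c in columns} for row in rows], columns=columns
    )
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


_LABEL_COLUMNS = ("record_id", "is_legitimate", "injected_violations", "cluster_id")


def write_labels(labels: Sequence[GroundTruthLabel], path) -> None:
    rows = []
    for lab in labels:
        rows.append({
            "record_id": lab.record_id,
            "is_legitimate": "true" if lab.is_legitimate else "false",
            "injected_violations": ";".join(
                sorted(c.name for c in lab.injected_violations)
            ),
            "cluster_id": "" if lab.cluster_id is None else str(lab.cluster_id),
        })
    frame = pd.DataFrame(rows, columns=_LABEL_COLUMNS)
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def load_labels(path) -> list[GroundTruthLabel]:
    frame = _read_string_frame(path)
    missing = [c for c in _LABEL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    labels = []
    for _, row in frame.iterrows():
        violations = frozenset(
            ViolationCategory[name]
            for name in row["injected_violations"].split(";")
            if name
        )
        labels.append(GroundTruthLabel(
            record_id=row["record_id"],
            is_legitimate=_parse_bool(row["is_legitimate"],
                                      f"label {row['record_id']!r}"),
            injected_violations=violations,
            cluster_id=None if row["cluster_id"] == "" else int(row["cluster_id"]),
        ))
    return labels
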