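"""Cleaning configuration: thresholds, filter order, DBSCAN parameters,
lookup-table paths, and packaged resource loaders."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import pandas as pd
import yaml

from .records import BOROUGHS, DEFAULT_FICTITIOUS_DRUG, ConfigurationError

#: Household income brackets in ascending order, as the survey offers them.
INCOME_BRACKETS = (
    "$0-29,999",
    "$30,000-39,999",
    "$40,000-49,999",
    "$50,000-59,999",
    "$60,000-74,999",
    "$75,000-99,999",
    "$100,000 or more",
    "Don't know",
)

#: Brackets treated as above Medicaid eligibility (>= US $50,000).
#: "Don't know" is never treated as above the cutoff.
DEFAULT_MEDICAID_FLAGGED_BRACKETS = (
    "$50,000-59,999",
    "$60,000-74,999",
    "$75,000-99,999",
    "$100,000 or more",
)

DEFAULT_DBSCAN_FEATURES = (
    "gender",
    "race_ethnicity",
    "age_years",
    "income_bracket",
    "education",
    "substance_use",
)

#: Cascade stage names in narrated protocol order. The ZIP stage emits two
#: categories (invalid ZIP, ZIP/borough mismatch).
DEFAULT_STAGE_ORDER = (
    "foreign_ip",
    "duplicates",
    "fictitious_drug",
    "zip",
    "improbable_use",
    "overdose_outlier",
    "clusters",
    "speeders",
    "demographic_inconsistency",
    "open_text",
    "email_pattern",
)


def _data_path(name: str):
    return resources.files("surveysweep").joinpath("data", name)


@dataclass
class CleaningConfig:
    """All tunables of the cleaning protocol.

    Defaults reproduce the published protocol: speeders below 7 minutes,
    overdose outliers above 10 lifetime overdoses, keep-first deduplication,
    a very narrow DBSCAN radius so only near-identical records co-cluster,
    and a minimum flagged cluster size of 6.
    """

    min_minutes: float = 7.0
    max_lifetime_overdoses: int = 10
    duplicate_policy: str = "keep-first"  # or "drop-all"
    medicaid_flagged_brackets: tuple = DEFAULT_MEDICAID_FLAGGED_BRACKETS
    fictitious_drug: str = DEFAULT_FICTITIOUS_DRUG
    min_duplicate_text_length: int = 12
    dbscan_eps: float = 0.5
    dbscan_min_samples: int = 2
    dbscan_features: tuple = DEFAULT_DBSCAN_FEATURES
    min_cluster_size: int = 6
    stage_order: tuple = DEFAULT_STAGE_ORDER
    zip_lookup_path: Optional[str] = None      # None -> packaged fixture
    phrase_list_path: Optional[str] = None
    impossible_pairs_path: Optional[str] = None
    chi_square_continuity_correction: bool = False
    seed: int = 0

    _zip_lookup: Optional[dict] = field(default=None, repr=False, compare=False)
    _phrases: Optional[tuple] = field(default=None, repr=False, compare=False)
    _pairs: Optional[frozenset] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.duplicate_policy not in ("keep-first", "drop-all"):
            raise ConfigurationError(
                f"unknown duplicate_policy {self.duplicate_policy!r}"
            )
        if self.dbscan_eps <= 0:
            raise ConfigurationError("dbscan_eps must be > 0")
        if self.dbscan_min_samples < 2:
            raise ConfigurationError("dbscan_min_samples must be >= 2")

    # -- packaged lookups ---------------------------------------------------

    def zip_lookup(self) -> dict:
        """ZIP -> borough map restricted to the five boroughs."""
        if self._zip_lookup is None:
            source = self.zip_lookup_path or _data_path("zip_borough.csv")
            frame = pd.read_csv(source, dtype=str)
            lookup = dict(zip(frame["zip"], frame["borough"]))
            bad = set(lookup.values()) - set(BOROUGHS)
            if bad:
                raise ConfigurationError(f"ZIP lookup names non-boroughs: {bad}")
            self._zip_lookup = lookup
        return self._zip_lookup

    def suspicious_phrases(self) -> tuple:
        if self._phrases is None:
            source = self.phrase_list_path or _data_path("suspicious_phrases.txt")
            with open(source, encoding="utf-8") as fh:
                self._phrases = tuple(
                    line.strip() for line in fh
                    if line.strip() and not line.startswith("#")
                )
        return self._phrases

    def impossible_pairs(self) -> frozenset:
        if self._pairs is None:
            source = self.impossible_pairs_path or _data_path("impossible_pairs.csv")
            frame = pd.read_csv(source, dtype=str)
            self._pairs = frozenset(
                zip(frame["substance"], frame["route"])
            )
        return self._pairs

    # -- YAML ---------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "CleaningConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        dbscan = raw.pop("dbscan", {})
        mapping = {
            "eps": "dbscan_eps",
            "min_samples": "dbscan_min_samples",
            "features": "dbscan_features",
            "min_cluster_size": "min_cluster_size",
        }
        for key, value in dbscan.items():
            if key not in mapping:
                raise ConfigurationError(f"unknown dbscan option {key!r}")
            raw[mapping[key]] = value
        for key in ("dbscan_features", "stage_order", "medicaid_flagged_brackets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config option(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = {
            "min_minutes": self.min_minutes,
            "max_lifetime_overdoses": self.max_lifetime_overdoses,
            "duplicate_policy": self.duplicate_policy,
            "medicaid_flagged_brackets": list(self.medicaid_flagged_brackets),
            "fictitious_drug": self.fictitious_drug,
            "min_duplicate_text_length": self.min_duplicate_text_length,
            "dbscan": {
                "eps": self.dbscan_eps,
                "min_samples": self.dbscan_min_samples,
                "features": list(self.dbscan_features),
                "min_cluster_size": self.min_cluster_size,
            },
            "stage_order": list(self.stage_order),
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    def with_(self, **kwargs) -> "CleaningConfig":
        """Return a copy with fields replaced (lookups re-resolved)."""
        return replace(self, _zip_lookup=None, _phrases=None, _pairs=None, **kwargs)


def default_cohort_spec_path():
    return _data_path("table2_default.yaml")


def default_recruitment_table_path():
    return _data_path("table1_default.csv")
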