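"""Click-farm detection: DBSCAN over near-identical response vectors.

Repeat submitters tend to resubmit the same answer set with trivial edits.
Encoding targeted demographics and the substance-use grid as one-hot /
min-max features and running DBSCAN with a very narrow radius (default
eps = 0.5 in the encoded space) groups records that are nearly identical:
exact duplicates sit at distance 0, while any single categorical
disagreement already costs sqrt(2) and cannot co-cluster. Clusters at or
above a minimum size (default 6) are treated as repeat-entry evidence and
all their members flagged; the per-cluster submission-time span is attached
as review detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .config import DEFAULT_DBSCAN_FEATURES, CleaningConfig
from .records import ROUTES, SUBSTANCES, RespondentRecord, ViolationCategory
from .filters import ViolationFlag

NOISE = -1

_NUMERIC_FEATURES = {"age_years", "lifetime_overdoses", "duration_minutes"}


@dataclass
class ClusterResult:
    """DBSCAN partition of the encoded, complete-case records."""

    labels: dict[str, int]                  # record_id -> cluster label (NOISE = -1)
    unclustered: list[str] = field(default_factory=list)  # dropped: incomplete
    spans_minutes: dict[int, float] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for label in self.labels.values():
            if label != NOISE:
                out[label] = out.get(label, 0) + 1
        return out


def encode_features(records: Sequence[RespondentRecord],
                    feature_list: Sequence[str] = DEFAULT_DBSCAN_FEATURES,
                    fictitious_drug: Optional[str] = None):
    """Encode records for clustering.

    Categorical fields are one-hot encoded, numeric fields min-max scaled to
    [0, 1], and the ``substance_use`` pseudo-field expands to one 0/1
    indicator per (substance, route) pair in the vocabulary. Records missing
    any listed feature are dropped (DBSCAN needs complete cases) and returned
    as unclustered.

    Returns ``(matrix, kept_ids, unclustered_ids)``.
    """
    if not feature_list:
        raise ValueError("feature_list must not be empty")

    kept, unclustered = [], []
    scalar_features = [f for f in feature_list if f != "substance_use"]
    for record in records:
        if any(getattr(record, f) is None for f in scalar_features):
            unclustered.append(record.record_id)
        else:
            kept.append(record)

    columns: list[np.ndarray] = []
    for feature in feature_list:
        if feature == "substance_use":
            substances = list(SUBSTANCES)
            if fictitious_drug is not None:
                substances.append(fictitious_drug)
            for substance in substances:
                for route in ROUTES:
                    pair = (substance, route)
                    columns.append(np.array(
                        [1.0 if pair in r.substance_use else 0.0 for r in kept]
                    ))
        elif feature in _NUMERIC_FEATURES:
            values = np.array([float(getattr(r, feature)) for r in kept])
            span = values.max() - values.min() if len(values) else 0.0
            columns.append((values - values.min()) / span if span > 0
                           else np.zeros_like(values))
        else:
            levels = sorted({getattr(r, feature) for r in kept})
            for level in levels:
                columns.append(np.array(
                    [1.0 if getattr(r, feature) == level else 0.0 for r in kept]
                ))
    matrix = (np.column_stack(columns) if kept
              else np.empty((0, max(len(columns), 1))))
    return matrix, [r.record_id for r in kept], unclustered


def find_clusters(matrix: np.ndarray, eps: float = 0.5, min_samples: int = 2,
                  ids: Optional[Sequence[str]] = None,
                  times: Optional[Sequence] = None) -> ClusterResult:
    """Run DBSCAN (Euclidean) on an encoded matrix.

    ``ids`` names the rows (defaults to stringified row indices); ``times``
    optionally provides submission timestamps used to compute per-cluster
    time spans.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    n = matrix.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    if n == 0:
        return ClusterResult(labels={})
    raw = DBSCAN(eps=eps, min_samples=min_samples, metric="euclidean").fit(matrix)
    labels = {rid: int(lab) for rid, lab in zip(ids, raw.labels_)}

    spans: dict[int, float] = {}
    if times is not None:
        by_cluster: dict[int, list] = {}
        for t, lab in zip(times, raw.labels_):
            if lab != NOISE:
                by_cluster.setdefault(int(lab), []).append(t)
        spans = {
            lab: (max(ts) - min(ts)).total_seconds() / 60.0
            for lab, ts in by_cluster.items()
        }
    return ClusterResult(labels=labels, spans_minutes=spans)


def flag_clusters(result: ClusterResult,
                  min_cluster_size: int = 6) -> list[ViolationFlag]:
    """Flag every member of every cluster of size >= ``min_cluster_size``."""
    sizes = result.sizes
    flags = []
    for rid, label in result.labels.items():
        if label == NOISE or sizes[label] < min_cluster_size:
            continue
        span = result.spans_minutes.get(label)
        detail = f"cluster {label} of {sizes[label]}"
        if span is not None:
            detail += f", submitted over {span:.1f} min"
        flags.append(ViolationFlag(rid, ViolationCategory.CLUSTER_DUPLICATE,
                                   detail))
    return flags


def cluster_records(records: Sequence[RespondentRecord],
                    config: Optional[CleaningConfig] = None
                    ) -> tuple[ClusterResult, list[ViolationFlag]]:
    """Convenience: encode, cluster, and flag in one call."""
    config = config or CleaningConfig()
    matrix, kept_ids, unclustered = encode_features(
        records, config.dbscan_features, config.fictitious_drug
    )
    times_by_id = {r.record_id: r.submitted_at for r in records}
    result = find_clusters(
        matrix, eps=config.dbscan_eps, min_samples=config.dbscan_min_samples,
        ids=kept_ids, times=[times_by_id[rid] for rid in kept_ids],
    )
    result.unclustered = unclustered
    return result, flag_clusters(result, config.min_cluster_size)
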