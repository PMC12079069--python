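"""Generator contracts: exact tally injection, overlap assignment,
determinism, and per-category detectability of injected violations."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surveysweep import (
    CleaningConfig,
    CohortSpec,
    ConfigurationError,
    ViolationCategory,
    assign_overlaps,
    generate_cohort,
    inject_violation,
    run_cascade,
    write_records,
)
from surveysweep.cohort import INVALID_ZIPS, fingerprint
from surveysweep.filters import (
    flag_fictitious_drug,
    flag_overdose_outlier,
    flag_zip,
)
from tests.conftest import SMALL_SPEC

V = ViolationCategory
CONFIG = CleaningConfig()


# -- overlap assignment ------------------------------------------------------

def test_overlap_multiplicities_exact_small_instance():
    rng = np.random.default_rng(0)
    sets = assign_overlaps(3, {"A": 3, "B": 2}, rng)
    assert all(sets), "no record may carry an empty violation set"
    assert sum("A" in s for s in sets) == 3
    assert sum("B" in s for s in sets) == 2


def test_overlap_underfull_tallies_rejected():
    with pytest.raises(ConfigurationError):
        assign_overlaps(2, {"A": 1}, np.random.default_rng(0))


def test_overlap_single_record_gets_both():
    (only,) = assign_overlaps(1, {"A": 1, "B": 1}, np.random.default_rng(0))
    assert only == {"A", "B"}


def test_overlap_oversized_tally_names_category():
    with pytest.raises(ConfigurationError, match="A"):
        assign_overlaps(3, {"A": 4, "B": 3}, np.random.default_rng(0))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    n=st.integers(1, 30),
    data=st.data(),
)
def test_overlap_assignment_properties(n, data):
    k = data.draw(st.integers(1, 5))
    cats = [f"C{i}" for i in range(k)]
    tallies = {c: data.draw(st.integers(0, n), label=c) for c in cats}
    feasible = sum(tallies.values()) >= n
    rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
    incompatible = [frozenset({"C0", "C1"})] if k >= 2 else []
    if not feasible:
        with pytest.raises(ConfigurationError):
            assign_overlaps(n, tallies, rng, incompatible=incompatible)
        return
    try:
        sets = assign_overlaps(n, tallies, rng, incompatible=incompatible)
    except ConfigurationError:
        # incompatibility can make an otherwise-feasible instance unplaceable
        return
    assert len(sets) == n and all(sets)
    for cat, tally in tallies.items():
        assert sum(cat in s for s in sets) == tally
    assert not any({"C0", "C1"} <= s for s in sets)


# -- single-record injections -----------------------------------------------

def test_fictitious_injection_fires_its_filter(make_record):
    record = inject_violation(make_record(), V.FICTITIOUS_DRUG,
                              np.random.default_rng(0), config=CONFIG)
    assert flag_fictitious_drug([record], CONFIG.fictitious_drug)


def test_overdose_injection_range_and_extreme(make_record):
    values = {
        inject_violation(make_record(), V.OVERDOSE_OUTLIER,
                         np.random.default_rng(seed)).lifetime_overdoses
        for seed in range(300)
    }
    assert min(values) >= 11 and max(values) <= 105
    assert 105 in values, "the documented extreme draw must be reachable"
    record = make_record(lifetime_overdoses=max(values))
    assert flag_overdose_outlier([record])


def test_invalid_zip_injection_defaults_to_retired_zip(make_record):
    zips = {
        inject_violation(make_record(), V.INVALID_ZIP,
                         np.random.default_rng(seed)).home_zip
        for seed in range(20)
    }
    assert zips <= set(INVALID_ZIPS)
    assert "10048" in zips
    record = inject_violation(make_record(), V.INVALID_ZIP,
                              np.random.default_rng(1))
    flags = flag_zip([record], CONFIG.zip_lookup())
    assert [f.category for f in flags] == [V.INVALID_ZIP]


def test_unknown_category_rejected(make_record):
    with pytest.raises(ValueError):
        inject_violation(make_record(), "not-a-category",
                         np.random.default_rng(0))


# -- cohort generation -------------------------------------------------------

def test_degenerate_all_legitimate_spec():
    spec = CohortSpec(n_total=50, n_legitimate=50, category_tallies={},
                      cluster_sizes=(), seed=11)
    records, labels = generate_cohort(spec)
    assert len(records) == 50
    assert all(lab.is_legitimate for lab in labels)
    report = run_cascade(records)
    assert report.excluded == {} and len(report.included_ids) == 50


def test_small_cohort_label_tallies_match_spec(small_cohort):
    _, labels = small_cohort
    for cat, tally in SMALL_SPEC.category_tallies.items():
        count = sum(cat in lab.injected_violations for lab in labels)
        assert count == tally, cat
    assert sum(lab.is_legitimate for lab in labels) == SMALL_SPEC.n_legitimate


def test_cluster_members_share_all_clustering_features(small_cohort):
    records, labels = small_cohort
    by_id = {r.record_id: r for r in records}
    clusters = {}
    for lab in labels:
        if lab.cluster_id is not None:
            clusters.setdefault(lab.cluster_id, []).append(by_id[lab.record_id])
    assert sorted(len(m) for m in clusters.values()) == sorted(
        SMALL_SPEC.cluster_sizes)
    for members in clusters.values():
        prints = {fingerprint(r) for r in members}
        ages = {r.age_years for r in members}
        assert len(prints) == 1 and len(ages) == 1


def test_same_seed_gives_byte_identical_csv():
    buffers = []
    for _ in range(2):
        records, _ = generate_cohort(SMALL_SPEC)
        buf = io.StringIO()
        write_records(records, buf)
        buffers.append(buf.getvalue())
    assert buffers[0] == buffers[1]


def test_different_seed_changes_output():
    import dataclasses

    other = dataclasses.replace(SMALL_SPEC, seed=SMALL_SPEC.seed + 1)
    a, _ = generate_cohort(SMALL_SPEC)
    b, _ = generate_cohort(other)
    assert a != b


def test_infeasible_spec_names_category():
    spec = CohortSpec(n_total=100, n_legitimate=90,
                      category_tallies={V.FICTITIOUS_DRUG: 50},
                      cluster_sizes=(), seed=1)
    with pytest.raises(ConfigurationError, match="FICTITIOUS_DRUG"):
        generate_cohort(spec)


def test_cluster_sizes_must_sum_to_tally():
    spec = CohortSpec(n_total=100, n_legitimate=10,
                      category_tallies={V.CLUSTER_DUPLICATE: 20,
                                        V.FICTITIOUS_DRUG: 70},
                      cluster_sizes=(6, 6), seed=1)
    with pytest.raises(ConfigurationError, match="cluster_sizes"):
        generate_cohort(spec)


def test_packaged_spec_yaml_matches_code_defaults():
    assert CohortSpec.from_yaml() == CohortSpec()


def test_cascade_recovers_labels_perfectly_on_small_cohort(small_cohort):
    records, labels = small_cohort
    report = run_cascade(records)
    fraudulent = {lab.record_id for lab in labels if not lab.is_legitimate}
    assert set(report.excluded) == fraudulent
    for cat, tally in SMALL_SPEC.category_tallies.items():
        assert report.category_counts[cat] == tally, cat
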