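"""Unit behavior of every rule filter, including boundary pins and the
missing-data-never-flags convention."""

from datetime import datetime, timedelta

import pytest

from surveysweep import (
    CleaningConfig,
    ViolationCategory,
    flag_demographic_inconsistency,
    flag_duplicates,
    flag_email_pattern,
    flag_fictitious_drug,
    flag_foreign_ip,
    flag_honeypot,
    flag_improbable_use,
    flag_open_text,
    flag_overdose_outlier,
    flag_speeders,
    flag_zip,
)

V = ViolationCategory
CONFIG = CleaningConfig()


def ids(flags):
    return sorted(f.record_id for f in flags)


# -- foreign IP -------------------------------------------------------------

@pytest.mark.parametrize("country,flagged", [
    ("GB", True), ("NG", True), ("US", False), ("CA", False), (None, False),
])
def test_foreign_ip_rule(make_record, country, flagged):
    record = make_record(ip_address="66.1.2.3", ip_country=country)
    assert bool(flag_foreign_ip([record])) is flagged


def test_malformed_ip_flagged_unresolvable(make_record):
    (flag,) = flag_foreign_ip([make_record(ip_address="999.1.1.1",
                                           ip_country="US")])
    assert flag.category is V.FOREIGN_IP and flag.detail == "unresolvable"


# -- duplicates -------------------------------------------------------------

def test_keep_first_flags_only_later_ip_sharer(make_record):
    t0 = datetime(2023, 9, 1, 12, 0, 0)
    early = make_record("R1", ip_address="66.0.0.1", submitted_at=t0,
                        email="a1@example.com")
    late = make_record("R2", ip_address="66.0.0.1",
                       submitted_at=t0 + timedelta(hours=1),
                       email="b2@example.com")
    assert ids(flag_duplicates([late, early], "keep-first")) == ["R2"]


def test_drop_all_flags_every_email_sharer(make_record):
    records = [make_record(f"R{i}", email="shared@example.com")
               for i in range(3)]
    assert ids(flag_duplicates(records, "drop-all")) == ["R0", "R1", "R2"]


def test_missing_emails_never_form_a_group(make_record):
    records = [make_record(f"R{i}", email=None) for i in range(3)]
    assert flag_duplicates(records) == []


# -- fictitious drug --------------------------------------------------------

def test_fictitious_drug_endorsement_flags(make_record):
    record = make_record(
        substance_use={("heroin", "inject"), ("cebranopadol-X", "oral")})
    (flag,) = flag_fictitious_drug([record], "cebranopadol-X")
    assert flag.category is V.FICTITIOUS_DRUG


def test_empty_substance_grid_not_flagged(make_record):
    assert flag_fictitious_drug([make_record(substance_use=set())]) == []


# -- ZIP validation ---------------------------------------------------------

def test_retired_zip_is_invalid(make_record):
    record = make_record(home_borough="Brooklyn", home_zip="10048")
    (flag,) = flag_zip([record], CONFIG.zip_lookup())
    assert flag.category is V.INVALID_ZIP


def test_wrong_borough_zip_is_mismatch(make_record):
    record = make_record(home_borough="Brooklyn", home_zip="10001")  # Manhattan
    (flag,) = flag_zip([record], CONFIG.zip_lookup())
    assert flag.category is V.ZIP_BOROUGH_MISMATCH


def test_homeless_exempt_from_home_zip_flags(make_record):
    lookup = CONFIG.zip_lookup()
    missing = make_record(homelessness_status="Currently homeless",
                          home_zip=None)
    invalid = make_record(homelessness_status="Currently homeless",
                          home_borough="Queens", home_zip="10048")
    assert flag_zip([missing, invalid], lookup) == []


def test_outside_nyc_borough_skips_zip_check(make_record):
    record = make_record(home_borough="Outside NYC", home_zip="14201")
    assert flag_zip([record], CONFIG.zip_lookup()) == []


def test_work_side_checked_only_when_working(make_record):
    working = make_record("R1", works_in_nyc=True, work_borough="Bronx",
                          work_zip="11201")  # Brooklyn ZIP
    idle = make_record("R2", works_in_nyc=False, work_borough="Bronx",
                       work_zip="11201")
    flags = flag_zip([working, idle], CONFIG.zip_lookup())
    assert ids(flags) == ["R1"]
    assert flags[0].category is V.ZIP_BOROUGH_MISMATCH


# -- improbable use ---------------------------------------------------------

@pytest.mark.parametrize("pair,flagged", [
    (("alcohol", "inject"), True),
    (("inhalants", "inject"), True),
    (("marijuana", "inject"), True),
    (("heroin", "inject"), False),
    (("alcohol", "oral"), False),
])
def test_impossible_route_rule(make_record, pair, flagged):
    record = make_record(substance_use={pair})
    assert bool(flag_improbable_use([record], CONFIG.impossible_pairs())) is flagged


# -- overdose outliers / speeders: strict boundaries ------------------------

@pytest.mark.parametrize("count,flagged", [(10, False), (11, True),
                                           (105, True), (0, False)])
def test_overdose_strictly_more_than_ten(make_record, count, flagged):
    record = make_record(lifetime_overdoses=count)
    assert bool(flag_overdose_outlier([record], 10)) is flagged


@pytest.mark.parametrize("minutes,flagged", [(6.98, True), (6.99, True),
                                             (7.0, False), (45.0, False)])
def test_speeder_strictly_under_seven_minutes(make_record, minutes, flagged):
    record = make_record(duration_minutes=minutes)
    assert bool(flag_speeders([record], 7.0)) is flagged


# -- demographic inconsistency ----------------------------------------------

@pytest.mark.parametrize("insurance,income,flagged", [
    ("Medicaid", "$100,000 or more", True),
    ("Medicaid", "$50,000-59,999", True),
    ("Medicaid", "$0-29,999", False),
    ("Medicaid", "Don't know", False),
    (None, "$100,000 or more", False),
    ("Private", "$100,000 or more", False),
])
def test_medicaid_income_rule(make_record, insurance, income, flagged):
    record = make_record(insurance_type=insurance, income_bracket=income,
                         insurance_status="Yes" if insurance else "No")
    assert bool(flag_demographic_inconsistency([record])) is flagged


# -- open text ---------------------------------------------------------------

def test_blocklisted_phrase_flags_after_normalization(make_record):
    record = make_record(open_text={"services": "  A MAGAZINE gauidiance!! "})
    (flag,) = flag_open_text([record], CONFIG.suspicious_phrases())
    assert flag.category is V.SUSPICIOUS_OPEN_TEXT


def test_cross_record_duplicate_answer_flags_both(make_record):
    records = [
        make_record("R1", open_text={"services": "General body check up"}),
        make_record("R2", open_text={"services": "general body CHECK up."}),
    ]
    assert ids(flag_open_text(records, [])) == ["R1", "R2"]


def test_short_duplicate_answers_tolerated(make_record):
    records = [make_record(f"R{i}", open_text={"services": "yes"})
               for i in range(2)]
    assert flag_open_text(records, CONFIG.suspicious_phrases()) == []


def test_unique_substantive_answer_not_flagged(make_record):
    record = make_record(
        open_text={"services": "They swapped my needles and gave me naloxone"})
    assert flag_open_text([record], CONFIG.suspicious_phrases()) == []


# -- email pattern -----------------------------------------------------------

@pytest.mark.parametrize("email,flagged", [
    ("qzkvjxb59214@example.com", True),
    ("abcde12345@example.com", True),
    ("jane.doe1984@example.com", False),   # dot breaks letters-only
    ("janedoe1984@example.com", False),    # only 4 digits
    ("12345abc@example.com", False),
    (None, False),
])
def test_bot_email_pattern(make_record, email, flagged):
    record = make_record(email=email)
    assert bool(flag_email_pattern([record])) is flagged


# -- honeypot ----------------------------------------------------------------

def test_honeypot_answer_is_bot_evidence(make_record):
    answered = make_record("R1", honeypot_answered=True)
    silent = make_record("R2", honeypot_answered=False)
    assert ids(flag_honeypot([answered, silent])) == ["R1"]


# -- shared properties -------------------------------------------------------

def test_filters_are_idempotent(small_cohort):
    records, _ = small_cohort
    filters = [
        lambda r: flag_foreign_ip(r),
        lambda r: flag_duplicates(r),
        lambda r: flag_fictitious_drug(r),
        lambda r: flag_zip(r, CONFIG.zip_lookup()),
        lambda r: flag_improbable_use(r, CONFIG.impossible_pairs()),
        lambda r: flag_overdose_outlier(r),
        lambda r: flag_speeders(r),
        lambda r: flag_demographic_inconsistency(r),
        lambda r: flag_open_text(r, CONFIG.suspicious_phrases()),
        lambda r: flag_email_pattern(r),
    ]
    for fn in filters:
        assert fn(records) == fn(records)


def test_filters_ignore_unrelated_fields(small_cohort):
    """Metamorphic: permuting a field a filter does not read leaves its
    flags unchanged."""
    import dataclasses

    records, _ = small_cohort
    before = flag_speeders(records)
    rotated = [dataclasses.replace(r, referral_source=other.referral_source,
                                   open_text=dict(other.open_text))
               for r, other in zip(records, records[::-1])]
    assert flag_speeders(rotated) == before
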