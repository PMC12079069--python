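"""Shared fixtures: a record factory plus session-scoped synthetic cohorts."""

from datetime import datetime

import pytest

from surveysweep import (
    CleaningConfig,
    CohortSpec,
    RespondentRecord,
    ViolationCategory,
    generate_cohort,
    run_cascade,
)

V = ViolationCategory


@pytest.fixture
def make_record():
    """Factory for a minimal clean record; override fields per test.

    IP and email default to missing so unrelated records never form
    duplicate groups by accident.
    """

    def factory(rid="R1", **kwargs):
        defaults = dict(
            record_id=rid,
            submitted_at=datetime(2023, 9, 1, 12, 0, 0),
            duration_minutes=20.0,
            ip_address=None,
            ip_country=None,
            email=None,
            age_years=30,
            gender="Man",
            race_ethnicity="Non-Hispanic White",
            sexual_orientation="Heterosexual",
            education="4-year college degree",
            income_bracket="$0-29,999",
            insurance_status="No",
            insurance_type=None,
            lives_in_nyc=True,
            works_in_nyc=False,
            home_borough="Brooklyn",
            work_borough=None,
            home_zip="11201",
            work_zip=None,
            homelessness_status="Stably housed, no past homelessness",
            substance_use=frozenset({("heroin", "inject")}),
            lifetime_overdoses=1,
            open_text={},
            honeypot_answered=False,
            counting_check_correct=True,
            referral_source="Meta",
        )
        defaults.update(kwargs)
        return RespondentRecord(**defaults)

    return factory


SMALL_SPEC = CohortSpec(
    n_total=160,
    n_legitimate=40,
    category_tallies={
        V.FOREIGN_IP: 20,
        V.DUPLICATE_IP_EMAIL: 25,
        V.FICTITIOUS_DRUG: 60,
        V.INVALID_ZIP: 18,
        V.ZIP_BOROUGH_MISMATCH: 8,
        V.IMPROBABLE_USE: 15,
        V.OVERDOSE_OUTLIER: 14,
        V.CLUSTER_DUPLICATE: 13,
        V.SPEEDER: 9,
        V.DEMOGRAPHIC_INCONSISTENCY: 5,
        V.SUSPICIOUS_OPEN_TEXT: 10,
        V.EMAIL_PATTERN: 3,
    },
    cluster_sizes=(7, 6),
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 160-record cohort exercising every violation category."""
    return generate_cohort(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged default study conditions (2560 records, 173 legitimate)."""
    return generate_cohort()


@pytest.fixture(scope="session")
def default_report(default_cohort):
    records, _ = default_cohort
    return run_cascade(records, CleaningConfig(), mode="marginal")
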