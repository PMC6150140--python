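from datetime import date

import pytest

from neoaudit import (AdmissionRecord, CohortParams, load_schema,
                      simulate_cohort)


@pytest.fixture(scope="session")
def revised_schema():
    return load_schema("revised2014")


@pytest.fixture(scope="session")
def baseline_schema():
    return load_schema("baseline")


@pytest.fixture
def make_record():
    """Factory for admission records with sensible structural defaults."""

    counter = {"n": 0}

    def _make(values=None, schema_version="revised2014", **kwargs):
        counter["n"] += 1
        defaults = dict(
            record_id=f"T{counter['n']:04d}",
            admission_date=date(2015, 3, 10),
            date_of_birth=date(2015, 3, 10),
            schema_version=schema_version,
            outcome="alive",
            values=dict(values or {}),
        )
        defaults.update(kwargs)
        return AdmissionRecord(**defaults)

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic mid-sized synthetic cohort shared across tests."""
    params = CohortParams(admissions_per_month=25, seed=11)
    return simulate_cohort(params)
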