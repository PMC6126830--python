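import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pscox import SimulationConfig, simulate_cohort, simulate_population

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_persons=4000)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_population(small_config, seed=11)


@pytest.fixture(scope="session")
def medium_cohorts():
    """Analysis-ready (main, validation) tables at n = 20,000."""
    cfg = SimulationConfig(n_persons=20_000)
    return simulate_cohort(cfg, seed=7)


def person(pid, birth_year=1932, sex="M", enroll_end=pd.NaT):
    return {"person_id": pid, "sex": sex, "birth_year": birth_year, "enroll_end": enroll_end}


def dx(pid, date, code):
    return {"person_id": pid, "date": pd.Timestamp(date), "icd9_code": code}


def rx(pid, date, drug_class, days=30):
    return {
        "person_id": pid,
        "date": pd.Timestamp(date),
        "drug_class": drug_class,
        "days_supplied": days,
    }


@pytest.fixture
def hand_bundle_factory():
    """Build a tiny ClaimsBundle from row dictionaries."""
    from pscox import ClaimsBundle

    def build(persons, diagnoses, prescriptions):
        return ClaimsBundle(
            persons=pd.DataFrame(persons),
            diagnosis_claims=pd.DataFrame(
                diagnoses,
                columns=["person_id", "date", "icd9_code"],
            ),
            prescription_claims=pd.DataFrame(
                prescriptions,
                columns=["person_id", "date", "drug_class", "days_supplied"],
            ),
            hidden_truth=pd.DataFrame({"person_id": [p["person_id"] for p in persons]}),
        )

    return build
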