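import numpy as np
import pandas as pd
import pytest

from fbctrend import default_config, fit_joint_pipeline, prepare_cohort, simulate_cohort
from fbctrend.cohort_prep import PreparedCohort


@pytest.fixture(scope="session")
def male_cohort():
    """Inflated-event male cohort shared across the suite."""
    cfg = default_config("male", 4000, seed=11, event_rate_multiplier=10)
    cohort = simulate_cohort(cfg)
    prepared = prepare_cohort(cohort.patients, cohort.measurements)
    return cohort, prepared


@pytest.fixture(scope="session")
def fitted_bundle(male_cohort):
    _, prepared = male_cohort
    return fit_joint_pipeline(prepared)


def make_prepared(patients: pd.DataFrame, measurements: pd.DataFrame) -> PreparedCohort:
    """Hand-built prepared cohorts for unit tests (no date plumbing)."""
    return PreparedCohort(patients=patients, measurements=measurements, flow={})


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
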