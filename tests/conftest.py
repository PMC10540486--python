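import numpy as np
import pytest

from ste_trials import build_interim_snapshot
from ste_trials.datasets import (
    EXAMPLE_INTERIM_TIME,
    EXAMPLE_SCHEDULE,
    example_design,
    example_patients,
)
from ste_trials.trial_core import AssessmentSchedule, PatientRecord


@pytest.fixture
def schedule():
    return AssessmentSchedule(k_star=4, spacing=3.0)


@pytest.fixture
def example_snapshot():
    """Interim snapshot of the bundled 18-patient worked example."""
    return build_interim_snapshot(
        example_patients(), EXAMPLE_SCHEDULE, EXAMPLE_INTERIM_TIME, n_total=38
    )


@pytest.fixture
def scenario1_design():
    return example_design()


def random_patients(rng: np.random.Generator, n: int, horizon: float = 30.0):
    """Random follow-up data for property tests: uniform recruitment,
    exponential event times, a fraction event-free."""
    patients = []
    for _ in range(n):
        recruit = float(rng.uniform(0.0, horizon))
        event = float(rng.exponential(8.0)) + 1e-6 if rng.uniform() < 0.8 else None
        patients.append(PatientRecord(recruit_time=recruit, event_time=event))
    return patients
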