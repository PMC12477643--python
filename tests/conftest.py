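import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heatbalance.calorimetry import SubjectProfile
from heatbalance.protocol import RampSchedule
from heatbalance.synthetic import TrueTrialParams, simulate_trial

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def subject() -> SubjectProfile:
    return SubjectProfile(height_m=1.7, mass_kg=75.0, age=25, sex="F", subject_id="Y001")


@pytest.fixture
def humidity_ramp() -> RampSchedule:
    """P_crit schedule: dry-bulb held at 38 degC, vapor pressure ramps from 16 mmHg."""
    return RampSchedule(mode="P_crit", held_value=38.0, start_value=16.0)


@pytest.fixture
def noiseless_truth() -> TrueTrialParams:
    return TrueTrialParams(
        true_critical_step=10,
        post_slope=0.6,
        noise_sd=0.0,
        skin_noise_sd=0.0,
        vo2_cv=0.0,
    )


@pytest.fixture
def noiseless_trial(subject, humidity_ramp, noiseless_truth):
    """One fully deterministic trial plus its generating ground truth."""
    return simulate_trial(
        subject, humidity_ramp, noiseless_truth, rng=np.random.default_rng(7),
        activity="MinAct",
    )
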