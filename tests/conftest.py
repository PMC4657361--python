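import numpy as np
import pytest

from gaitdisp import TrialConfig, generate_trial
from gaitdisp.pipeline import Trial


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free, sway-free, fixed-period trial: every stage should be exact."""
    return generate_trial(
        TrialConfig(speed_kmh=3, seed=7, duration_s=60.0, accel_noise_sd=0.0,
                    gyro_noise_sd=0.0, gyro_bias=0.0, slow_sway_mm=0.0,
                    stride_time_cv=0.0)
    )


@pytest.fixture(scope="session")
def default_trial():
    """One-minute trial at 5 km/h with default sensor noise."""
    return generate_trial(TrialConfig(speed_kmh=5, seed=3, duration_s=60.0))


@pytest.fixture(scope="session")
def default_trial_inputs(default_trial):
    return Trial.from_synthetic(default_trial)


@pytest.fixture(scope="session")
def clean_trial_inputs(clean_trial):
    return Trial.from_synthetic(clean_trial)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
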