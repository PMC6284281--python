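import numpy as np
import pytest

from maizephen import RateParams, SimulationConfig, generate_trials


@pytest.fixture
def ve201_params():
    # published Briere-1 estimates for variety VE 201
    return RateParams(a=0.0003, tb=8.9826, tm=40.1123)


@pytest.fixture
def ve220_params():
    # published Briere-2 estimates for variety VE 220
    return RateParams(a=0.00004, tb=10.0339, tm=40.4344, mu=1.0307)


RECOVERY_TEMPS = tuple(np.linspace(12.0, 36.0, 12).tolist())
RECOVERY_TRUTH = (2e-5, 9.0, 40.0)


@pytest.fixture
def zero_noise_obs():
    """Noise-free briere1 observations with exact (unrounded) durations."""
    obs, _ = generate_trials(SimulationConfig(
        true_params=RECOVERY_TRUTH, site_temperatures=RECOVERY_TEMPS,
        noise_sd_rate=0.0, seed=0, round_durations=False,
    ))
    return obs


def brute_force_duration(rates, threshold=1.0):
    """Independent day-loop oracle for the accumulation engine."""
    D = 0.0
    for i, r in enumerate(rates):
        if D + r >= threshold:
            return i + (threshold - D) / r
        D += r
    raise AssertionError("phase did not complete in oracle")
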