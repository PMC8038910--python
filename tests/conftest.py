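import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tmpulse import ManeuverSchedule, SimulationConfig, simulate_recording

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def single_state_config(
    state: str = "upright_baseline", duration: float = 60.0, **overrides
) -> SimulationConfig:
    """One-segment simulation config, convenient for focused tests."""
    base = dict(schedule=ManeuverSchedule.single(state, duration), seed=0)
    base.update(overrides)
    return SimulationConfig(**base)


def quiet_config(state: str = "upright_baseline", duration: float = 60.0, **overrides):
    """Noise-free, drift-free config: the generator's deterministic skeleton."""
    return single_state_config(
        state,
        duration,
        noise_sd=0.0,
        respiratory_drift=(0.25, 0.0),
        cycle_jitter_cv=overrides.pop("cycle_jitter_cv", 0.0),
        heart_rate_subject_sd=0.0,
        heart_rate_mean=overrides.pop("heart_rate_mean", 60.0),
        **overrides,
    )


@pytest.fixture()
def quiet_minute_trace():
    """60 s noise-free baseline at exactly 60 bpm, with its ground truth."""
    config = quiet_config()
    return simulate_recording(config)


@pytest.fixture()
def noisy_two_minutes():
    """120 s baseline at 70 bpm with default jitter, noise and drift."""
    config = single_state_config("upright_baseline", 120.0, heart_rate_mean=70.0)
    rng = np.random.default_rng(7)
    return simulate_recording(config, rng=rng, heart_rate=70.0)
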