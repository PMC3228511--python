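import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lvpress import SimConfig, simulate

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


def clean_config(**overrides) -> SimConfig:
    """Noise-free, jitter-free, drift-free baseline simulation config."""
    base = dict(duration_s=20.0, rr_cv=0.0, noise_sd_mmHg=0.0,
                drift_amplitude_mmHg=0.0, seed=0)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def clean_recording():
    """20 s of noise-free baseline: exactly 80 beats at 240 bpm."""
    return simulate(clean_config())


@pytest.fixture(scope="session")
def noisy_recording():
    """60 s with 1 mmHg sensor noise and mild RR jitter."""
    return simulate(SimConfig(duration_s=60.0, rr_cv=0.02, noise_sd_mmHg=1.0,
                              drift_amplitude_mmHg=0.0, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
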