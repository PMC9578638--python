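import numpy as np
import pytest

from sit2stand import SimulationConfig, simulate_trial


@pytest.fixture(scope="session")
def clean_trial():
    """One noise-free simulated trial (sensor noise off; truth-level wobble on)."""
    cfg = SimulationConfig(seed=7, n_cycles=3, accel_noise_sd=0.0, gyro_noise_sd=0.0)
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    """One trial with the default sensor-noise levels."""
    cfg = SimulationConfig(seed=7, n_cycles=3)
    return simulate_trial(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
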