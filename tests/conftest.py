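import numpy as np
import pytest

from imcdenoise.simulate import SimulationConfig, simulate_triplet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_triplet():
    """128x128 blob scene with 1% single hot pixels (session-cached)."""
    cfg = SimulationConfig(shape=(128, 128), lambda_fg=20.0, lambda_bg=1.0,
                           hot_pixel_density=0.01, seed=3)
    return simulate_triplet(cfg)


@pytest.fixture(scope="session")
def clean_triplet():
    """128x128 blob scene with shot noise only (session-cached)."""
    cfg = SimulationConfig(shape=(128, 128), lambda_fg=20.0, lambda_bg=1.0,
                           hot_pixel_density=0.0, seed=11)
    return simulate_triplet(cfg)
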