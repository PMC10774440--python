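import numpy as np
import pytest

from ccsplit.synth import ImageSimConfig, simulate_image_set


@pytest.fixture(scope="session")
def noiseless_config() -> ImageSimConfig:
    """Small noiseless field set: detection should be exact on it."""
    return ImageSimConfig(
        n_cells=20, two_dot_fraction=1.0, mitotic_fraction=0.0,
        distance_mean_um=1.2, distance_sd_um=0.15,
        noise_sd=0.0, shot_noise=False, background_level=50.0, seed=42,
    )


@pytest.fixture(scope="session")
def noiseless_set(noiseless_config):
    return simulate_image_set(noiseless_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
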