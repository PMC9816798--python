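import numpy as np
import pytest

from wheatyield import SceneConfig, generate_yield_grid, simulate_multispectral_series


@pytest.fixture
def small_config():
    """A 12x12 scene, fast enough for per-test generation."""
    return SceneConfig(n_rows=12, n_cols=12, seed=7)


@pytest.fixture
def clean_config():
    """Noise-free, cloud-free variant of the small scene."""
    return SceneConfig(
        n_rows=12, n_cols=12, seed=7, noise_sd=0.0, cloudy_scene_prob=0.0
    )


@pytest.fixture
def small_series(small_config):
    grid = generate_yield_grid(small_config)
    return simulate_multispectral_series(grid, small_config), grid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
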