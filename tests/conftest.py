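import numpy as np
import pytest

from laccscreen import (
    PlateLayout,
    SimulationConfig,
    default_grid,
    make_screen_layouts,
)


@pytest.fixture
def small_config():
    """Fast-to-render plate geometry for an 8x12 toy array."""
    return SimulationConfig(
        image_width=240,
        image_height=160,
        colony_radius=6.0,
        colony_blur_sigma=0.0,
        base_signal=0.2,
        edge_amplitude=0.0,
        background_field_scale=0.0,
        noise_sd=0.0,
        site_cv=0.0,
    )


@pytest.fixture
def small_layout():
    return PlateLayout(n_rows=8, n_cols=12)


@pytest.fixture
def small_grid(small_layout, small_config):
    return default_grid(small_layout, small_config)


@pytest.fixture
def screen_config():
    """Full-noise configuration used for the simulated screen."""
    return SimulationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240926)
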