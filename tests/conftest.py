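import numpy as np
import pytest

from lgraf import Config, CropSpec, create_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """A 20x20 grid of 50 m cells (0.25 ha per cell)."""
    return create_grid(20, 20, 50.0)


@pytest.fixture
def demo_config():
    """A small, fast full-pipeline configuration."""
    return Config(
        setup_type="area",
        prop_agricultural_area=0.3,
        width=50,
        height=50,
        cell_length_m=50.0,
        total_road_length=150,
        min_dist_roads=4.0,
        crops=(CropSpec(1, "oil-palm", 0.5), CropSpec(2, "rubber", 0.5)),
        fill_up_crop=1,
        seed=7,
    )
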