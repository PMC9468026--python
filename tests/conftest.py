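import numpy as np
import pytest

from simca import AffineTransform2D, SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast-to-render synthetic condition used across test modules."""
    return SimulationConfig(
        image_height_px=256,
        image_width_px=512,
        cab_count_range=(60, 120),
        nonspecific_dab_per_fov=12.0,
        seed=0,
    )


@pytest.fixture
def example_transform() -> AffineTransform2D:
    """A realistic near-identity inter-channel misregistration."""
    return AffineTransform2D.from_params(
        rotation_deg=0.5, scale=1.002, tx=3.1, ty=-2.7
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
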