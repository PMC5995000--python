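import numpy as np
import pytest

from octseg.io import BScan
from octseg.phantom import LayerSpec, PhantomConfig, generate_bscan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_flat_config():
    """Small, fast 2-layer phantom with a flat surface (no speckle)."""
    return PhantomConfig(
        layers=[LayerSpec.from_class("dense_collagen", 60),
                LayerSpec.from_class("normal_myocardium", 200)],
        width_px=220, depth_px=260, surface_profile="flat",
        surface_depth_px=30, speckle_on=False, seed=7,
    )


@pytest.fixture
def small_flat_bscan(small_flat_config):
    bscan, truth = generate_bscan(small_flat_config)
    return bscan, truth


@pytest.fixture
def constant_bscan():
    return BScan(np.full((64, 64), 0.5), axial_um_per_px=4.9, lateral_um_per_px=5.0, id="const")
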