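import numpy as np
import pytest

from thermolock.model import BoundarySpec, Layer, LayerStack, SpectralGrid

POLYESTER = Layer(14e-3, 0.155, 1090.0, 1670.0)


@pytest.fixture
def polyester_stack() -> LayerStack:
    """Single 14-mm polyester slab (phantom material)."""
    return LayerStack([POLYESTER])


@pytest.fixture
def three_layer_stack() -> LayerStack:
    """Skin-fat-muscle-like contrast for multilayer checks."""
    return LayerStack([
        Layer(2e-3, 0.37, 1100.0, 3400.0),
        Layer(4e-3, 0.21, 920.0, 2300.0),
        Layer(10e-3, 0.49, 1050.0, 3600.0),
    ])


@pytest.fixture
def convective_bc() -> BoundarySpec:
    """Free-air convection on top, insulated bottom (phantom conditions)."""
    return BoundarySpec(h_up=10.0, h_dn=0.0)


@pytest.fixture
def small_grid() -> SpectralGrid:
    return SpectralGrid(64, 64, 1e-3)


@pytest.fixture
def fine_grid() -> SpectralGrid:
    return SpectralGrid(128, 128, 0.5e-3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
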