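import numpy as np
import pytest
from hypothesis import settings

from digiwell.layout import build_layout
from digiwell.simulate import SimulationConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_layout():
    """2 modules x 6 wells on a 2x3 grid."""
    return build_layout(2, 6, 2, 3, well_pitch_um=100.0, well_diameter_um=60.0)


@pytest.fixture
def small_layout():
    """One module of 500 wells (20 x 25), renderable in a small image."""
    return build_layout(1, 500, 20, 25, well_pitch_um=120.0, well_diameter_um=90.0)


@pytest.fixture
def noiseless_config():
    """All stochastic imaging terms off: rendering is exactly deterministic."""
    return SimulationConfig(
        seed=0,
        retention_fraction=1.0,
        negative_sd=0.0,
        positive_sd=0.0,
        psf_sigma=0.0,
        read_noise_sd=0.0,
    )
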