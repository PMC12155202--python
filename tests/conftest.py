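import numpy as np
import pytest

from widefield3d import OpticalConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def paper_optics():
    """The acquisition optics of the thick-tissue protocol: NA 1.0 water
    immersion, cleared tissue at refractive index 1.50."""
    return OpticalConfig(
        na=1.0,
        n_immersion=1.33,
        n_sample=1.50,
        em_wavelength_nm=520.0,
        voxel_size=(0.8, 0.34, 0.34),
    )


@pytest.fixture
def matched_optics():
    """Index-matched configuration: no depth-dependent aberration."""
    return OpticalConfig(
        na=1.0,
        n_immersion=1.33,
        n_sample=1.33,
        em_wavelength_nm=520.0,
        voxel_size=(0.8, 0.34, 0.34),
    )
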