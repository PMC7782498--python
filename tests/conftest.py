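import numpy as np
import pytest

from cacs.optics import make_system_psf


@pytest.fixture(scope="session")
def small_psf():
    """Isotropic 1-um FWHM Gaussian kernel at 0.5-um pitch."""
    return make_system_psf("gaussian", {"fwhm_xy": 1.0, "fwhm_z": 1.0}, (0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def system_psf():
    """The x3.2-mode system PSF: 2.0 um lateral / 1.6 um axial FWHM at 0.5-um pitch."""
    return make_system_psf("gaussian", {"fwhm_xy": 2.0, "fwhm_z": 1.6}, (0.5, 0.5, 0.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
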