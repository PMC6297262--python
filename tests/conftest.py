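import numpy as np
import pytest

from tbmorph.core import ImageVolume
from tbmorph.phantom import PhantomGeometry, make_base_phantom


@pytest.fixture(scope="session")
def geom():
    """Desk-scale acquisition geometry: 64x64 matrix, 0.2 mm in-plane, 32 slices."""
    return PhantomGeometry(shape=(64, 64, 32), spacing=(0.2, 0.2, 1.0))


@pytest.fixture(scope="session")
def iso_geom():
    """Isotropic 0.2 mm grid for Jacobian-oracle checks."""
    return PhantomGeometry(shape=(48, 48, 48), spacing=(0.2, 0.2, 0.2))


@pytest.fixture(scope="session")
def base_phantom(geom):
    """Base anatomy at the desk-scale geometry (shared, read-only)."""
    return make_base_phantom(geom, seed=7)


@pytest.fixture
def zero_volume(iso_geom):
    return ImageVolume(data=np.zeros(iso_geom.shape, np.float32),
                       spacing=iso_geom.spacing, affine=iso_geom.affine)
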