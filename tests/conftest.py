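import numpy as np
import pytest

from voxelreg.image import Geometry, Image
from voxelreg.synthetic import FixtureSpec, make_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def image2d(rng):
    """Smooth textured 32x32 test image."""
    x, y = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
    data = 500 + 300 * np.sin(x / 5.0) * np.cos(y / 6.0) + rng.normal(0, 10, (32, 32))
    return Image(data, Geometry((32, 32)))


@pytest.fixture
def image3d_small():
    return make_image(FixtureSpec(shape=(24, 24, 24), seed=5, noise_sd=3.0))


@pytest.fixture
def aniso_geometry():
    return Geometry((12, 10, 8), (0.95, 0.95, 1.20), (-4.0, 2.0, 7.5))
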