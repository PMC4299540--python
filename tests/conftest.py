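import numpy as np
import pytest
from scipy import ndimage

from tumorloc import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_volume(rng):
    """Band-limited random volume: white noise smoothed to ~2-voxel scale."""

    def make(shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), scale=100.0):
        data = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
        data *= scale / max(np.abs(data).max(), 1e-12)
        return Volume(data=data, spacing=spacing)

    return make


def gaussian_blob(shape, center, a, amplitude=100.0, spacing=1.0):
    """Isotropic Gaussian blob A*exp(-r^2 / (2 a^2)) as a Volume."""
    coords = [spacing * np.arange(n) - c for n, c in zip(shape, center)]
    r2 = (coords[0][:, None, None] ** 2 + coords[1][None, :, None] ** 2
          + coords[2][None, None, :] ** 2)
    return Volume(data=amplitude * np.exp(-r2 / (2.0 * a * a)),
                  spacing=(spacing,) * 3)


def sphere_mask(shape, center, radius, spacing=1.0):
    coords = [spacing * np.arange(n) - c for n, c in zip(shape, center)]
    r2 = (coords[0][:, None, None] ** 2 + coords[1][None, :, None] ** 2
          + coords[2][None, None, :] ** 2)
    return r2 <= radius * radius
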