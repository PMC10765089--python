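import numpy as np
import pytest

from parquant import synthgen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spot_cfg():
    """One bright spot in a small stack, low noise: easy detection."""
    return sg.SyntheticSpotConfig(
        shape_voxels=(16, 48, 48), n_spots=1, seed=1,
        amplitude_range=(1000.0, 1000.0), background=100.0,
        poisson_gain=1.0, gaussian_sd=2.0)


@pytest.fixture
def blob_frame(rng):
    """A 2D scene of smooth blobs, suitable for registration tests."""
    yy, xx = np.mgrid[0:64, 0:64]
    img = np.zeros((64, 64))
    for cy, cx in rng.uniform(12, 52, (6, 2)):
        img += 500.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.5 ** 2))
    return img
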