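import numpy as np
import pytest

from ctcount import PhantomSpec, SubsetROI, Volume3D


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_volume():
    """Deterministic 6x8x10 greyscale volume with anisotropic spacing."""
    rng = np.random.default_rng(7)
    data = rng.integers(0, 256, size=(6, 8, 10)).astype(np.uint8)
    return Volume3D(data, spacing=(2.0, 0.5, 0.5), provenance="unit-test")


@pytest.fixture()
def tiny_pollinium_spec():
    """Small, fast phantom: ~30 separated grains in a 64³ grid."""
    return PhantomSpec(n_objects=30, radius_mean_um=4.0, radius_cv=0.1,
                       mode="loose", shape=(64, 64, 64), psf_sigma_um=1.0,
                       noise_sd=12.0, seed=42)


def sphere_volume(data_shape, centre, radius, fg=200.0, bg=0.0):
    """Binary-ish sphere raster used by several segmentation tests."""
    zz, yy, xx = np.ogrid[:data_shape[0], :data_shape[1], :data_shape[2]]
    d2 = (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
    out = np.full(data_shape, bg, dtype=np.float64)
    out[d2 <= radius ** 2] = fg
    return out
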