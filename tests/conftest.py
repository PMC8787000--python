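import numpy as np
import pytest

from tzs.phantoms import PhantomParams, RegionPrior


def small_params(**overrides) -> PhantomParams:
    """Desk-scale phantom parameters used across the unit tests: a 48x64x48
    voxel body at 3 mm spacing with 9 mm TZ signatures."""
    defaults = dict(
        volume_shape=(48, 64, 48),
        voxel_spacing_mm=(4.0, 4.0, 4.0),
        body_axes_mm=(88.0, 124.0, 88.0),
        tz_radius_mm=6.0,
        noise_sd=0.0,
        closed_loop_prob=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomParams(**defaults)


@pytest.fixture
def phantom_params():
    return small_params()


@pytest.fixture
def noisy_params():
    return small_params(noise_sd=0.05, closed_loop_prob=0.2)


@pytest.fixture
def table_prior():
    return RegionPrior.default()


def make_ellipsoid_volume(shape=(48, 64, 48), spacing=(4.0, 4.0, 4.0),
                          axes_mm=(88.0, 124.0, 88.0), intensity=1.0):
    """Analytic ellipsoid-on-air volume plus its exact body mask."""
    shape = tuple(shape)
    center = (np.asarray(shape) - 1) / 2.0
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    coords = [zz, yy, xx]
    ell = sum(
        (((coords[ax] - center[ax]) * spacing[ax]) / axes_mm[ax]) ** 2 for ax in range(3)
    )
    mask = ell <= 1.0
    return np.where(mask, intensity, 0.0), mask
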