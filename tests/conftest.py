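import numpy as np
import pytest

from omtemplate.phantom import PhantomParams, make_canonical_anatomy, make_subject
from omtemplate.volgeom import DisplacementField, ImageGrid, ScalarImage

from scipy import ndimage


@pytest.fixture
def grid8():
    return ImageGrid.isotropic((8, 8, 8), 2.0)


@pytest.fixture
def grid16():
    return ImageGrid.isotropic((16, 16, 16), 2.0)


def smooth_random_field(grid: ImageGrid, amplitude: float, sigma_vox: float,
                        seed: int, taper_vox: float = 3.0) -> DisplacementField:
    """Gaussian-filtered white noise, edge-tapered, scaled to a max |d|."""
    rng = np.random.default_rng(seed)
    disp = rng.standard_normal(grid.shape + (3,))
    for c in range(3):
        disp[..., c] = ndimage.gaussian_filter(disp[..., c], sigma_vox)
    for ax, n in enumerate(grid.shape):
        ramp = np.clip(np.minimum(np.arange(n), np.arange(n)[::-1]) / taper_vox,
                       0, 1)
        shape = [1, 1, 1, 1]
        shape[ax] = n
        disp *= ramp.reshape(shape)
    mag = np.linalg.norm(disp, axis=-1).max()
    if mag > 0:
        disp *= amplitude / mag
    return DisplacementField(grid, disp)


def smooth_random_image(grid: ImageGrid, seed: int, sigma_vox: float = 2.0,
                        taper_vox: float = 0.0) -> ScalarImage:
    rng = np.random.default_rng(seed)
    vals = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma_vox)
    if taper_vox > 0:
        for ax, n in enumerate(grid.shape):
            ramp = np.clip(
                np.minimum(np.arange(n), np.arange(n)[::-1]) / taper_vox, 0, 1)
            shape = [1, 1, 1]
            shape[ax] = n
            vals *= ramp.reshape(shape)
    return ScalarImage(grid, vals)


# desk-scale phantoms shared across test modules (expensive to build)

@pytest.fixture(scope="session")
def small_params():
    """32^3 phantom: fast enough for registration tests."""
    return PhantomParams(grid_shape=(32, 32, 32), voxel_size=3.0,
                         subject_warp_amplitude=2.0,
                         affine_jitter=(0.0, 0.0), affine_translation=0.0,
                         noise_sd=(4.0, 4.0, 1e-5))


@pytest.fixture(scope="session")
def canonical_small(small_params):
    return make_canonical_anatomy(small_params)


@pytest.fixture(scope="session")
def subject_small(small_params):
    return make_subject(small_params, age=60.0, subject_seed=11)
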