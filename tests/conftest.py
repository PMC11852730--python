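import numpy as np
import pytest

from parotid_radiomics import SegmentationMask, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return VolumeImage(np.asarray(data, dtype=np.float64), spacing)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    return SegmentationMask(np.asarray(data, dtype=bool), spacing)


def sphere_mask(radius_mm, spacing=(1.0, 1.0, 1.0), margin_mm=3.0):
    """Digitized ball: voxel centres within radius of the grid centre."""
    spacing = np.asarray(spacing, float)
    half = radius_mm + margin_mm
    shape = tuple(int(np.ceil(2 * half / s)) for s in spacing)
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    c = [n * s / 2 for n, s in zip(shape, spacing)]
    d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
    return SegmentationMask(d2 <= radius_mm**2, tuple(spacing))


def random_level_grid(rng, shape=(6, 6, 6), n_levels=4, mask_fraction=0.85):
    """Random small level grid with 0 = outside ROI."""
    grid = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < mask_fraction
    if not mask.any():
        mask.flat[0] = True
    return (grid * mask).astype(np.int32)


@pytest.fixture
def small_cohort():
    """Tiny but complete cohort: quick to extract, exercises every stage."""
    from parotid_radiomics import CohortSpec, generate_cohort

    spec = CohortSpec(
        n_wt=5, n_mt=4, roi_shape=(16, 16, 8), spacing_mm=(0.7, 0.7, 3.0),
        n_reseg=4, seed=7,
    )
    return generate_cohort(spec)
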