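import numpy as np
import pytest

from pancradiomics.discretization import LevelMap
from pancradiomics.io_preprocess import Mask3D
from pancradiomics.synthetic_data import PhantomSpec, generate_cohort

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


def levelmap_from_array(arr, spacing=(1.0, 1.0, 1.0), bin_count=None) -> LevelMap:
    """Build a LevelMap directly from an integer array (0 = outside ROI)."""
    arr = np.asarray(arr, dtype=np.int16)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    roi = arr > 0
    if bin_count is None:
        bin_count = max(2, int(arr.max()))
        # round up to a power of two so matrices stay well formed
        bin_count = 1 << (bin_count - 1).bit_length()
    edges = np.linspace(0.0, 1.0, bin_count + 1)
    return LevelMap(arr, roi, bin_count, edges, spacing)


def random_levelmap(rng, shape=(3, 6, 6), bin_count=4, roi_density=0.8) -> LevelMap:
    roi = rng.random(shape) < roi_density
    if not roi.any():
        roi.flat[0] = True
    arr = np.where(roi, rng.integers(1, bin_count + 1, size=shape), 0).astype(np.int16)
    return levelmap_from_array(arr, bin_count=bin_count)


def ball_mask(radius_vox: int, spacing=(1.0, 1.0, 1.0)) -> Mask3D:
    r = radius_vox
    n = 2 * r + 3
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = n // 2
    inside = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r * r
    return Mask3D(inside.astype(np.uint8), spacing, {1: "tumor"})


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-case phantom cohort (3 head / 3 body-tail) at the default geometry."""
    spec = PhantomSpec(seed=7, n_head=3, n_bodytail=3)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
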