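import numpy as np
import pytest

from fetrad.images import SUVImage
from fetrad.preprocessing import DiscretizedVolume


def make_disc(levels_array, mask=None) -> DiscretizedVolume:
    """Wrap an integer level array (1..Ng) into a DiscretizedVolume."""
    lv = np.asarray(levels_array, dtype=np.int64)
    if lv.ndim < 3:
        lv = lv.reshape(lv.shape + (1,) * (3 - lv.ndim))
    m = np.ones(lv.shape, bool) if mask is None else np.asarray(mask, bool)
    lv = np.where(m, lv, 0)
    return DiscretizedVolume(lv, m, int(lv[m].max()))


def random_roi(rng, max_side=6, max_levels=5):
    """A random small discretized ROI with a random (non-empty) mask."""
    shape = tuple(rng.integers(2, max_side + 1, 3))
    ng = int(rng.integers(1, max_levels + 1))
    lv = rng.integers(1, ng + 1, shape)
    mask = rng.uniform(size=shape) < 0.8
    if not mask.any():
        mask.flat[0] = True
    lv = np.where(mask, lv, 0)
    # renumber so max level inside the mask equals Ng
    ng_eff = int(lv[mask].max())
    return make_disc(lv, mask), ng_eff


def image_from(values, spacing=(2.0, 2.0, 2.0)) -> SUVImage:
    arr = np.asarray(values, dtype=float)
    if arr.ndim < 3:
        arr = arr.reshape(arr.shape + (1,) * (3 - arr.ndim))
    return SUVImage(arr, spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
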