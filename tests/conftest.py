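import numpy as np
import pytest

from vmoquant import segmentation as seg
from vmoquant import synthetic as syn


@pytest.fixture
def disk_mask():
    """Filled digital disk of radius 50 centered in a 128x128 grid."""
    yy, xx = np.mgrid[0:128, 0:128]
    return seg.BinaryMask((yy - 64) ** 2 + (xx - 64) ** 2 <= 50 * 50)


@pytest.fixture
def bimodal_image():
    """Two-Gaussian intensity image (means 30/180, sigma 10, 50/50, seed 7)."""
    rng = np.random.default_rng(7)
    img = np.concatenate([rng.normal(30, 10, 5000), rng.normal(180, 10, 5000)])
    return np.clip(np.round(img), 0, 255).astype(np.uint8).reshape(100, 100)


@pytest.fixture
def y_scene():
    img, truth = syn.generate_vessel_scene(syn.y_spec(width=9, seed=1))
    return img, truth


def segment_and_clean(img, params=None):
    """Threshold + standard cleanup, shared by several suites."""
    from vmoquant import vessels

    t = seg.li_threshold(img)
    mask = seg.apply_threshold(img, t.t)
    return vessels.clean_vessel_mask(mask, params)
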