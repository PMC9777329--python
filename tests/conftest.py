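import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the bruteforce oracle module

from radioga import BinaryMask, GrayImage
from radioga.features import DiscretizedROI


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_roi(levels: np.ndarray, mask: np.ndarray | None = None) -> DiscretizedROI:
    """Build a DiscretizedROI directly from a level grid (0 = out of mask)."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    n_levels = int(levels[mask].max())
    return DiscretizedROI(
        levels=np.where(mask, levels, 0),
        mask=np.asarray(mask, bool),
        n_levels=n_levels,
        bin_edges=np.arange(n_levels + 1, dtype=float),
    )


@pytest.fixture
def checker_image():
    """16x16 checkerboard of 0/255, 8-bit."""
    g = np.indices((16, 16)).sum(axis=0) % 2
    return GrayImage(g * 255, bit_depth=8)


@pytest.fixture
def ellipse_image():
    """Synthetic frame: dark background, bright ellipse, corner label box."""
    n = 120
    img = np.full((n, n), 10)
    r, c = np.mgrid[0:n, 0:n]
    ellipse = ((r - 60) / 35.0) ** 2 + ((c - 45) / 30.0) ** 2 <= 1
    img[ellipse] = 200
    img[1:4, n - 5 : n - 1] = 220  # label inside the 5% margin
    return GrayImage(img, bit_depth=8), BinaryMask(ellipse)
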