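"""Gray-level discretization of a masked region of interest."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..io import BinaryMask, GrayImage, ValidationError


@dataclass(frozen=True)
class DiscretizedROI:
    """Masked ROI quantized to integer gray levels 1..n_levels.

    ``levels`` holds the level of every in-mask pixel and 0 outside the
    mask; ``bin_edges`` are the intensity boundaries of the bins.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(image: GrayImage, mask: BinaryMask, bin_width: float = 25.0) -> DiscretizedROI:
    """Fixed-bin-width quantization: level = floor((I - min)/width) + 1.

    The minimum is taken over in-mask intensities only, so the levels (and
    every texture feature downstream) are invariant to where the ROI sits
    in the frame and to anything outside the mask.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if image.shape != mask.shape:
        raise ValidationError("image and mask shapes differ")
    m = mask.pixels
    if not m.any():
        raise ValidationError("empty mask")
    vals = image.pixels[m]
    lo = vals.min()
    levels = np.zeros(image.shape, dtype=np.int64)
    levels[m] = (image.pixels[m] - lo) // int(bin_width) + 1 if float(
        bin_width
    ).is_integer() else np.floor((image.pixels[m] - lo) / bin_width).astype(np.int64) + 1
    n_levels = int(levels[m].max())
    edges = lo + bin_width * np.arange(n_levels + 1)
    return DiscretizedROI(levels=levels, mask=m, n_levels=n_levels, bin_edges=edges)
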