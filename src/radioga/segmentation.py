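"""Automated whole-breast segmentation.

The breast occupies the single largest bright region of a mammogram. The
segmenter thresholds candidate tissue at a global intensity cutoff (strictly
above 50 on the 0-255 scale), clears a 5% margin along every image edge to
drop scanner artifacts and labels that hug the frame, and keeps the largest
connected component of what remains. Applying the resulting mask to the
image zeroes everything outside the breast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BinaryMask, GrayImage, ValidationError


class SegmentationError(RuntimeError):
    """Raised when no breast tissue can be found."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the whole-breast segmenter.

    threshold : candidate-tissue cutoff on the 0-255 scale (kept strictly
        exclusive: a pixel must exceed it). Default 50.
    border_fraction : per-side margin cleared before component selection,
        as a fraction of each dimension, floor-rounded to pixels. Default 0.05.
    connectivity : 4 or 8, for connected-component labelling. Default 8.
    """

    threshold: int = 50
    border_fraction: float = 0.05
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValidationError("threshold must be in [0, 255]")
        if not 0 <= self.border_fraction < 0.5:
            raise ValidationError("border_fraction must be in [0, 0.5)")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def threshold_mask(image: GrayImage, threshold: int = 50) -> BinaryMask:
    """Candidate-tissue mask: true exactly where intensity > threshold."""
    return BinaryMask(image.pixels > threshold)


def largest_component(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Keep only the connected component with the most pixels.

    Ties are broken toward the component whose first pixel comes earliest in
    row-major order, which is the lowest label assigned by the scan.
    """
    labels, n = ndimage.label(mask.pixels, structure=_structure(connectivity))
    if n == 0:
        raise SegmentationError("no breast tissue found (empty mask)")
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # argmax returns the first maximum
    return BinaryMask(labels == best)


def trim_border(mask: BinaryMask, border_fraction: float = 0.05) -> BinaryMask:
    """Clear floor(fraction*height) rows and floor(fraction*width) columns
    along each edge."""
    if not 0 <= border_fraction < 0.5:
        raise ValidationError("border_fraction must be in [0, 0.5)")
    h, w = mask.shape
    dh = int(border_fraction * h)
    dw = int(border_fraction * w)
    out = np.zeros_like(mask.pixels)
    out[dh : h - dh, dw : w - dw] = mask.pixels[dh : h - dh, dw : w - dw]
    return BinaryMask(out)


def segment_breast(image: GrayImage, config: SegmentationConfig | None = None) -> BinaryMask:
    """Threshold, trim the frame margin, keep the largest component.

    The margin is trimmed before component selection so an edge artifact
    can never bridge into the breast component. 16-bit input is rescaled
    to 0-255 first (the threshold is defined on that scale).
    """
    config = config or SegmentationConfig()
    img = image.to_8bit()
    mask = threshold_mask(img, config.threshold)
    mask = trim_border(mask, config.border_fraction)
    return largest_component(mask, config.connectivity)


def apply_mask(image: GrayImage, mask: BinaryMask) -> GrayImage:
    """Binary AND of image and mask: intensities kept where the mask is
    true, zero elsewhere."""
    if image.shape != mask.shape:
        raise ValidationError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    return GrayImage(np.where(mask.pixels, image.pixels, 0), bit_depth=image.bit_depth)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    if a.shape != b.shape:
        raise ValidationError("masks must share a shape")
    inter = np.logical_and(a.pixels, b.pixels).sum()
    total = a.pixels.sum() + b.pixels.sum()
    if total == 0:
        return 1.0
    return 2.0 * inter / total
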