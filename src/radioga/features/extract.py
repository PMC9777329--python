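"""The full feature vector: 94 texture and first-order features per ROI."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..io import BinaryMask, GrayImage, ValidationError
from .discretize import discretize
from .families import (
    FIRSTORDER_NAMES,
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    SHAPE_NAMES,
    firstorder_features,
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    shape_features,
)
from .matrices import DEFAULT_ANGLES, glcm_matrix


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings.

    bin_width : gray-level bin width on the intensity scale (default 25,
        i.e. about 11 levels over a 0-255 range).
    distance : pixel offset for GLCM pairs and the GLDM neighborhood.
    gldm_alpha : dependence tolerance in gray levels.
    pixel_area : physical area of one pixel (scales TotalEnergy).
    include_shape : add the 2D shape family (off by default; the standard
        pipeline is texture-only).
    """

    bin_width: float = 25.0
    distance: int = 1
    angles: tuple[tuple[int, int], ...] = DEFAULT_ANGLES
    gldm_alpha: float = 0.0
    pixel_area: float = 1.0
    include_shape: bool = False


#: feature names per family, in registry order
FAMILY_REGISTRY: dict[str, list[str]] = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}


def registry_names(include_shape: bool = False) -> list[str]:
    """Namespaced feature names, e.g. ``glcm.Contrast`` — 94 by default."""
    names = [f"{fam}.{n}" for fam, lst in FAMILY_REGISTRY.items() for n in lst]
    if include_shape:
        names += [f"shape.{n}" for n in SHAPE_NAMES]
    return names


def extract_features(
    image: GrayImage,
    mask: BinaryMask,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Compute the full feature vector inside a mask.

    Returns an ordered name -> value map with exactly 94 entries under the
    default registry (19 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM,
    5 NGTDM, 14 GLDM), all finite. Deterministic for fixed input/config.
    """
    config = config or FeatureConfig()
    if image.shape != mask.shape:
        raise ValidationError("image and mask shapes differ")
    if not mask.pixels.any():
        raise ValidationError("empty mask")
    roi = discretize(image, mask, config.bin_width)
    out: dict[str, float] = {}
    fam_values = {
        "firstorder": firstorder_features(
            image, mask, bin_width=config.bin_width, pixel_area=config.pixel_area
        ),
        "glcm": glcm_features(glcm_matrix(roi, config.distance, config.angles)),
        "glrlm": glrlm_features(roi, config.angles),
        "glszm": glszm_features(roi),
        "ngtdm": ngtdm_features(roi),
        "gldm": gldm_features(roi, alpha=config.gldm_alpha, distance=config.distance),
    }
    for fam, names in FAMILY_REGISTRY.items():
        vals = fam_values[fam]
        for n in names:
            out[f"{fam}.{n}"] = vals[n]
    if config.include_shape:
        vals = shape_features(mask)
        for n in SHAPE_NAMES:
            out[f"shape.{n}"] = vals[n]
    return out
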