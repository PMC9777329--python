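"""Synthetic mammogram-like cohorts and planted-feature tables.

The image generator emulates the structure screening mammograms present to
this pipeline: a dark background, a bright half-elliptical breast region,
a small scanner/label artifact hugging the frame edge, and a textured
lesion inside a radiologist-style circular ROI. Class information is
carried by second-order texture only: malignant masses get
shorter-correlation-length (busier) internal noise, malignant
calcifications a denser bright-speckle cluster, so co-occurrence
contrast/busyness-type features are the a-priori informative ones. The
separation between the benign and malignant texture parameters scales
linearly with ``texture_effect``; at 0 the classes are identically
distributed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (
    BinaryMask,
    GrayImage,
    SampleManifest,
    ValidationError,
    write_image,
    write_manifest,
    write_mask,
)
from .tables import FeatureTable

BACKGROUND_MAX = 25  # keeps the frame strictly below the 50 threshold
BREAST_MIN = 110  # keeps tissue strictly above it


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort."""

    n_samples: int = 40
    lesion_type: str = "mass"
    class_balance: float = 0.5
    texture_effect: float = 1.0
    image_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("n_samples must be at least 4")
        if self.lesion_type not in ("calcification", "mass"):
            raise ValidationError("lesion_type must be calcification or mass")
        if not 0 < self.class_balance < 1:
            raise ValidationError("class_balance must be in (0, 1)")
        if self.image_size < 64:
            raise ValidationError("image_size must be at least 64")


def _breast_mask(size: int) -> np.ndarray:
    """Half-ellipse anchored near the left edge, clear of the 5% margin."""
    r, c = np.mgrid[0:size, 0:size]
    cy, cx = size / 2.0, 0.08 * size
    a, b = 0.34 * size, 0.50 * size
    return (((r - cy) / a) ** 2 + ((c - cx) / b) ** 2 <= 1.0) & (c >= cx)


def make_mammogram(
    spec: CohortSpec, class_label: str, seed: int
) -> tuple[GrayImage, BinaryMask, BinaryMask]:
    """One synthetic mammogram.

    Returns ``(image, roi, truth_breast)``: the 8-bit image, the
    radiologist-style circular lesion ROI, and the ground-truth breast
    mask for scoring the automated segmentation. Background stays below
    30 and breast tissue above 80 by construction, so the candidate-tissue
    threshold separates them exactly. Byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = spec.image_size
    img = rng.uniform(5, BACKGROUND_MAX, size=(n, n))

    breast = _breast_mask(n)
    base = 140.0 + 8.0 * np.sin(np.linspace(0, np.pi, n))[:, None]
    tissue = ndimage.gaussian_filter(rng.normal(0, 14, size=(n, n)), 4.0)
    img[breast] = np.clip(base + tissue, BREAST_MIN, 210)[breast]

    # corner label artifact inside the 5% trim margin
    m = max(2, int(0.05 * n) - 2)
    img[2 : 2 + m, n - 2 - m : n - 2] = 220.0

    # lesion inside the breast
    r, c = np.mgrid[0:n, 0:n]
    lc = (int(0.5 * n), int(0.30 * n))
    lesion_r = 0.09 * n
    lesion = (r - lc[0]) ** 2 + (c - lc[1]) ** 2 <= lesion_r**2
    malignant = class_label == "malignant"
    if spec.lesion_type == "mass":
        # correlation length shrinks (texture gets busier) for malignant
        sigma = 3.0 - (1.8 * spec.texture_effect if malignant else 0.0)
        sigma = max(sigma, 0.6)
        blob = ndimage.gaussian_filter(rng.normal(0, 1, size=(n, n)), sigma)
        blob *= 35.0 / max(blob[lesion].std(), 1e-9)
        img[lesion] = np.clip(160.0 + blob[lesion], BREAST_MIN, 245)
    else:
        density = 0.006 + (0.020 * spec.texture_effect if malignant else 0.0)
        speckle = (rng.random((n, n)) < density) & lesion
        img[lesion] = np.clip(135.0 + rng.normal(0, 6, size=(n, n))[lesion], BREAST_MIN, 180)
        img[speckle] = 250.0

    roi = (r - lc[0]) ** 2 + (c - lc[1]) ** 2 <= (1.25 * lesion_r) ** 2
    return (
        GrayImage(np.rint(np.clip(img, 0, 255)).astype(np.int64), bit_depth=8),
        BinaryMask(roi),
        BinaryMask(breast),
    )


def make_cohort(spec: CohortSpec, out_dir: str | Path) -> SampleManifest:
    """Write a full cohort (images, lesion ROIs, manifest.csv) to disk.

    Labels are assigned so the malignant proportion is within one sample
    of ``class_balance``; their order is shuffled reproducibly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n_mal = int(round(spec.n_samples * spec.class_balance))
    labels = ["malignant"] * n_mal + ["benign"] * (spec.n_samples - n_mal)
    order = rng.permutation(spec.n_samples)
    labels = [labels[i] for i in order]
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_samples)

    rows = []
    for i, (label, s) in enumerate(zip(labels, seeds)):
        image, roi, _ = make_mammogram(spec, label, int(s))
        img_name = f"sample_{i:03d}.png"
        mask_name = f"sample_{i:03d}_roi.png"
        write_image(image, out_dir / img_name)
        write_mask(roi, out_dir / mask_name)
        rows.append(
            {
                "image": img_name,
                "mask": mask_name,
                "label": label,
                "lesion_type": spec.lesion_type,
                "view": "CC",
            }
        )
    manifest = SampleManifest(pd.DataFrame(rows), root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def make_feature_table(
    n_samples: int,
    n_features: int,
    n_informative: int,
    effect_size: float,
    seed: int = 0,
    class_balance: float = 0.5,
) -> FeatureTable:
    """Gaussian table with class-shifted informative columns.

    Informative columns are N(0,1) for benign and N(effect_size, 1) for
    malignant; the rest are N(0,1) noise for both classes. The planted
    column indices are recorded on the returned table as
    ``informative_indices``.
    """
    if n_informative > n_features:
        raise ValidationError("n_informative exceeds n_features")
    rng = np.random.default_rng(seed)
    n_mal = int(round(n_samples * class_balance))
    y = np.zeros(n_samples, dtype=int)
    y[rng.choice(n_samples, size=n_mal, replace=False)] = 1
    X = rng.normal(0, 1, size=(n_samples, n_features))
    informative = rng.choice(n_features, size=n_informative, replace=False)
    X[np.ix_(y == 1, informative)] += effect_size
    table = FeatureTable(
        X, [f"f{i:03d}" for i in range(n_features)], y
    )
    table.informative_indices = sorted(int(i) for i in informative)  # type: ignore[attr-defined]
    return table
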