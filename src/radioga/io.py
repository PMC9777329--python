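"""Image, mask, manifest and feature-table I/O.

Images are 2D single-channel rasters (DICOM, TIFF or PNG); masks are 0/255
PNG rasters where white marks the segmented region, following the common
radiology-mask convention. Feature tables and sample manifests are CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised for inputs in an unsupported or inconsistent format."""


class ValidationError(ValueError):
    """Raised when a value violates a documented contract."""


@dataclass(frozen=True)
class GrayImage:
    """A 2D grayscale intensity raster.

    Parameters
    ----------
    pixels : ndarray of int
        Row-major intensity grid, 0-based (row i, column j).
    bit_depth : int
        Bits per sample, 8 or 16. All intensities must lie in
        ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("image must be a nonempty 2D array")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise ValidationError(
                f"intensities outside [0, {2**self.bit_depth - 1}] for "
                f"bit depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px.astype(np.int64, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_8bit(self) -> "GrayImage":
        """Linear min-max rescale to the 0-255 scale.

        16-bit intensities are mapped to 8-bit before segmentation because the
        candidate-tissue threshold is defined on a 0-255 scale. A constant
        image maps to all zeros.
        """
        if self.bit_depth == 8:
            return self
        px = self.pixels.astype(np.float64)
        lo, hi = px.min(), px.max()
        if hi == lo:
            out = np.zeros_like(self.pixels)
        else:
            out = np.rint((px - lo) / (hi - lo) * 255).astype(np.int64)
        return GrayImage(out, bit_depth=8)


@dataclass(frozen=True)
class BinaryMask:
    """A 2D boolean raster aligned to an image; on disk 0/255 PNG."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("mask must be a nonempty 2D array")
        object.__setattr__(self, "pixels", px.astype(bool, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_true(self) -> int:
        return int(self.pixels.sum())


LABELS = ("benign", "malignant")
LESION_TYPES = ("calcification", "mass")
VIEWS = ("CC", "MLO")

_MANIFEST_COLUMNS = ["image", "mask", "label", "lesion_type", "view"]


@dataclass
class SampleManifest:
    """Tabular index of a cohort: image paths, optional lesion-mask paths,
    pathology label and lesion type per sample."""

    frame: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        missing = [c for c in _MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        bad = set(self.frame["label"]) - set(LABELS)
        if bad:
            raise ValidationError(f"labels outside {LABELS}: {sorted(bad)}")
        bad = set(self.frame["lesion_type"]) - set(LESION_TYPES)
        if bad:
            raise ValidationError(f"lesion_type outside {LESION_TYPES}: {sorted(bad)}")
        bad = set(self.frame["view"]) - set(VIEWS)
        if bad:
            raise ValidationError(f"view outside {VIEWS}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_lesion_masks(self) -> bool:
        return self.frame["mask"].notna().all() and (self.frame["mask"] != "").all()

    def image_path(self, i: int) -> Path:
        return self.root / str(self.frame["image"].iloc[i])

    def mask_path(self, i: int) -> Path | None:
        v = self.frame["mask"].iloc[i]
        if pd.isna(v) or v == "":
            return None
        return self.root / str(v)

    def binary_labels(self) -> np.ndarray:
        """0 = benign, 1 = malignant."""
        return (self.frame["label"].to_numpy() == "malignant").astype(int)


def _load_raster(path: str | os.PathLike) -> tuple[np.ndarray, int]:
    """Return (2D int array, bit depth) from a DICOM/TIFF/PNG file."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise IOError(f"empty file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        depth = int(ds.BitsAllocated)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        depth = 16 if np.asarray(arr).dtype.itemsize > 1 else 8
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # Reject colour; a trailing singleton channel axis is tolerated.
        if arr.shape[-1] == 1:
            arr = arr[..., 0]
        else:
            raise FormatError(f"{path}: multi-channel image; grayscale required")
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2D raster, got shape {arr.shape}")
    return arr.astype(np.int64), depth


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read a single-channel DICOM, TIFF or PNG image.

    The bit depth is taken from the file (DICOM BitsAllocated, else the sample
    dtype width). RGB inputs raise :class:`FormatError`.
    """
    arr, depth = _load_raster(path)
    return GrayImage(arr, bit_depth=depth)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask: any nonzero sample is foreground."""
    arr, _ = _load_raster(path)
    return BinaryMask(arr != 0)


def write_image(image: GrayImage, path: str | os.PathLike) -> None:
    """Write a GrayImage as PNG or TIFF (dtype matches its bit depth)."""
    import imageio.v3 as iio

    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), image.pixels.astype(dtype))


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as 0/255 8-bit PNG (white = foreground)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.where(mask.pixels, 255, 0).astype(np.uint8))


def write_feature_table(table: "FeatureTable", path: str | os.PathLike) -> None:
    """Serialize a feature table as CSV with the label in a reserved
    ``label`` column. Non-finite values are rejected."""
    from .tables import FeatureTable  # noqa: F401  (type only)

    if not np.all(np.isfinite(table.values)):
        raise ValidationError("feature table contains non-finite values")
    df = pd.DataFrame(table.values, columns=list(table.feature_names))
    df.insert(0, "label", table.labels)
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | os.PathLike) -> "FeatureTable":
    """Read a feature table written by :func:`write_feature_table`."""
    from .tables import FeatureTable

    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValidationError(f"{path}: no 'label' column")
    names = [c for c in df.columns if c != "label"]
    return FeatureTable(
        values=df[names].to_numpy(dtype=float),
        feature_names=list(names),
        labels=df["label"].to_numpy(),
    )


def write_manifest(manifest: SampleManifest, path: str | os.PathLike) -> None:
    manifest.frame.to_csv(path, index=False)


def read_manifest(path: str | os.PathLike, root: str | os.PathLike | None = None) -> SampleManifest:
    path = Path(path)
    frame = pd.read_csv(path, keep_default_na=False)
    if "mask" not in frame.columns:
        frame["mask"] = ""
    return SampleManifest(frame, root=Path(root) if root is not None else path.parent)
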