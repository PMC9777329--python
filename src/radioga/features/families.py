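"""The six radiomic feature families.

Definitions follow the IBSI-standardized forms. Degenerate limits use the
conventions 0*log(0) = 0, an eps = 2.2e-16 guard on denominators, and a
1e6 cap on NGTDM Coarseness when its denominator vanishes, so every
feature is finite on every nonempty ROI.
"""

from __future__ import annotations

import numpy as np

from ..io import BinaryMask, GrayImage, ValidationError
from .discretize import DiscretizedROI
from .matrices import (
    DEFAULT_ANGLES,
    gldm_matrix,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_matrix,
)

EPS = 2.2e-16
COARSENESS_CAP = 1e6


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy(p: np.ndarray) -> float:
    return float(-_xlog2x(p).sum())


# ---------------------------------------------------------------- GLCM ----

GLCM_NAMES = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "SumVariance",
]


def _glcm_single(P: np.ndarray) -> dict[str, float]:
    L = P.shape[0]
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((px * i).sum())
    muy = float((py * i).sum())
    sigx = float(np.sqrt((px * (i - mux) ** 2).sum()))
    sigy = float(np.sqrt((py * (i - muy) ** 2).sum()))

    k_diff = np.arange(L)  # |i-j| in 0..L-1
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * L + 1)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in k_sum])

    diff_avg = float((p_diff * k_diff).sum())
    sum_avg = float((p_sum * k_sum).sum())

    HX = _entropy(px)
    HY = _entropy(py)
    HXY = _entropy(P)
    outer = np.outer(px, py)
    HXY1 = float(-(P * np.where(outer > 0, np.log2(outer + (outer <= 0)), 0.0)).sum())
    HXY2 = _entropy(outer)

    autoc = float((P * ii * jj).sum())
    corr = 1.0 if sigx * sigy < EPS else (autoc - mux * muy) / (sigx * sigy)
    imc1 = 0.0 if max(HX, HY) < EPS else (HXY - HXY1) / max(HX, HY)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))

    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float((P * (ii + jj - mux - muy) ** 4).sum()),
        "ClusterShade": float((P * (ii + jj - mux - muy) ** 3).sum()),
        "ClusterTendency": float((P * (ii + jj - mux - muy) ** 2).sum()),
        "Contrast": float((P * (ii - jj) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float((p_diff * (k_diff - diff_avg) ** 2).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / L) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / L)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p_diff[1:] / k_diff[1:] ** 2).sum()) if L > 1 else 0.0,
        "JointAverage": mux,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": HXY,
        "MaximumProbability": float(P.max()),
        "SumAverage": sum_avg,
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float((P * (ii - mux) ** 2).sum()),
        "SumVariance": float((p_sum * (k_sum - sum_avg) ** 2).sum()),
    }


def glcm_features(matrices: np.ndarray) -> dict[str, float]:
    """24 co-occurrence features, averaged over angles.

    ``matrices`` is the (n_angles, L, L) stack from :func:`glcm_matrix`;
    angles with no valid pair (all-zero slices) are skipped.
    """
    per_angle = [_glcm_single(P) for P in matrices if P.sum() > 0]
    if not per_angle:
        raise ValidationError("no valid pixel pairs for GLCM")
    return {n: float(np.mean([d[n] for d in per_angle])) for n in GLCM_NAMES}


# --------------------------------------------------------------- GLRLM ----

GLRLM_NAMES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]


def _run_zone_common(P: np.ndarray, n_pixels: int, kind: str) -> dict[str, float]:
    """Shared run-length / size-zone feature algebra.

    ``P`` counts runs (or zones) by gray level i (rows, 1-based) and
    length/size j (columns, 1-based).
    """
    Nr = P.sum()
    if Nr == 0:
        raise ValidationError("empty run/zone matrix")
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = P / Nr
    pg = P.sum(axis=1)  # per gray level
    ps = P.sum(axis=0)  # per length/size
    mu_g = (p.sum(axis=1) * i).sum()
    mu_s = (p.sum(axis=0) * j).sum()
    short = "ShortRun" if kind == "run" else "SmallArea"
    long_ = "LongRun" if kind == "run" else "LargeArea"
    run = "Run" if kind == "run" else "Zone"
    rl = "RunLength" if kind == "run" else "SizeZone"
    glre = "RunEmphasis" if kind == "run" else "ZoneEmphasis"
    feats = {
        f"{short}Emphasis": (P / jj**2).sum() / Nr,
        f"{long_}Emphasis": (P * jj**2).sum() / Nr,
        "GrayLevelNonUniformity": (pg**2).sum() / Nr,
        "GrayLevelNonUniformityNormalized": (pg**2).sum() / Nr**2,
        f"{rl}NonUniformity": (ps**2).sum() / Nr,
        f"{rl}NonUniformityNormalized": (ps**2).sum() / Nr**2,
        f"{run}Percentage": Nr / n_pixels,
        "GrayLevelVariance": (p * (ii - mu_g) ** 2).sum(),
        f"{run}Variance": (p * (jj - mu_s) ** 2).sum(),
        f"{run}Entropy": _entropy(p),
        f"LowGrayLevel{glre}": (P / ii**2).sum() / Nr,
        f"HighGrayLevel{glre}": (P * ii**2).sum() / Nr,
        f"{short}LowGrayLevelEmphasis": (P / (ii**2 * jj**2)).sum() / Nr,
        f"{short}HighGrayLevelEmphasis": (P * ii**2 / jj**2).sum() / Nr,
        f"{long_}LowGrayLevelEmphasis": (P * jj**2 / ii**2).sum() / Nr,
        f"{long_}HighGrayLevelEmphasis": (P * ii**2 * jj**2).sum() / Nr,
    }
    return {k: float(v) for k, v in feats.items()}


def glrlm_features(roi: DiscretizedROI, angles=DEFAULT_ANGLES) -> dict[str, float]:
    """16 run-length features over 4 directions, averaged per feature."""
    mats = glrlm_matrix(roi, angles)
    per_dir = [_run_zone_common(P, roi.n_pixels, "run") for P in mats if P.sum() > 0]
    return {n: float(np.mean([d[n] for d in per_dir])) for n in GLRLM_NAMES}


# --------------------------------------------------------------- GLSZM ----

GLSZM_NAMES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
]


def glszm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 size-zone features (zones are 8-connected equal-level regions)."""
    feats = _run_zone_common(glszm_matrix(roi), roi.n_pixels, "zone")
    return {n: feats[n] for n in GLSZM_NAMES}


# --------------------------------------------------------------- NGTDM ----

NGTDM_NAMES = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]


def ngtdm_features(roi: DiscretizedROI) -> dict[str, float]:
    """5 neighbouring gray-tone difference features."""
    n_i, s_i, Nv = ngtdm_matrix(roi)
    p_i = n_i / Nv
    present = p_i > 0
    Ngp = int(present.sum())
    levels = np.arange(1, roi.n_levels + 1, dtype=float)

    ps = float((p_i * s_i).sum())
    coarseness = COARSENESS_CAP if ps < EPS else 1.0 / ps

    if Ngp <= 1:
        contrast = 0.0
    else:
        pi = p_i[present]
        li = levels[present]
        pair = (pi[:, None] * pi[None, :] * (li[:, None] - li[None, :]) ** 2).sum()
        contrast = pair / (Ngp * (Ngp - 1)) * s_i.sum() / Nv

    li = levels[present]
    pi = p_i[present]
    si = s_i[present]
    ipi = li * pi
    denom_busy = np.abs(ipi[:, None] - ipi[None, :]).sum()
    busyness = 0.0 if denom_busy < EPS else ps / denom_busy

    with np.errstate(divide="ignore", invalid="ignore"):
        pair_w = (pi[:, None] * si[:, None] + pi[None, :] * si[None, :]) / (
            pi[:, None] + pi[None, :]
        )
    complexity = float(
        (np.abs(li[:, None] - li[None, :]) * pair_w).sum() / Nv
    )

    s_total = s_i.sum()
    if s_total < EPS:
        strength = 0.0
    else:
        strength = float(
            ((pi[:, None] + pi[None, :]) * (li[:, None] - li[None, :]) ** 2).sum()
            / s_total
        )
    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": complexity,
        "Contrast": float(contrast),
        "Strength": strength,
    }


# ---------------------------------------------------------------- GLDM ----

GLDM_NAMES = [
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]


def gldm_features(
    roi: DiscretizedROI, alpha: float = 0.0, distance: int = 1
) -> dict[str, float]:
    """14 gray-level dependence features.

    The matrix column index is the dependent-neighbor count; formulas use
    dependence size = count + 1 (the center pixel joins its own dependence
    set) so the small/large-dependence emphases stay finite for lone pixels.
    """
    P = gldm_matrix(roi, alpha=alpha, distance=distance)
    Nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    k = np.arange(1, P.shape[1] + 1, dtype=float)  # dependence size
    ii, kk = np.meshgrid(i, k, indexing="ij")
    p = P / Nz
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    mu_g = (p.sum(axis=1) * i).sum()
    mu_d = (p.sum(axis=0) * k).sum()
    return {
        "SmallDependenceEmphasis": float((P / kk**2).sum() / Nz),
        "LargeDependenceEmphasis": float((P * kk**2).sum() / Nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / Nz),
        "DependenceNonUniformity": float((pd**2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / Nz**2),
        "GrayLevelVariance": float((p * (ii - mu_g) ** 2).sum()),
        "DependenceVariance": float((p * (kk - mu_d) ** 2).sum()),
        "DependenceEntropy": _entropy(p),
        "LowGrayLevelEmphasis": float((P / ii**2).sum() / Nz),
        "HighGrayLevelEmphasis": float((P * ii**2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (ii**2 * kk**2)).sum() / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * ii**2 / kk**2).sum() / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * kk**2 / ii**2).sum() / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * ii**2 * kk**2).sum() / Nz),
    }


# ---------------------------------------------------------- first order ----

FIRSTORDER_NAMES = [
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "StandardDeviation",
    "TotalEnergy",
    "Uniformity",
    "Variance",
]


def firstorder_features(
    image: GrayImage,
    mask: BinaryMask,
    bin_width: float = 25.0,
    pixel_area: float = 1.0,
) -> dict[str, float]:
    """19 first-order statistics of the raw in-mask intensities.

    Entropy and Uniformity use the fixed-bin-width histogram; every other
    statistic is computed on the undiscretized values with population
    (1/N) moments. TotalEnergy scales Energy by the physical pixel area.
    """
    if image.shape != mask.shape:
        raise ValidationError("image and mask shapes differ")
    x = image.pixels[mask.pixels].astype(float)
    if x.size == 0:
        raise ValidationError("empty mask")
    n = x.size
    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    m3 = ((x - mean) ** 3).mean()
    m4 = ((x - mean) ** 4).mean()
    skew = 0.0 if m2 < EPS else m3 / m2**1.5
    kurt = 0.0 if m2 < EPS else m4 / m2**2
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    nbins = int((x.max() - x.min()) // bin_width) + 1
    hist = np.bincount(((x - x.min()) // bin_width).astype(int), minlength=nbins)
    p = hist / n
    energy = float((x**2).sum())
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": _entropy(p),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": float(kurt),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(skew),
        "StandardDeviation": float(np.sqrt(m2)),
        "TotalEnergy": float(pixel_area * energy),
        "Uniformity": float((p**2).sum()),
        "Variance": float(m2),
    }


# ---------------------------------------------------------------- shape ----

SHAPE_NAMES = [
    "Elongation",
    "MajorAxisLength",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MinorAxisLength",
    "Perimeter",
    "PixelSurface",
]


def shape_features(mask: BinaryMask) -> dict[str, float]:
    """A compact 2D shape set (off the default texture-only path).

    Maximum2DDiameterRow/Column are the largest extents of the region along
    the row and column axes; axis lengths come from the second central
    moments of the pixel coordinates.
    """
    from skimage import measure

    m = mask.pixels.astype(np.uint8)
    if m.sum() == 0:
        raise ValidationError("empty mask")
    props = measure.regionprops(m)[0]
    rows, cols = np.nonzero(mask.pixels)
    return {
        "Elongation": float(
            np.sqrt(props.axis_minor_length / props.axis_major_length)
            if props.axis_major_length > 0
            else 1.0
        ),
        "MajorAxisLength": float(props.axis_major_length),
        "Maximum2DDiameterColumn": float(cols.max() - cols.min() + 1),
        "Maximum2DDiameterRow": float(rows.max() - rows.min() + 1),
        "MinorAxisLength": float(props.axis_minor_length),
        "Perimeter": float(props.perimeter),
        "PixelSurface": float(m.sum()),
    }
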