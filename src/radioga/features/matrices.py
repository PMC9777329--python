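"""Texture-matrix builders: GLCM, GLRLM, GLSZM, NGTDM, GLDM.

All builders operate on a :class:`DiscretizedROI`; only pixel pairs, runs,
zones and neighborhoods fully inside the mask contribute. Directions are
given as (row, col) offsets; the default four 2D directions at distance 1
are 0°, 45°, 90° and 135° in image convention.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

#: unit (row, col) offsets for 0, 45, 90, 135 degrees
DEFAULT_ANGLES: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def _shift_pairs(levels: np.ndarray, mask: np.ndarray, dr: int, dc: int):
    """Levels of all in-mask pixel pairs at offset (dr, dc)."""
    h, w = levels.shape
    r0 = max(0, -dr)
    r1 = min(h, h - dr)
    c0 = max(0, -dc)
    c1 = min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ok = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a[ok], b[ok]


def glcm_matrix(
    roi: DiscretizedROI,
    distance: int = 1,
    angles: tuple[tuple[int, int], ...] = DEFAULT_ANGLES,
) -> np.ndarray:
    """Symmetric, per-angle normalized co-occurrence matrices.

    Returns an array of shape (n_angles, n_levels, n_levels); each slice
    sums to 1 (every pair is counted in both directions) unless the angle
    has no valid pairs, in which case the slice is all zero.
    """
    L = roi.n_levels
    if L < 2:
        warnings.warn("degenerate texture: fewer than 2 gray levels", stacklevel=2)
    out = np.zeros((len(angles), L, L))
    for k, (dr, dc) in enumerate(angles):
        a, b = _shift_pairs(roi.levels, roi.mask, dr * distance, dc * distance)
        if a.size == 0:
            continue
        counts = np.zeros((L, L))
        np.add.at(counts, (a - 1, b - 1), 1)
        counts = counts + counts.T  # symmetric: both pair directions
        out[k] = counts / counts.sum()
    return out


def _direction_lines(levels: np.ndarray, mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Concatenate all scan lines along (dr, dc), separated and padded with
    0 (the out-of-mask sentinel), as one 1D level sequence."""
    lv = np.where(mask, levels, 0)
    if (dr, dc) == (0, 1):
        lines = list(lv)
    elif (dr, dc) == (-1, 0):
        lines = list(lv.T)
    elif (dr, dc) == (-1, 1):  # anti-diagonals
        lines = [np.diagonal(np.flipud(lv), k) for k in range(-lv.shape[0] + 1, lv.shape[1])]
    elif (dr, dc) == (-1, -1):  # main diagonals
        lines = [np.diagonal(lv, k) for k in range(-lv.shape[0] + 1, lv.shape[1])]
    else:
        raise ValueError(f"unsupported direction {(dr, dc)}")
    sep = np.zeros(1, dtype=np.int64)
    parts = []
    for ln in lines:
        parts.append(np.asarray(ln, dtype=np.int64))
        parts.append(sep)
    return np.concatenate(parts) if parts else sep


def glrlm_matrix(
    roi: DiscretizedROI,
    angles: tuple[tuple[int, int], ...] = DEFAULT_ANGLES,
) -> list[np.ndarray]:
    """Run-length matrices, one per direction.

    Entry (i-1, j-1) counts maximal runs of j consecutive in-mask pixels of
    level i along the direction; out-of-mask pixels break runs. Each matrix
    has shape (n_levels, longest_run) with a shared run-length axis.
    """
    mats = []
    max_run = 1
    runs_per_angle = []
    for dr, dc in angles:
        seq = _direction_lines(roi.levels, roi.mask, dr, dc)
        # run-length encode: boundaries where the value changes
        change = np.flatnonzero(np.diff(seq)) + 1
        starts = np.concatenate(([0], change))
        lengths = np.diff(np.concatenate((starts, [len(seq)])))
        vals = seq[starts]
        keep = vals > 0
        runs_per_angle.append((vals[keep], lengths[keep]))
        if keep.any():
            max_run = max(max_run, int(lengths[keep].max()))
    for vals, lengths in runs_per_angle:
        mat = np.zeros((roi.n_levels, max_run))
        np.add.at(mat, (vals - 1, lengths - 1), 1)
        mats.append(mat)
    return mats


def glszm_matrix(roi: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix: entry (i-1, s-1) counts 8-connected zones of
    level i with s pixels."""
    structure = ndimage.generate_binary_structure(2, 2)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for level in range(1, roi.n_levels + 1):
        lab, n = ndimage.label((roi.levels == level) & roi.mask, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((level, int(s)))
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((roi.n_levels, max_size))
    for level, s in zones:
        mat[level - 1, s - 1] += 1
    return mat


_NEIGHBOR_OFFSETS_8 = [
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
]


def ngtdm_matrix(roi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Neighbouring gray-tone difference statistics.

    Returns ``(n_i, s_i, Nv)``: per-level pixel counts, per-level summed
    absolute deviation of each pixel from the mean of its in-mask
    8-neighbors, and the total in-mask pixel count. Pixels with no in-mask
    neighbor contribute zero deviation.
    """
    lv = np.where(roi.mask, roi.levels, 0).astype(float)
    m = roi.mask.astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    nb_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    n_i = np.zeros(roi.n_levels)
    s_i = np.zeros(roi.n_levels)
    inmask = roi.mask
    has_nb = inmask & (nb_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = np.abs(roi.levels - nb_sum / np.maximum(nb_cnt, 1))
    for level in range(1, roi.n_levels + 1):
        sel = inmask & (roi.levels == level)
        n_i[level - 1] = sel.sum()
        s_i[level - 1] = dev[sel & has_nb].sum()
    return n_i, s_i, int(inmask.sum())


def gldm_matrix(roi: DiscretizedROI, alpha: float = 0.0, distance: int = 1) -> np.ndarray:
    """Dependence matrix: entry (i-1, j) counts in-mask pixels of level i
    with exactly j dependent neighbors.

    A neighbor is any in-mask pixel within Chebyshev distance ``distance``
    whose level differs from the center by at most ``alpha``. A lone pixel
    has dependence 0 (column index 0).
    """
    h, w = roi.levels.shape
    dep = np.zeros((h, w), dtype=np.int64)
    offsets = [
        (dr, dc)
        for dr in range(-distance, distance + 1)
        for dc in range(-distance, distance + 1)
        if (dr, dc) != (0, 0)
    ]
    lv = roi.levels
    m = roi.mask
    for dr, dc in offsets:
        r0 = max(0, -dr)
        r1 = min(h, h - dr)
        c0 = max(0, -dc)
        c1 = min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        center = np.s_[r0:r1, c0:c1]
        nb = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = m[center] & m[nb] & (np.abs(lv[center] - lv[nb]) <= alpha)
        dep[center] += ok
    max_dep = int(dep[m].max()) if m.any() else 0
    mat = np.zeros((roi.n_levels, max_dep + 1))
    np.add.at(mat, (lv[m] - 1, dep[m]), 1)
    return mat
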