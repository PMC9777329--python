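"""Independent brute-force enumerators used as oracles for the texture
matrices. These walk pixels one at a time and share no code with the
package's vectorized builders."""

from __future__ import annotations

import numpy as np


def brute_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int, dr: int, dc: int) -> np.ndarray:
    """Symmetric co-occurrence counts at offset (dr, dc): every in-mask
    pair counted in both directions."""
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for sr, sc in ((dr, dc), (-dr, -dc)):
                r2, c2 = r + sr, c + sc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                    counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    return counts


def brute_runs(levels: np.ndarray, mask: np.ndarray, n_levels: int, dr: int, dc: int) -> np.ndarray:
    """Run-length counts along (dr, dc): maximal in-mask equal-level runs."""
    h, w = levels.shape
    runs = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            pr, pc = r - dr, c - dc  # predecessor along the direction
            if 0 <= pr < h and 0 <= pc < w and mask[pr, pc] and levels[pr, pc] == levels[r, c]:
                continue  # not a run start
            length = 1
            nr, nc = r + dr, c + dc
            while 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and levels[nr, nc] == levels[r, c]:
                length += 1
                nr += dr
                nc += dc
            runs.append((levels[r, c], length))
    max_run = max((ln for _, ln in runs), default=1)
    mat = np.zeros((n_levels, max_run))
    for lv, ln in runs:
        mat[lv - 1, ln - 1] += 1
    return mat


def brute_zones(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts via explicit 8-connected flood fill."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            level = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                cr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = cr + dr, cc + dc
                        if (
                            0 <= nr < h
                            and 0 <= nc < w
                            and mask[nr, nc]
                            and not seen[nr, nc]
                            and levels[nr, nc] == level
                        ):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            zones.append((level, size))
    max_size = max((s for _, s in zones), default=1)
    mat = np.zeros((n_levels, max_size))
    for lv, s in zones:
        mat[lv - 1, s - 1] += 1
    return mat


def brute_gldm(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: float, distance: int
) -> np.ndarray:
    """Dependence counts: per in-mask pixel, neighbors within Chebyshev
    ``distance`` whose level differs by at most alpha."""
    h, w = levels.shape
    deps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 0
            for dr in range(-distance, distance + 1):
                for dc in range(-distance, distance + 1):
                    if (dr, dc) == (0, 0):
                        continue
                    nr, nc = r + dr, c + dc
                    if (
                        0 <= nr < h
                        and 0 <= nc < w
                        and mask[nr, nc]
                        and abs(int(levels[nr, nc]) - int(levels[r, c])) <= alpha
                    ):
                        dep += 1
            deps.append((levels[r, c], dep))
    max_dep = max((d for _, d in deps), default=0)
    mat = np.zeros((n_levels, max_dep + 1))
    for lv, d in deps:
        mat[lv - 1, d] += 1
    return mat


def brute_ngtdm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level counts and summed |level - neighborhood mean|."""
    h, w = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            n_i[levels[r, c] - 1] += 1
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) == (0, 0):
                        continue
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                        nb.append(levels[nr, nc])
            if nb:
                s_i[levels[r, c] - 1] += abs(levels[r, c] - sum(nb) / len(nb))
    return n_i, s_i, int(mask.sum())


def random_roi(rng: np.random.Generator, max_side: int = 8, max_levels: int = 4):
    """A random small DiscretizedROI-compatible (levels, mask) pair."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    mask = rng.random((h, w)) < 0.75
    if not mask.any():
        mask[rng.integers(h), rng.integers(w)] = True
    levels = rng.integers(1, max_levels + 1, size=(h, w))
    levels = np.where(mask, levels, 0)
    return levels.astype(np.int64), mask
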