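"""Independent brute-force oracles, kept free of ccfd internals.

Each function recomputes a pipeline quantity by the most literal
possible method (per-pixel loops, exhaustive enumeration, direct
formula arithmetic) so the fast implementations can be checked against
something that cannot share their bugs.
"""

from itertools import combinations
from math import comb, exp, sqrt

import numpy as np


def gaussian_blur_oracle(pixels: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Direct separable Gaussian convolution with edge replication.

    Kernel radius matches the conventional int(truncate*sigma + 0.5).
    Returns floats (no quantization).
    """
    radius = int(truncate * sigma + 0.5)
    offsets = np.arange(-radius, radius + 1)
    k = np.exp(-(offsets**2) / (2.0 * sigma**2))
    k /= k.sum()
    padded = np.pad(pixels.astype(np.float64), radius, mode="edge")
    rows, cols = pixels.shape
    out = np.empty((rows, cols))
    for i in range(rows):
        for j in range(cols):
            win = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
            out[i, j] = k @ win @ k
    return out


def phansalkar_oracle(
    pixels: np.ndarray,
    max_value: int,
    radius: int,
    k: float = 0.25,
    r: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
    window_shape: str = "circular",
) -> np.ndarray:
    """Per-pixel recomputation of the Phansalkar deficit mask.

    Edge-replicated borders, population SD, strict `<` tie rule.
    """
    norm = pixels.astype(np.float64) / max_value
    padded = np.pad(norm, radius, mode="edge")
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    if window_shape == "circular":
        fp = (yy * yy + xx * xx) <= radius * radius
    else:
        fp = np.ones_like(yy, dtype=bool)
    rows, cols = norm.shape
    mask = np.zeros((rows, cols), dtype=bool)
    for i in range(rows):
        for j in range(cols):
            win = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1][fp]
            mu = win.mean()
            sd = sqrt(((win - mu) ** 2).mean())
            t = mu * (1.0 + p * exp(-q * mu) + k * (sd / r - 1.0))
            mask[i, j] = norm[i, j] < t
    return mask


def mann_whitney_exact_oracle(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating rank arrangements.

    Assumes no ties.  Returns (U of sample a, p).
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    na, nb = len(a), len(b)

    def u_of(rank_subset):
        return sum(rank_subset) - na * (na + 1) / 2

    u_obs = u_of([ranks[v] for v in a])
    us = [u_of(sub) for sub in combinations(range(1, na + nb + 1), na)]
    total = comb(na + nb, na)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def kruskal_h_oracle(groups) -> float:
    """Rank-sum H formula without tie correction (for tie-free data)."""
    pooled = sorted(v for g in groups for v in g)
    assert len(set(pooled)) == len(pooled)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(pooled)
    s = sum(sum(ranks[v] for v in g) ** 2 / len(g) for g in groups)
    return 12.0 / (n * (n + 1)) * s - 3 * (n + 1)


def welch_oracle(a, b) -> tuple[float, float]:
    """Welch t statistic and Satterthwaite df by direct formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df


def component_sizes_oracle(mask: np.ndarray, connectivity: int) -> list[int]:
    """Flood-fill component sizes, descending."""
    mask = mask.astype(bool)
    rows, cols = mask.shape
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    sizes = []
    for si in range(rows):
        for sj in range(cols):
            if not mask[si, sj] or seen[si, sj]:
                continue
            stack, size = [(si, sj)], 0
            seen[si, sj] = True
            while stack:
                i, j = stack.pop()
                size += 1
                for di, dj in nbrs:
                    ni, nj = i + di, j + dj
                    if 0 <= ni < rows and 0 <= nj < cols and mask[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        stack.append((ni, nj))
            sizes.append(size)
    return sorted(sizes, reverse=True)
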