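"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain nested loops / textbook formulas,
deliberately sharing no code with the package: these are the reference
answers the fast implementations must reproduce.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


# ---------------------------------------------------------------- GLCM

def glcm_bruteforce(levels: np.ndarray, ng: int, offsets, symmetric: bool
                    ) -> np.ndarray:
    """Co-occurrence counts by looping over every voxel pair."""
    counts = np.zeros((ng, ng), dtype=float)
    nx, ny, nz = levels.shape
    for dx, dy, dz in offsets:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    x2, y2, z2 = x + dx, y + dy, z + dz
                    if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz:
                        a, b = levels[x, y, z] - 1, levels[x2, y2, z2] - 1
                        counts[a, b] += 1
                        if symmetric:
                            counts[b, a] += 1
    return counts


# ---------------------------------------------------------------- NGTDM

def ngtdm_bruteforce(levels: np.ndarray, ng: int):
    """(n_i, s_i) by looping over voxels with complete 26-neighborhoods."""
    nx, ny, nz = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for x in range(1, nx - 1):
        for y in range(1, ny - 1):
            for z in range(1, nz - 1):
                total = 0.0
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if dx == dy == dz == 0:
                                continue
                            total += levels[x + dx, y + dy, z + dz]
                mean = total / 26.0
                lv = levels[x, y, z]
                n_i[lv - 1] += 1
                s_i[lv - 1] += abs(lv - mean)
    return n_i, s_i


# ---------------------------------------------------------------- GLSZM

def glszm_bruteforce(levels: np.ndarray, ng: int) -> dict[tuple[int, int], int]:
    """Zone counts {(level, size): count} via 26-connected flood fill."""
    nx, ny, nz = levels.shape
    seen = np.zeros(levels.shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if seen[x, y, z]:
                    continue
                lv = levels[x, y, z]
                size = 0
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    cx, cy, cz = queue.popleft()
                    size += 1
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                if dx == dy == dz == 0:
                                    continue
                                nx2, ny2, nz2 = cx + dx, cy + dy, cz + dz
                                if (0 <= nx2 < nx and 0 <= ny2 < ny
                                        and 0 <= nz2 < nz
                                        and not seen[nx2, ny2, nz2]
                                        and levels[nx2, ny2, nz2] == lv):
                                    seen[nx2, ny2, nz2] = True
                                    queue.append((nx2, ny2, nz2))
                zones[(lv, size)] = zones.get((lv, size), 0) + 1
    return zones


def glszm_features_bruteforce(zones: dict[tuple[int, int], int], n_v: int
                              ) -> dict[str, float]:
    """The 11 size-zone features evaluated term by term from zone counts."""
    n_z = sum(zones.values())
    f = dict.fromkeys(
        ["sze", "lze", "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge"], 0.0
    )
    by_level: dict[int, float] = {}
    by_size: dict[int, float] = {}
    for (i, s), c in zones.items():
        f["sze"] += c / s**2
        f["lze"] += c * s**2
        f["lgze"] += c / i**2
        f["hgze"] += c * i**2
        f["szlge"] += c / (i**2 * s**2)
        f["szhge"] += c * i**2 / s**2
        f["lzlge"] += c * s**2 / i**2
        f["lzhge"] += c * i**2 * s**2
        by_level[i] = by_level.get(i, 0) + c
        by_size[s] = by_size.get(s, 0) + c
    out = {k: v / n_z for k, v in f.items()}
    out["gln"] = sum(v**2 for v in by_level.values()) / n_z
    out["zsn"] = sum(v**2 for v in by_size.values()) / n_z
    out["zp"] = n_z / n_v
    return out


# ---------------------------------------------------------------- GLCM features

def glcm_features_bruteforce(p: np.ndarray) -> dict[str, float]:
    """The 19 co-occurrence features from literal double sums over (i, j)."""
    ng = p.shape[0]
    log2 = lambda v: math.log2(v) if v > 0 else 0.0
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))
    pxy_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    pxy_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            pxy_sum[i + j + 2] += p[i, j]
            pxy_diff[abs(i - j)] += p[i, j]
    asm = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    contrast = sum(k**2 * v for k, v in pxy_diff.items())
    if sx > 0 and sy > 0:
        corr = (sum((i + 1) * (j + 1) * p[i, j]
                    for i in range(ng) for j in range(ng)) - mux * muy) / (sx * sy)
    else:
        corr = 0.0
    ssq = sum((i + 1 - mux) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    homog = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    sum_avg = sum(k * v for k, v in pxy_sum.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in pxy_sum.items())
    sum_ent = -sum(v * log2(v) for v in pxy_sum.values())
    entropy = -sum(p[i, j] * log2(p[i, j]) for i in range(ng) for j in range(ng))
    diff_avg = sum(k * v for k, v in pxy_diff.items())
    diff_var = sum((k - diff_avg) ** 2 * v for k, v in pxy_diff.items())
    diff_ent = -sum(v * log2(v) for v in pxy_diff.values())
    hx = -sum(v * log2(v) for v in px)
    hy = -sum(v * log2(v) for v in py)
    hxy1 = -sum(p[i, j] * log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if p[i, j] > 0)
    hxy2 = -sum(px[i] * py[j] * log2(px[i] * py[j])
                for i in range(ng) for j in range(ng))
    ic1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    ic2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - entropy))))
    autoc = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    dissim = sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng))
    shade = sum((i + j + 2 - mux - muy) ** 3 * p[i, j]
                for i in range(ng) for j in range(ng))
    prom = sum((i + j + 2 - mux - muy) ** 4 * p[i, j]
               for i in range(ng) for j in range(ng))
    inv_diff = sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    return {
        "glcm_angular_second_moment": asm,
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_sum_of_squares_variance": ssq,
        "glcm_homogeneity": homog,
        "glcm_sum_average": sum_avg,
        "glcm_sum_variance": sum_var,
        "glcm_sum_entropy": sum_ent,
        "glcm_entropy": entropy,
        "glcm_difference_variance": diff_var,
        "glcm_difference_entropy": diff_ent,
        "glcm_information_correlation_1": ic1,
        "glcm_information_correlation_2": ic2,
        "glcm_autocorrelation": autoc,
        "glcm_dissimilarity": dissim,
        "glcm_cluster_shade": shade,
        "glcm_cluster_prominence": prom,
        "glcm_maximum_probability": float(np.max(p)),
        "glcm_inverse_difference": inv_diff,
    }


# ---------------------------------------------------------------- NGTDM features

def ngtdm_features_bruteforce(n_i: np.ndarray, s_i: np.ndarray, eps: float = 1e-6
                              ) -> dict[str, float]:
    """Amadasun's five features evaluated from explicit (p_i, s_i) sums."""
    n = n_i.sum()
    ng = len(n_i)
    p = n_i / n
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    psum = sum(p[i] * s_i[i] for i in range(ng))
    coarseness = 1.0 / (eps + psum)
    if ngp <= 1:
        return {"ngtdm_coarseness": coarseness, "ngtdm_contrast": 0.0,
                "ngtdm_busyness": 0.0, "ngtdm_complexity": 0.0,
                "ngtdm_strength": 0.0}
    contrast = (
        sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
        / (ngp * (ngp - 1))
    ) * (s_i.sum() / n)
    busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                   for i in present for j in present)
    busyness = psum / busy_den if busy_den > 0 else 0.0
    complexity = sum(
        abs(i - j) / (n * (p[i] + p[j])) * (p[i] * s_i[i] + p[j] * s_i[j])
        for i in present for j in present
    )
    strength = sum((p[i] + p[j]) * (i - j) ** 2
                   for i in present for j in present) / (eps + s_i.sum())
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


# ---------------------------------------------------------------- histogram

def histogram_features_bruteforce(levels: np.ndarray, ng: int
                                  ) -> dict[str, float]:
    x = [float(v) for v in levels.ravel()]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    if var > 0:
        skew = sum((v - mean) ** 3 for v in x) / n / var**1.5
        kurt = sum((v - mean) ** 4 for v in x) / n / var**2 - 3
    else:
        skew = kurt = 0.0
    h = [sum(1 for v in x if v == k) / n for k in range(1, ng + 1)]
    energy = sum(v**2 for v in h)
    entropy = -sum(v * math.log2(v) for v in h if v > 0)
    return {
        "hist_mean": mean, "hist_variance": var, "hist_skewness": skew,
        "hist_kurtosis": kurt, "hist_energy": energy, "hist_entropy": entropy,
    }


# ---------------------------------------------------------------- statistics

def kruskal_h_bruteforce(samples: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from the textbook rank formula."""
    pooled = np.concatenate(samples)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2 + 1  # average rank for ties
        i = j + 1
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start: start + len(s)]
        h += len(s) * (r.mean() - (n + 1) / 2) ** 2
        start += len(s)
    h *= 12.0 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    ties = 1.0 - sum(c**3 - c for c in counts) / (n**3 - n)
    return h / ties


def spearman_rho_closed_form(x: np.ndarray, y: np.ndarray) -> float:
    """1 - 6*sum(d^2)/(n(n^2-1)) — valid only for untied vectors."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = float(np.sum((rx - ry) ** 2))
    n = len(x)
    return 1 - 6 * d2 / (n * (n**2 - 1))


def auc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) Mann-Whitney AUC: ties between classes count half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))
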