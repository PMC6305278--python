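"""Texture matrices built from a quantized patch: GLCM, NGTDM, GLSZM.

Conventions (the underlying references leave several free parameters; the
choices here are the common radiomics defaults):

* GLCM: the 13 unique 3D direction offsets at a given voxel distance, pairs
  counted in both orders (symmetric), counts pooled across directions and
  then normalized to sum 1.  An axial-only 4-direction mode is available.
* NGTDM: only voxels with a complete 26-neighborhood contribute (on a
  3-slice patch that is the interior of the middle slice); the neighborhood
  mean excludes the centre voxel.
* GLSZM: zones are maximal 26-connected components of equal gray level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import QuantizedPatch

# 13 unique direction offsets covering all 26 3D neighbors up to sign.
OFFSETS_3D_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0),
    (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

# In-plane (axial) offsets only: 4 unique 2D directions.
OFFSETS_AXIAL_4 = ((1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0))


@dataclass
class GLCM:
    """Normalized gray-level co-occurrence matrix with derived marginals.

    ``p`` is the Ng x Ng joint probability of level pairs at the configured
    offsets.  Marginals, means/SDs and entropy terms are precomputed because
    nearly every derived feature needs them.
    """

    p: np.ndarray
    ng: int
    symmetric: bool = True
    # derived quantities, filled in __post_init__
    px: np.ndarray = field(init=False)
    py: np.ndarray = field(init=False)
    p_xplusy: np.ndarray = field(init=False)   # index k-2 holds k = i+j, k=2..2Ng
    p_xminusy: np.ndarray = field(init=False)  # index k holds k = |i-j|, k=0..Ng-1
    mu_x: float = field(init=False)
    mu_y: float = field(init=False)
    sigma_x: float = field(init=False)
    sigma_y: float = field(init=False)
    hx: float = field(init=False)
    hy: float = field(init=False)
    hxy: float = field(init=False)
    hxy1: float = field(init=False)
    hxy2: float = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.ng, self.ng):
            raise ValueError(f"GLCM must be {self.ng}x{self.ng}, got {p.shape}")
        if p.min() < 0:
            raise ValueError("GLCM has negative entries")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"GLCM not normalized: sum = {p.sum()}")
        self.p = p
        i = np.arange(1, self.ng + 1, dtype=float)
        self.px = p.sum(axis=1)
        self.py = p.sum(axis=0)
        # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
        ii, jj = np.meshgrid(i, i, indexing="ij")
        sums = (ii + jj).astype(int)
        diffs = np.abs(ii - jj).astype(int)
        self.p_xplusy = np.bincount(
            (sums - 2).ravel(), weights=p.ravel(), minlength=2 * self.ng - 1
        )
        self.p_xminusy = np.bincount(
            diffs.ravel(), weights=p.ravel(), minlength=self.ng
        )
        self.mu_x = float(i @ self.px)
        self.mu_y = float(i @ self.py)
        self.sigma_x = float(np.sqrt(((i - self.mu_x) ** 2) @ self.px))
        self.sigma_y = float(np.sqrt(((i - self.mu_y) ** 2) @ self.py))
        self.hx = _entropy(self.px)
        self.hy = _entropy(self.py)
        self.hxy = _entropy(p)
        pxpy = np.outer(self.px, self.py)
        mask = p > 0
        self.hxy1 = float(-np.sum(p[mask] * _safe_log2(pxpy[mask])))
        self.hxy2 = _entropy(pxpy)


def _safe_log2(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = np.log2(x[pos])
    return out


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits; zero-probability terms contribute 0."""
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def compute_glcm(
    q: QuantizedPatch,
    distance: int = 1,
    symmetric: bool = True,
    directions: str = "13",
    offsets=None,
) -> GLCM:
    """Accumulate level co-occurrences over 3D offsets and normalize.

    Parameters
    ----------
    q : QuantizedPatch
    distance : int
        Offset magnitude in voxels along each direction component.
    symmetric : bool
        Count each ordered pair in both orders (standard Haralick symmetry).
    directions : {"13", "axial-4"}
        13 unique 3D offsets (default) or the 4 in-plane offsets.
    offsets : sequence of (dx, dy, dz), optional
        Explicit direction list overriding ``directions`` (used by tests
        that probe a single offset).
    """
    if distance < 1:
        raise ValueError(f"offset distance must be >= 1, got {distance}")
    if offsets is None:
        if directions == "13":
            offsets = OFFSETS_3D_13
        elif directions == "axial-4":
            offsets = OFFSETS_AXIAL_4
        else:
            raise ValueError(f"unknown direction set: {directions!r}")
    levels = q.levels
    ng = q.ng
    counts = np.zeros((ng, ng), dtype=float)
    for off in offsets:
        dx, dy, dz = (int(distance) * int(c) for c in off)
        src = _shift_slice(levels.shape, (dx, dy, dz), source=True)
        dst = _shift_slice(levels.shape, (dx, dy, dz), source=False)
        a = levels[src].ravel() - 1
        b = levels[dst].ravel() - 1
        np.add.at(counts, (a, b), 1.0)
        if symmetric:
            np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("patch too small for the requested GLCM offsets")
    return GLCM(p=counts / total, ng=ng, symmetric=symmetric)


def _shift_slice(shape, offset, source: bool):
    """Slices selecting voxel pairs (v, v+offset) both inside the array."""
    sl = []
    for n, d in zip(shape, offset):
        if d >= 0:
            sl.append(slice(0, n - d) if source else slice(d, n))
        else:
            sl.append(slice(-d, n) if source else slice(0, n + d))
    return tuple(sl)


@dataclass
class NGTDM:
    """Neighborhood gray-tone difference accumulator.

    For each level i: ``n_i`` counts contributing voxels, ``p_i = n_i / n``,
    and ``s_i`` sums |i - neighborhood mean| over those voxels.  Only voxels
    whose full 26-neighborhood lies inside the patch contribute.
    """

    n_i: np.ndarray
    s_i: np.ndarray
    ng: int

    def __post_init__(self) -> None:
        self.n_i = np.asarray(self.n_i, dtype=float)
        self.s_i = np.asarray(self.s_i, dtype=float)
        if self.n_i.shape != (self.ng,) or self.s_i.shape != (self.ng,):
            raise ValueError("n_i and s_i must have one entry per gray level")
        if self.n_i.sum() <= 0:
            raise ValueError("no voxel has a complete neighborhood")

    @property
    def n(self) -> float:
        return float(self.n_i.sum())

    @property
    def p_i(self) -> np.ndarray:
        return self.n_i / self.n

    @property
    def n_gp(self) -> int:
        """Number of gray levels actually present among valid voxels."""
        return int(np.count_nonzero(self.n_i))


def compute_ngtdm(q: QuantizedPatch) -> NGTDM:
    """Build the NGTDM from voxels with complete 26-neighborhoods."""
    levels = q.levels.astype(float)
    if any(s < 3 for s in levels.shape):
        raise ValueError(
            f"patch shape {levels.shape} has no voxel with a complete "
            "26-neighborhood"
        )
    # Neighborhood sum via a 3x3x3 box filter; subtract the centre, divide by 26.
    kernel = np.ones((3, 3, 3))
    box = ndimage.convolve(levels, kernel, mode="constant", cval=0.0)
    nbr_mean = (box - levels) / 26.0
    interior = (slice(1, -1),) * 3
    lv = q.levels[interior].ravel()
    dev = np.abs(levels[interior] - nbr_mean[interior]).ravel()
    n_i = np.bincount(lv - 1, minlength=q.ng).astype(float)
    s_i = np.bincount(lv - 1, weights=dev, minlength=q.ng)
    return NGTDM(n_i=n_i, s_i=s_i, ng=q.ng)


@dataclass
class GLSZM:
    """Gray-level size-zone matrix.

    ``z[i-1, s-1]`` counts the 26-connected zones of level i and size s.
    Zone sizes partition the patch: sum over i, s of s * z = voxel count.
    """

    z: np.ndarray
    ng: int
    n_v: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape[0] != self.ng:
            raise ValueError("GLSZM must have one row per gray level")
        sizes = np.arange(1, self.z.shape[1] + 1, dtype=float)
        covered = float((self.z * sizes).sum())
        if covered != float(self.n_v):
            raise ValueError(
                f"zone partition covers {covered} voxels, patch has {self.n_v}"
            )

    @property
    def n_z(self) -> float:
        return float(self.z.sum())


_STRUCTURES = {
    26: np.ones((3, 3, 3), dtype=int),
    6: ndimage.generate_binary_structure(3, 1),
}


def compute_glszm(q: QuantizedPatch, connectivity: int = 26) -> GLSZM:
    """Label equal-level connected zones and tally them by level and size."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    structure = _STRUCTURES[connectivity]
    levels = q.levels
    n_v = int(levels.size)
    max_size = n_v
    z = np.zeros((q.ng, max_size), dtype=float)
    largest = 0
    for level in np.unique(levels):
        labeled, n_comp = ndimage.label(levels == level, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]  # drop background count
        for s in sizes:
            z[level - 1, s - 1] += 1
            largest = max(largest, int(s))
    return GLSZM(z=z[:, :largest], ng=q.ng, n_v=n_v)
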