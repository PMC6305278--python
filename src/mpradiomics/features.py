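"""The 41 radiomic features: 6 histogram, 19 GLCM, 5 NGTDM, 11 GLSZM.

Histogram features are computed on the quantized gray levels (not raw
intensities) so they are commensurate across scanners.  Degenerate patches
(zero variance, single gray level) yield finite vectors by explicit
convention rather than NaNs: correlation, skewness and kurtosis default to
0, coarseness is capped at 1/eps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import QuantizedPatch
from .texture import GLCM, GLSZM, NGTDM, _entropy

logger = logging.getLogger(__name__)

COARSENESS_EPS = 1e-6

HISTOGRAM_FEATURES = (
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_energy",
    "hist_entropy",
)

GLCM_FEATURES = (
    "glcm_angular_second_moment",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_sum_of_squares_variance",
    "glcm_homogeneity",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_entropy",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_information_correlation_1",
    "glcm_information_correlation_2",
    "glcm_autocorrelation",
    "glcm_dissimilarity",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_maximum_probability",
    "glcm_inverse_difference",
)

NGTDM_FEATURES = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
)

GLSZM_FEATURES = (
    "glszm_small_zone_emphasis",
    "glszm_large_zone_emphasis",
    "glszm_low_gray_level_zone_emphasis",
    "glszm_high_gray_level_zone_emphasis",
    "glszm_small_zone_low_gray_emphasis",
    "glszm_small_zone_high_gray_emphasis",
    "glszm_large_zone_low_gray_emphasis",
    "glszm_large_zone_high_gray_emphasis",
    "glszm_gray_level_non_uniformity",
    "glszm_zone_size_non_uniformity",
    "glszm_zone_size_percentage",
)

#: canonical order of the 41 features
FEATURE_NAMES = HISTOGRAM_FEATURES + GLCM_FEATURES + NGTDM_FEATURES + GLSZM_FEATURES


def histogram_features(q: QuantizedPatch) -> dict[str, float]:
    """First-order statistics of the quantized gray-level histogram."""
    x = q.levels.ravel().astype(float)
    mean = float(x.mean())
    var = float(x.var())
    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / sd**4 - 3.0)
    else:
        skew = kurt = 0.0
    h = np.bincount(q.levels.ravel() - 1, minlength=q.ng) / x.size
    return {
        "hist_mean": mean,
        "hist_variance": var,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_energy": float(np.sum(h**2)),
        "hist_entropy": _entropy(h),
    }


def glcm_features(m: GLCM) -> dict[str, float]:
    """The 19 co-occurrence features (Haralick/Soh conventions)."""
    p = m.p
    ng = m.ng
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)    # i + j
    k_diff = np.arange(0, ng, dtype=float)           # |i - j|

    asm = float(np.sum(p**2))
    contrast = float((k_diff**2) @ m.p_xminusy)
    if m.sigma_x > 0 and m.sigma_y > 0:
        corr = float((np.sum(ii * jj * p) - m.mu_x * m.mu_y)
                     / (m.sigma_x * m.sigma_y))
    else:
        corr = 0.0
    ssq_var = float(np.sum((ii - m.mu_x) ** 2 * p))
    homogeneity = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    sum_avg = float(k_sum @ m.p_xplusy)
    sum_var = float(((k_sum - sum_avg) ** 2) @ m.p_xplusy)
    sum_ent = _entropy(m.p_xplusy)
    entropy = m.hxy
    diff_avg = float(k_diff @ m.p_xminusy)
    diff_var = float(((k_diff - diff_avg) ** 2) @ m.p_xminusy)
    diff_ent = _entropy(m.p_xminusy)
    hmax = max(m.hx, m.hy)
    ic1 = float((m.hxy - m.hxy1) / hmax) if hmax > 0 else 0.0
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (m.hxy2 - m.hxy)))))
    autocorr = float(np.sum(ii * jj * p))
    dissim = float(k_diff @ m.p_xminusy)
    dev = ii + jj - m.mu_x - m.mu_y
    shade = float(np.sum(dev**3 * p))
    prominence = float(np.sum(dev**4 * p))
    max_prob = float(p.max())
    inv_diff = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    return {
        "glcm_angular_second_moment": asm,
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_sum_of_squares_variance": ssq_var,
        "glcm_homogeneity": homogeneity,
        "glcm_sum_average": sum_avg,
        "glcm_sum_variance": sum_var,
        "glcm_sum_entropy": sum_ent,
        "glcm_entropy": entropy,
        "glcm_difference_variance": diff_var,
        "glcm_difference_entropy": diff_ent,
        "glcm_information_correlation_1": ic1,
        "glcm_information_correlation_2": ic2,
        "glcm_autocorrelation": autocorr,
        "glcm_dissimilarity": dissim,
        "glcm_cluster_shade": shade,
        "glcm_cluster_prominence": prominence,
        "glcm_maximum_probability": max_prob,
        "glcm_inverse_difference": inv_diff,
    }


def ngtdm_features(m: NGTDM, eps: float = COARSENESS_EPS) -> dict[str, float]:
    """Amadasun's five neighborhood gray-tone difference features."""
    p = m.p_i
    s = m.s_i
    n = m.n
    present = p > 0
    i = np.arange(1, m.ng + 1, dtype=float)
    psum = float(p @ s)
    coarseness = 1.0 / (eps + psum)
    if m.n_gp <= 1:
        # single gray level: no tone differences to measure
        return {
            "ngtdm_coarseness": coarseness,
            "ngtdm_contrast": 0.0,
            "ngtdm_busyness": 0.0,
            "ngtdm_complexity": 0.0,
            "ngtdm_strength": 0.0,
        }
    ip = i[present]
    pp = p[present]
    sp = s[present]
    di = ip[:, None] - ip[None, :]
    contrast = float(
        np.sum(pp[:, None] * pp[None, :] * di**2)
        / (m.n_gp * (m.n_gp - 1))
        * (s.sum() / n)
    )
    busy_den = float(np.sum(np.abs(ip[:, None] * pp[:, None]
                                   - ip[None, :] * pp[None, :])))
    busyness = psum / busy_den if busy_den > 0 else 0.0
    complexity = float(
        np.sum(
            np.abs(di)
            / (n * (pp[:, None] + pp[None, :]))
            * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
        )
    )
    strength = float(np.sum((pp[:, None] + pp[None, :]) * di**2) / (eps + s.sum()))
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


def glszm_features(m: GLSZM) -> dict[str, float]:
    """Thibault's eleven size-zone features."""
    z = m.z
    if m.n_z < 1:
        raise ValueError("empty size-zone matrix")
    nz = m.n_z
    i = np.arange(1, m.ng + 1, dtype=float)[:, None]
    s = np.arange(1, z.shape[1] + 1, dtype=float)[None, :]
    zone_by_size = z.sum(axis=0)
    zone_by_level = z.sum(axis=1)
    return {
        "glszm_small_zone_emphasis": float(np.sum(z / s**2) / nz),
        "glszm_large_zone_emphasis": float(np.sum(z * s**2) / nz),
        "glszm_low_gray_level_zone_emphasis": float(np.sum(z / i**2) / nz),
        "glszm_high_gray_level_zone_emphasis": float(np.sum(z * i**2) / nz),
        "glszm_small_zone_low_gray_emphasis": float(np.sum(z / (i**2 * s**2)) / nz),
        "glszm_small_zone_high_gray_emphasis": float(np.sum(z * i**2 / s**2) / nz),
        "glszm_large_zone_low_gray_emphasis": float(np.sum(z * s**2 / i**2) / nz),
        "glszm_large_zone_high_gray_emphasis": float(np.sum(z * i**2 * s**2) / nz),
        "glszm_gray_level_non_uniformity": float(np.sum(zone_by_level**2) / nz),
        "glszm_zone_size_non_uniformity": float(np.sum(zone_by_size**2) / nz),
        "glszm_zone_size_percentage": float(nz / m.n_v),
    }


def compute_feature_vector(
    q: QuantizedPatch,
    glcm_kwargs: dict | None = None,
    glszm_connectivity: int = 26,
) -> dict[str, float]:
    """All 41 features of one quantized patch, in canonical order."""
    from .texture import compute_glcm, compute_glszm, compute_ngtdm

    out: dict[str, float] = {}
    out.update(histogram_features(q))
    out.update(glcm_features(compute_glcm(q, **(glcm_kwargs or {}))))
    out.update(ngtdm_features(compute_ngtdm(q)))
    out.update(glszm_features(compute_glszm(q, connectivity=glszm_connectivity)))
    return {name: out[name] for name in FEATURE_NAMES}


def extract_patient_features(
    t2: QuantizedPatch | None,
    adc: QuantizedPatch | None,
    mode: str = "mean",
    **kwargs,
) -> pd.Series:
    """Per-patient 41-feature vector, per modality or modality-averaged.

    ``mean`` returns the elementwise arithmetic mean of the T2 and ADC
    feature vectors; ``T2`` / ``ADC`` return the single-modality vector.
    """
    if mode == "mean":
        if t2 is None or adc is None:
            raise ValueError("mean mode requires both T2 and ADC patches")
        if t2.ng != adc.ng:
            raise ValueError(
                f"modalities quantized with different Ng: {t2.ng} vs {adc.ng}"
            )
        a = pd.Series(compute_feature_vector(t2, **kwargs))
        b = pd.Series(compute_feature_vector(adc, **kwargs))
        vec = (a + b) / 2.0
    elif mode == "T2":
        if t2 is None:
            raise ValueError("T2 mode requires a T2 patch")
        vec = pd.Series(compute_feature_vector(t2, **kwargs))
    elif mode == "ADC":
        if adc is None:
            raise ValueError("ADC mode requires an ADC patch")
        vec = pd.Series(compute_feature_vector(adc, **kwargs))
    else:
        raise ValueError(f"unknown feature mode: {mode!r}")
    vec.attrs["modality"] = mode
    return vec


@dataclass
class CohortFeatureTable:
    """Patients x 41 feature matrix with group labels.

    ``scaled`` records whether cohort min-max scaling has been applied;
    ``scaling_params`` holds per-feature (min, range) fitted on this cohort
    so held-out patients can be transformed consistently.
    """

    data: pd.DataFrame          # index: patient_id, columns: FEATURE_NAMES
    groups: pd.Series           # index: patient_id, values in 1..k
    scaled: bool = False
    scaling_params: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing[:3]}...")
        self.data = self.data[list(FEATURE_NAMES)]
        if not self.data.index.equals(self.groups.index):
            raise ValueError("feature matrix and group labels misaligned")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scaled: bool = False
                   ) -> "CohortFeatureTable":
        return cls(
            data=frame[list(FEATURE_NAMES)],
            groups=frame["group"].astype(int),
            scaled=scaled,
        )


def scale_features(table: CohortFeatureTable) -> CohortFeatureTable:
    """Min-max scale every feature column to [0, 1] over the cohort.

    Constant columns map to zeros (with a warning).  The fitted (min, range)
    parameters are stored on the returned table; applying them to held-out
    patients may legitimately produce values outside [0, 1] — no clipping.
    """
    if table.scaled:
        raise ValueError("feature table is already scaled")
    if table.n_patients < 2:
        raise ValueError("need at least 2 patients to fit scaling")
    lo = table.data.min(axis=0)
    rng = table.data.max(axis=0) - lo
    constant = rng == 0
    if constant.any():
        logger.warning(
            "constant feature columns scaled to zeros: %s",
            list(table.data.columns[constant]),
        )
    safe_rng = rng.replace(0, 1.0)
    scaled = (table.data - lo) / safe_rng
    scaled.loc[:, constant] = 0.0
    params = pd.DataFrame({"min": lo, "range": safe_rng})
    return CohortFeatureTable(
        data=scaled, groups=table.groups, scaled=True, scaling_params=params
    )


def apply_scaling(data: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Transform new rows with previously fitted min/range (no clipping)."""
    return (data[params.index] - params["min"]) / params["range"]
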