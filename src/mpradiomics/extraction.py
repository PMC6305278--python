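"""Cohort-level feature extraction: volumes -> patients x 41 tables.

Glue between the imaging primitives and the statistics: for every patient,
normalize each modality's volume, cut the lesion-centred 21x21x3 ROI,
quantize it to 32 levels and evaluate the 41 features, per requested
feature mode (modality-averaged "mean", or single-modality "T2"/"ADC").
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .features import (
    FEATURE_NAMES,
    CohortFeatureTable,
    extract_patient_features,
    scale_features,
)
from .imaging import (
    DEFAULT_NG,
    MRIVolume,
    extract_roi,
    gleason_to_group,
    normalize_volume,
    quantize,
)

logger = logging.getLogger(__name__)

FEATURE_MODES = ("mean", "T2", "ADC")


def patient_quantized_patches(
    t2: MRIVolume,
    adc: MRIVolume,
    centroid,
    patient_id: str = "",
    ng: int = DEFAULT_NG,
    normalization: str = "minmax",
):
    """Normalize both volumes, cut the ROI at the centroid and quantize."""
    patches = {}
    for vol in (t2, adc):
        norm = normalize_volume(vol, method=normalization)
        roi = extract_roi(norm, centroid, patient_id=patient_id)
        patches[vol.modality] = quantize(roi, ng=ng)
    return patches["T2"], patches["ADC"]


def extract_cohort_tables(
    patients,
    modes=("mean",),
    ng: int = DEFAULT_NG,
    scale: bool = True,
    grouping: str = "three",
    normalization: str = "minmax",
) -> dict[str, CohortFeatureTable]:
    """Feature tables for a cohort of patients, one per feature mode.

    ``patients`` is an iterable of objects with ``patient_id``,
    ``t2_volume``, ``adc_volume`` and ``lesion`` attributes (synthetic
    patients or loaded real ones).  Group labels are derived from each
    lesion's Gleason score under the requested grouping scheme.
    """
    bad = [m for m in modes if m not in FEATURE_MODES]
    if bad:
        raise ValueError(f"unknown feature modes: {bad}")
    rows: dict[str, list[pd.Series]] = {m: [] for m in modes}
    ids, groups = [], []
    for p in patients:
        t2q, adcq = patient_quantized_patches(
            p.t2_volume, p.adc_volume, p.lesion.centroid,
            patient_id=p.patient_id, ng=ng, normalization=normalization,
        )
        for m in modes:
            rows[m].append(extract_patient_features(t2q, adcq, mode=m))
        ids.append(p.patient_id)
        groups.append(gleason_to_group(p.lesion.gleason_score, scheme=grouping))
    group_series = pd.Series(groups, index=ids, name="group")
    tables = {}
    for m in modes:
        data = pd.DataFrame(rows[m], index=ids)
        table = CohortFeatureTable(data=data, groups=group_series)
        tables[m] = scale_features(table) if scale else table
    return tables


def patches_to_table(
    patch_pairs,
    groups,
    mode: str = "mean",
    scale: bool = True,
) -> CohortFeatureTable:
    """Feature table straight from quantized patch pairs (no volume I/O).

    Used for patch-level simulation studies where generating and re-reading
    full volumes adds nothing: ``patch_pairs`` is a sequence of
    (t2_patch, adc_patch) QuantizedPatch tuples.
    """
    rows = [
        extract_patient_features(t2q, adcq, mode=mode)
        for t2q, adcq in patch_pairs
    ]
    ids = [f"P{i:04d}" for i in range(len(rows))]
    data = pd.DataFrame(rows, index=ids)
    table = CohortFeatureTable(
        data=data, groups=pd.Series(list(groups), index=ids, name="group")
    )
    return scale_features(table) if scale else table


class RadiomicFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping quantized patch pairs to the 41-feature matrix.

    ``X`` is a sequence of (t2, adc) QuantizedPatch pairs; ``transform``
    returns an (n_patients, 41) array in canonical feature order.  The
    transformer is stateless (``fit`` records only the feature names) and
    exists so the extraction step composes with scikit-learn pipelines.
    """

    def __init__(self, mode: str = "mean"):
        self.mode = mode

    def fit(self, X, y=None) -> "RadiomicFeatureExtractor":
        if self.mode not in FEATURE_MODES:
            raise ValueError(f"unknown feature mode: {self.mode!r}")
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        if self.mode not in FEATURE_MODES:
            raise ValueError(f"unknown feature mode: {self.mode!r}")
        rows = [
            extract_patient_features(t2q, adcq, mode=self.mode).to_numpy()
            for t2q, adcq in X
        ]
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
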