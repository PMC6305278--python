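# mpradiomics

Radiomic texture analysis of paired prostate mpMRI (T2-weighted + ADC) for
predicting Gleason-score groups.

Biopsy-based Gleason grading is invasive and prone to sampling error, so
image-derived surrogates of tumour grade are of real clinical interest.
This package implements a complete radiomic pipeline for that question:
given a pair of co-acquired MRI volumes per patient (T2-WI and an ADC map)
and a lesion centroid, it

1. cuts a lesion-centred sub-volume of **21 × 21 × 3 voxels** from each
   modality and uniformly quantizes it to **Ng = 32** gray levels;
2. computes **41 radiomic features** per patient — 6 first-order histogram
   statistics, 19 gray-level co-occurrence (GLCM) features, 5 neighborhood
   gray-tone difference (NGTDM) features and 11 gray-level size-zone
   (GLSZM) features — averaged across the two modalities;
3. screens each feature for association with the Gleason groups
   G1 (GS ≤ 6), G2 (GS = 3+4), G3 (GS ≥ 4+3) using the Kruskal–Wallis
   rank test and Spearman rank correlation with the ordinal group index,
   with step-down **Holm–Bonferroni** control of the family-wise error;
4. classifies groups one-vs-rest with a **500-tree random forest**
   (stratified 5-fold cross-validation, plus a balanced 40/20
   train/test hold-out) reporting AUC, accuracy, NPV and PPV; and
5. ranks features by **out-of-bag permutation importance**: the per-tree
   increase in OOB error after permuting one feature, normalized by the
   SD of the per-tree increases and averaged over folds.

Because clinical imaging archives cannot be bundled, the package ships a
**synthetic cohort generator** that emulates the one statistical property
this analysis hinges on: the spatial zone-size structure of the lesion.
Group-1 lesions are composed of a few large homogeneous blobs, group-3
lesions of many small fragmented ones, so large-zone-size emphasis falls —
and zone-size percentage rises — with grade, and the full pipeline can be
exercised and validated end to end.

## The statistics in brief

For a quantized patch with gray levels 1..Ng, the GLSZM entry Z(i, s)
counts the maximal 26-connected zones of level *i* and size *s* voxels.
With N_z = ΣΣ Z total zones and N_v voxels, the three headline features
are

- large zone size emphasis  LZE = Σᵢ Σₛ s²·Z(i,s) / N_z,
- zone size non-uniformity  ZSN = Σₛ (Σᵢ Z(i,s))² / N_z,
- zone size percentage      ZP  = N_z / N_v.

The GLCM pools co-occurrence counts over the 13 unique 3D direction
offsets at distance 1 (symmetric) before normalization; the NGTDM uses
only voxels with a complete 26-neighborhood. Feature screening and the
random-forest analysis operate on the patients × 41 table.

## Worked example

```python
from mpradiomics import (CohortSpec, RFConfig, generate_cohort,
                         extract_cohort_tables, screen_features, crossval_rf)

spec = CohortSpec(n_per_group=10, seed=42)          # 30 synthetic patients
patients = generate_cohort(spec)
table = extract_cohort_tables(patients, modes=("mean",))["mean"]

results, summary = screen_features(table, alpha=0.05)
print(results.loc[["glszm_large_zone_emphasis",
                   "glszm_zone_size_non_uniformity",
                   "glszm_zone_size_percentage"],
                  ["H", "p_kw_adj", "rho", "p_rho_adj"]].round(4))

res = crossval_rf(table, target=1, cfg=RFConfig(n_trees=500, seed=42))
print(f"G1-vs-rest mean AUC: {res.mean_metrics['auc']:.3f}")
```

prints

```
                                      H  p_kw_adj     rho  p_rho_adj
feature
glszm_large_zone_emphasis       25.8065    0.0001 -0.9433        0.0
glszm_zone_size_non_uniformity  21.5252    0.0004  0.8443        0.0
glszm_zone_size_percentage      24.1318    0.0001  0.9104        0.0
G1-vs-rest mean AUC: 1.000
```

All three size-zone features remain significant after Holm correction,
with the expected signs: large homogeneous zones become rarer (ρ < 0) and
lesions more fragmented (ρ > 0) as grade increases. On this clean
synthetic cohort the forest separates G1 perfectly; on real data the
separation is necessarily weaker.

The same analysis runs from the shell:

```bash
mpradiomics all --config config.json --seed 7
```

which stages `simulate → extract → screen → classify → report` into a run
directory containing the feature tables, univariate CSVs, classification
metrics JSON, importance tables and a `summary.txt`. Rerunning the same
config reproduces every tabular output byte for byte.

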