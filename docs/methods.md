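# Methods

## Analysis model

The pipeline treats tumour grade prediction as a texture problem: within a
lesion-centred region of interest, higher-grade lesions are expected to be
more heterogeneous — fragmented into many small iso-intense regions —
while low-grade lesions contain larger homogeneous regions. Three texture
matrices quantify this at increasing spatial order:

- **GLCM** — joint probability P(i, j) of gray-level pairs at distance-1
  offsets. Co-occurrence counts are pooled over the 13 unique 3D direction
  offsets, each pair counted in both orders (symmetric), then normalized
  once. Pooling before normalization (rather than averaging per-direction
  features) was chosen for rotation robustness and simplicity; an
  axial-only 4-direction mode and per-direction distance are config
  options. Entropies use base-2 logarithms with 0·log 0 = 0.
- **NGTDM** — per gray level, the summed absolute deviation between a
  voxel's level and the mean of its 26-neighborhood (centre excluded).
  Only voxels with a *complete* neighborhood contribute, the original
  convention for this matrix; on a 3-slice patch that is the interior of
  the middle slice (19 × 19 = 361 voxels).
- **GLSZM** — counts Z(i, s) of maximal 26-connected zones of level i and
  size s. 26-connectivity is the most permissive standard choice;
  6-connectivity is available. The zone partition covers the patch
  exactly, which the implementation asserts.

From these, 41 features are computed per patch in a fixed canonical
order: 6 histogram (on quantized levels), 19 GLCM (Haralick/Soh
conventions, including both information-correlation measures and the
cluster statistics), 5 NGTDM (Amadasun definitions) and 11 GLSZM
(Thibault definitions). Features are extracted independently from the
T2-WI and ADC patches and averaged elementwise ("mean" mode);
single-modality tables support the modality-comparison analysis.

## Regions of interest and quantization

The ROI is a 21 × 21 × 3 window centred on the lesion centroid (±10
voxels in-plane, ±1 slice). A window crossing a volume boundary is
shifted minimally to fit, with a logged warning — padding would inject
artificial homogeneous zones into the GLSZM. Each patch is uniformly
quantized to Ng = 32 equal-width bins over *its own* intensity range:
level = min(Ng, ⌊(v − min)/(max − min)·Ng⌋ + 1). Patch-local binning
makes every downstream feature invariant to positive affine transforms of
the scanner output (asserted in tests), so the whole-volume min–max
normalization step matters only for inspection, not for the features.
Degenerate inputs have explicit contracts: a constant volume normalizes
to zeros, a constant patch quantizes to level 1, zero-variance skewness/
kurtosis/GLCM-correlation are defined as 0, and NGTDM coarseness is
capped at 1/ε with ε = 10⁻⁶ (configurable). T2 and ADC ROIs are cut in
each volume's own voxel grid; no inter-modality registration or
resampling is attempted.

## Univariate screening

Each feature is tested with the tie-corrected Kruskal–Wallis H across the
three groups (χ² approximation, k − 1 df) and with Spearman rank
correlation against the ordinal group index 1 < 2 < 3 (average ranks for
the heavily tied labels; large-sample p-value). The two families of 41
p-values are Holm–Bonferroni-corrected separately at α = 0.05, mirroring
two independent analyses; a single joint 82-test family is a config
option. Group summaries report median and IQR (Q3 − Q1,
linear-interpolation quantiles). All screening statistics are rank-based
and therefore invariant to the cohort min–max feature scaling (asserted).
Degenerate inputs (single group, zero rank variance) return H = 0, p = 1
with a warning rather than NaN.

## Classification and importance

Each of the three one-vs-rest tasks fits a 500-tree random forest
(unlimited depth, √p feature subsampling, bootstrap on — the canonical
defaults) under stratified 5-fold cross-validation; stratification
prevents single-class test folds at these group sizes. Metrics (AUC,
accuracy, NPV, PPV at threshold 0.5) are reported per fold and averaged;
a pooled out-of-fold confusion matrix is also emitted. A balanced
hold-out run draws disjoint class-balanced train (40) and test (20)
subsets; when the raw table is used, min–max scaling parameters are
fitted on the training subset only and applied without clipping to the
test subset, so no information leaks.

Feature importance is the Breiman-style out-of-bag permutation
importance, implemented on top of scikit-learn's per-tree bootstrap
bookkeeping: for every tree, the increase in OOB misclassification error
after permuting one feature among that tree's OOB rows; per fold, the
mean over trees divided by the SD of the per-tree increases; finally
averaged over the 5 folds. The phrase "normalized by the ensemble's
standard deviation" admits two readings (SD of per-tree importance
values vs. SD of OOB errors); the former is implemented as the default
and the normalization is switchable (`normalize="none"`). Positive
values mark predictive features.

All randomness — fold shuffling, per-fold forest seeds, permutation
draws, hold-out subsets — derives from one master seed through
`numpy.random.SeedSequence` stream splitting (sub-seeds kept below 2³¹),
so every result is replayable.

## Synthetic cohort generator

The generator emulates the one property the analysis is designed to
detect: group-dependent zone-size structure. A lesion patch starts at a
mid-gray background (0.5); spherical blobs of group-dependent mean
diameter (defaults 9 / 5 / 2 voxels for G1 / G2 / G3, diameters jittered
±30%, intensities uniform in [0, 1]) are stamped in random order, later
blobs overwriting earlier ones, with the blob count scaled to
≈2× coverage of the patch volume; Gaussian noise (SD 0.05 of the unit
signal range) is added and the result clipped to [0, 1]. Each patient
receives *independent* texture draws for T2 and ADC (the analysis
averages features across modalities and assumes nothing about
inter-modality correlation), embedded at a recorded centroid inside a
quieter noisy background volume of 64 × 64 × 19 voxels — a scaled
stand-in for a full acquisition matrix, kept small so the suite runs
quickly; the shape is configurable. Modality-specific affine output
scales and voxel spacings mimic scanner units but are irrelevant to the
features by construction. Mean lesion intensities are held equal across
groups: intensity histograms alone are deliberately uninformative, so any
group signal must come from spatial texture. Group-3 patients draw their
Gleason score uniformly from {4+3, 8, 9, 10} so the five-tier grade-group
reanalysis populates bins 3–5.

Setting the three blob scales equal gives the *null* cohort: groups are
exchangeable by construction, which calibrates the corrected screen (the
family-wise any-rejection rate over 200 replicates must stay ≤ 0.08 at
α = 0.05).

What the generator does **not** emulate: prostate anatomy, partial-volume
and bias-field effects, inter-modality spatial correlation, realistic
intensity distributions, scanner noise spectra, or class imbalance (the
synthetic cohort is balanced 30/30/30). Passing tests therefore
demonstrate that the pipeline recovers zone-size group structure when it
exists and stays calibrated when it does not — not that any particular
performance level transfers to clinical data, where separations are far
weaker.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own analysis scale: the sign-pattern and
classifier checks use the seeded 30-per-group cohort (90 patients) at
full 500-tree forests; the null-calibration study uses 200 replicates of
10-per-group cohorts generated at patch level (21 × 21 × 3 textures
directly, skipping volume I/O that cannot affect rank statistics); the
label-permutation null uses 20 replicates at 50 trees, since the chance
level of AUC does not depend on ensemble size. Oracle-equivalence checks
run on ≤ 7 × 7 × 3 patches with Ng ≤ 5 where brute-force enumeration is
exact and fast.

## Known limitations

- The 21 × 21 in-plane window is defined in each image's own voxel grid;
  with different native resolutions for T2 and DWI-derived ADC the
  physical extents differ, and no resampling is performed.
- The whole-volume normalization method is min–max by default (z-score
  available); patch-local quantization makes the choice immaterial to
  the features.
- Whether published feature tables reflect cohort-level unit scaling is
  not derivable from the pipeline itself; `scale_features` defaults on
  and is toggleable, and every rank statistic is invariant to it.
- Hold-out evaluation uses a single balanced 40/20 draw per seed (60 of
  90 synthetic patients; the unused count is logged), so its metrics
  have substantial draw-to-draw variance by design.
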