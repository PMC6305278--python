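"""Feature formulas vs. literal-formula oracles plus closed-form examples."""

import logging

import numpy as np
import pandas as pd
import pytest

from mpradiomics import (
    FEATURE_NAMES,
    CohortFeatureTable,
    compute_feature_vector,
    compute_glcm,
    compute_glszm,
    compute_ngtdm,
    extract_patient_features,
    glcm_features,
    glszm_features,
    histogram_features,
    kruskal_wallis,
    ngtdm_features,
    scale_features,
    spearman_vs_group,
)
from mpradiomics.features import COARSENESS_EPS, apply_scaling
from mpradiomics.imaging import QuantizedPatch
from mpradiomics.texture import GLCM, GLSZM

from .oracles import (
    glcm_features_bruteforce,
    glszm_features_bruteforce,
    glszm_bruteforce,
    histogram_features_bruteforce,
    ngtdm_features_bruteforce,
)


def _patch(levels, ng):
    return QuantizedPatch(levels=np.asarray(levels), ng=ng)


def _random_patch(seed, shape=(7, 7, 3), ng=5):
    rng = np.random.default_rng(seed)
    return _patch(rng.integers(1, ng + 1, size=shape), ng=ng)


class TestHistogramFeatures:
    def test_constant_patch(self):
        f = histogram_features(_patch(np.ones((21, 21, 3), dtype=int), ng=32))
        assert f["hist_variance"] == 0.0
        assert f["hist_energy"] == 1.0
        assert f["hist_entropy"] == 0.0
        assert f["hist_skewness"] == 0.0
        assert f["hist_kurtosis"] == 0.0

    def test_two_equal_bins(self):
        levels = np.ones((2, 2, 1), dtype=int)
        levels[:, 1, :] = 2
        f = histogram_features(_patch(levels, ng=2))
        assert f["hist_entropy"] == pytest.approx(1.0)
        assert f["hist_energy"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_formula_oracle(self, seed):
        q = _random_patch(seed)
        got = histogram_features(q)
        want = histogram_features_bruteforce(q.levels, q.ng)
        for name in want:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name


class TestGLCMFeatures:
    def test_point_mass_matrix(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        f = glcm_features(GLCM(p=p, ng=4))
        assert f["glcm_angular_second_moment"] == 1.0
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_homogeneity"] == 1.0
        assert f["glcm_maximum_probability"] == 1.0
        assert f["glcm_correlation"] == 0.0  # zero-variance convention

    def test_two_level_diagonal_matrix(self):
        p = np.diag([0.5, 0.5])
        f = glcm_features(GLCM(p=p, ng=2))
        assert f["glcm_angular_second_moment"] == pytest.approx(0.5)
        assert f["glcm_contrast"] == pytest.approx(0.0)
        assert f["glcm_entropy"] == pytest.approx(1.0)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            GLCM(p=np.ones((3, 3)), ng=3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_formula_oracle(self, seed):
        q = _random_patch(seed, ng=4)
        m = compute_glcm(q)
        got = glcm_features(m)
        want = glcm_features_bruteforce(m.p)
        for name in want:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name


class TestNGTDMFeatures:
    def test_constant_patch_capped_coarseness(self):
        m = compute_ngtdm(_patch(np.ones((5, 5, 3), dtype=int), ng=4))
        f = ngtdm_features(m)
        assert f["ngtdm_coarseness"] == pytest.approx(1.0 / COARSENESS_EPS)
        assert f["ngtdm_contrast"] == 0.0
        assert f["ngtdm_busyness"] == 0.0
        assert f["ngtdm_complexity"] == 0.0
        assert f["ngtdm_strength"] == 0.0

    def test_single_centre_bump_coarseness(self):
        levels = np.ones((3, 3, 3), dtype=int)
        levels[1, 1, 1] = 2
        m = compute_ngtdm(_patch(levels, ng=2))
        # p_2 = 1, s_2 = 1 -> sum p_i s_i = 1
        f = ngtdm_features(m)
        assert f["ngtdm_coarseness"] == pytest.approx(1.0 / (1.0 + COARSENESS_EPS))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_formula_oracle(self, seed):
        q = _random_patch(seed, ng=4)
        m = compute_ngtdm(q)
        got = ngtdm_features(m)
        want = ngtdm_features_bruteforce(m.n_i, m.s_i)
        for name in want:
            assert got[name] == pytest.approx(want[name], rel=1e-10), name


class TestGLSZMFeatures:
    def test_toy_matrix_hand_values(self):
        # three zones of size 3, one per level, from a 9-voxel patch
        z = np.zeros((3, 3))
        z[:, 2] = 1.0
        f = glszm_features(GLSZM(z=z, ng=3, n_v=9))
        assert f["glszm_small_zone_emphasis"] == pytest.approx(1 / 9)
        assert f["glszm_large_zone_emphasis"] == pytest.approx(9.0)
        assert f["glszm_zone_size_non_uniformity"] == pytest.approx(3.0)
        assert f["glszm_gray_level_non_uniformity"] == pytest.approx(1.0)
        assert f["glszm_zone_size_percentage"] == pytest.approx(1 / 3)

    def test_constant_patch_single_zone(self):
        m = compute_glszm(_patch(np.ones((21, 21, 3), dtype=int), ng=32))
        f = glszm_features(m)
        assert f["glszm_zone_size_percentage"] == pytest.approx(1 / 1323)
        assert f["glszm_large_zone_emphasis"] == pytest.approx(1323.0**2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_formula_oracle(self, seed):
        q = _random_patch(seed, shape=(6, 6, 3), ng=3)
        got = glszm_features(compute_glszm(q))
        zones = glszm_bruteforce(q.levels, q.ng)
        want = glszm_features_bruteforce(zones, int(q.levels.size))
        mapping = {
            "glszm_small_zone_emphasis": "sze",
            "glszm_large_zone_emphasis": "lze",
            "glszm_low_gray_level_zone_emphasis": "lgze",
            "glszm_high_gray_level_zone_emphasis": "hgze",
            "glszm_small_zone_low_gray_emphasis": "szlge",
            "glszm_small_zone_high_gray_emphasis": "szhge",
            "glszm_large_zone_low_gray_emphasis": "lzlge",
            "glszm_large_zone_high_gray_emphasis": "lzhge",
            "glszm_gray_level_non_uniformity": "gln",
            "glszm_zone_size_non_uniformity": "zsn",
            "glszm_zone_size_percentage": "zp",
        }
        for name, key in mapping.items():
            assert got[name] == pytest.approx(want[key], rel=1e-10), name


class TestFeatureVector:
    def test_canonical_order_and_count(self):
        q = _random_patch(0, shape=(21, 21, 3), ng=32)
        vec = compute_feature_vector(q)
        assert list(vec) == list(FEATURE_NAMES)
        assert len(vec) == 41
        assert all(np.isfinite(v) for v in vec.values())

    def test_bounded_feature_ranges(self):
        q = _random_patch(1, shape=(21, 21, 3), ng=32)
        vec = compute_feature_vector(q)
        for name in ("hist_energy", "glcm_angular_second_moment",
                     "glcm_maximum_probability", "glszm_zone_size_percentage"):
            assert 0 < vec[name] <= 1, name
        for name in vec:
            if "entropy" in name:
                assert vec[name] >= 0, name

    def test_mean_mode_is_arithmetic_mean(self):
        t2 = _random_patch(2, shape=(21, 21, 3), ng=32)
        adc = _random_patch(3, shape=(21, 21, 3), ng=32)
        mean = extract_patient_features(t2, adc, mode="mean")
        a = extract_patient_features(t2, None, mode="T2")
        b = extract_patient_features(None, adc, mode="ADC")
        pd.testing.assert_series_equal(mean, (a + b) / 2, check_names=False)

    def test_identical_patches_mean_is_idempotent(self):
        q = _random_patch(4, shape=(21, 21, 3), ng=32)
        mean = extract_patient_features(q, q, mode="mean")
        single = extract_patient_features(q, None, mode="T2")
        pd.testing.assert_series_equal(mean, single, check_names=False)

    def test_single_modality_ignores_other_patch(self):
        t2 = _random_patch(5, shape=(21, 21, 3), ng=32)
        noise_a = _random_patch(6, shape=(21, 21, 3), ng=32)
        noise_b = _random_patch(7, shape=(21, 21, 3), ng=32)
        va = extract_patient_features(t2, noise_a, mode="T2")
        vb = extract_patient_features(t2, noise_b, mode="T2")
        pd.testing.assert_series_equal(va, vb)

    def test_mismatched_ng_rejected_in_mean_mode(self):
        t2 = _random_patch(8, shape=(21, 21, 3), ng=32)
        adc = _random_patch(9, shape=(21, 21, 3), ng=16)
        with pytest.raises(ValueError, match="Ng"):
            extract_patient_features(t2, adc, mode="mean")


def _toy_table(matrix, groups):
    data = pd.DataFrame(
        np.tile(matrix, (1, 41))[:, :41], columns=list(FEATURE_NAMES),
        index=[f"P{i}" for i in range(len(groups))],
    )
    return CohortFeatureTable(
        data=data, groups=pd.Series(groups, index=data.index)
    )


class TestScaleFeatures:
    def test_minmax_column(self):
        t = _toy_table(np.array([[2.0], [4.0], [6.0]]), [1, 2, 3])
        scaled = scale_features(t)
        np.testing.assert_allclose(
            scaled.data.iloc[:, 0], [0.0, 0.5, 1.0]
        )

    def test_constant_column_zeros_with_warning(self, caplog):
        t = _toy_table(np.array([[5.0], [5.0], [5.0]]), [1, 2, 3])
        with caplog.at_level(logging.WARNING):
            scaled = scale_features(t)
        assert np.all(scaled.data.to_numpy() == 0.0)
        assert "constant" in caplog.text

    def test_double_scaling_rejected(self):
        t = _toy_table(np.array([[2.0], [4.0], [6.0]]), [1, 2, 3])
        scaled = scale_features(t)
        with pytest.raises(ValueError, match="already"):
            scale_features(scaled)

    def test_heldout_rows_not_clipped(self):
        t = _toy_table(np.array([[2.0], [4.0], [6.0]]), [1, 2, 3])
        scaled = scale_features(t)
        new = pd.DataFrame(
            [[10.0] * 41], columns=list(FEATURE_NAMES), index=["Q0"]
        )
        out = apply_scaling(new, scaled.scaling_params)
        assert out.iloc[0, 0] == pytest.approx(2.0)  # (10-2)/4, outside [0,1]

    def test_rank_statistics_invariant_to_scaling(self, separable_table):
        raw = CohortFeatureTable(
            data=separable_table.data * 3.7 + 2.0,  # undo-proof affine map
            groups=separable_table.groups,
        )
        scaled = scale_features(raw)
        g = raw.groups.to_numpy()
        for name in ("glszm_large_zone_emphasis", "glcm_entropy"):
            h1, p1 = kruskal_wallis(raw.data[name], g)
            h2, p2 = kruskal_wallis(scaled.data[name], g)
            assert h1 == pytest.approx(h2, rel=1e-12)
            assert p1 == pytest.approx(p2, rel=1e-12)
            r1, q1 = spearman_vs_group(raw.data[name], g)
            r2, q2 = spearman_vs_group(scaled.data[name], g)
            assert r1 == pytest.approx(r2, rel=1e-12)
            assert q1 == pytest.approx(q2, rel=1e-12)
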