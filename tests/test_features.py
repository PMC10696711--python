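"""Texture features: hand-derived values, oracle equality, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from oracles import glcm_oracle, glrlm_oracle, lbp_oracle, stats_oracle
from neolus.dtcwt import dtcwt_forward
from neolus.features import (FeatureConfig, GLCM_OFFSETS, GLRLM_DIRECTIONS,
                             GLRLMatrix, QuantizedImage, extract_features,
                             glcm, glcm_features, glrlm, glrlm_features,
                             lbp_histogram, quantize, split_rois,
                             statistical_features)
from neolus.phantom import SampleMeta


# ---------------------------------------------------------------------------
# split_rois
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("h,top_rows,bottom_rows", [(500, 250, 250),
                                                    (31, 15, 16), (2, 1, 1)])
def test_split_halves(h, top_rows, bottom_rows):
    r = np.arange(h * 4, dtype=float).reshape(h, 4)
    top, bottom, full = split_rois(r)
    assert top.shape[0] == top_rows and bottom.shape[0] == bottom_rows
    np.testing.assert_array_equal(np.vstack([top, bottom]), full)


# ---------------------------------------------------------------------------
# statistical features
# ---------------------------------------------------------------------------

def test_statistics_hand_values():
    s = statistical_features(np.array([1.0, 2.0, 3.0, 4.0]))
    assert s.mean == pytest.approx(2.5)
    assert s.sd == pytest.approx(1.1180, abs=1e-4)
    assert s.skewness == pytest.approx(0.0, abs=1e-12)


def test_constant_roi_uniform_entropy():
    s = statistical_features(np.full((6, 8), 3.0))
    assert s.mean == 3.0 and s.sd == 0.0 and s.degenerate
    assert s.skewness == 0.0 and s.kurtosis == 0.0
    assert s.entropy == pytest.approx(np.log2(48))


def test_gaussian_excess_kurtosis_near_zero():
    x = np.random.default_rng(42).standard_normal(100_000) + 10.0
    s = statistical_features(x)
    assert abs(s.kurtosis) < 0.05


def test_statistics_match_scipy_oracle():
    for seed in range(10):
        roi = np.random.default_rng(seed).uniform(0.1, 9.0, (16, 16))
        s = statistical_features(roi)
        ref = stats_oracle(roi)
        np.testing.assert_allclose(s.values(), ref, rtol=1e-9)


def test_statistics_permutation_invariant():
    rng = np.random.default_rng(7)
    roi = rng.uniform(0, 10, (12, 12))
    perm = rng.permutation(roi.ravel()).reshape(12, 12)
    np.testing.assert_allclose(statistical_features(roi).values(),
                               statistical_features(perm).values(),
                               rtol=1e-9)


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def test_quantize_integer_grid():
    q = quantize(np.arange(8.0).reshape(2, 4), L=8)
    np.testing.assert_array_equal(q.levels.ravel(), np.arange(1, 9))


def test_quantize_constant_all_level_one():
    q = quantize(np.full((4, 4), 5.0))
    assert np.all(q.levels == 1)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(arrays(float, (6, 6), elements=st.floats(0, 255, allow_nan=False)))
def test_quantize_range_invariant(a):
    q = quantize(a, L=8)
    assert q.levels.min() >= 1 and q.levels.max() <= 8


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def test_glcm_hand_enumeration():
    q = QuantizedImage(np.array([[1, 1], [2, 2]]), 8, np.zeros(7))
    m = glcm(q, (0, 1))
    assert m.counts[0, 0] == 1 and m.counts[1, 1] == 1
    assert m.counts.sum() == 2
    m2 = glcm(q, (1, 0))
    assert m2.counts[0, 1] == 2 and m2.counts.sum() == 2


def test_glcm_pair_count_identity():
    rng = np.random.default_rng(0)
    q = quantize(rng.uniform(0, 255, (13, 17)))
    for dr, dc in GLCM_OFFSETS:
        m = glcm(q, (dr, dc))
        assert m.counts.sum() == (13 - abs(dr)) * (17 - abs(dc))
        assert m.normalized.sum() == pytest.approx(1.0)


def test_glcm_smaller_than_offset_rejected():
    q = QuantizedImage(np.ones((1, 3), dtype=int), 8, np.zeros(7))
    with pytest.raises(ValueError):
        glcm(q, (2, 0))


def test_glcm_features_two_diagonal_cells():
    q = QuantizedImage(np.array([[1, 1], [2, 2]]), 8, np.zeros(7))
    f = glcm_features(glcm(q, (0, 1)), q)
    assert f["contrast"] == 0.0
    assert f["homogeneity"] == pytest.approx(1.0)
    assert f["energy"] == pytest.approx(0.5)
    assert f["entropy"] == pytest.approx(1.0)


def test_glcm_feature_bounds_and_degenerate_correlation():
    q = quantize(np.random.default_rng(1).uniform(0, 9, (10, 10)))
    f = glcm_features(glcm(q, (1, 1)), q)
    assert 0 < f["energy"] <= 1 and 0 < f["homogeneity"] <= 1
    qc = quantize(np.full((5, 5), 2.0))
    fc = glcm_features(glcm(qc, (0, 1)), qc)
    assert fc["correlation"] == 0.0 and fc["contrast"] == 0.0


def test_glcm_matches_skimage_cross_check():
    """Counts agree with skimage's graycomatrix for the row offset."""
    from skimage.feature import graycomatrix

    rng = np.random.default_rng(5)
    q = quantize(rng.uniform(0, 255, (16, 16)))
    ours = glcm(q, (0, 1)).counts
    ref = graycomatrix(q.levels - 1, [1], [0], levels=8,
                       symmetric=False, normed=False)[:, :, 0, 0]
    np.testing.assert_array_equal(ours, ref)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def test_glrlm_hand_run_enumeration():
    q = QuantizedImage(np.array([[1, 1, 2, 2, 2]]), 8, np.zeros(7))
    r = glrlm(q, 0)
    assert r.runs[0, 1] == 1      # level 1, run length 2
    assert r.runs[1, 2] == 1      # level 2, run length 3


def test_glrlm_constant_rows_full_runs():
    q = QuantizedImage(np.ones((4, 4), dtype=int), 8, np.zeros(7))
    r = glrlm(q, 0)
    assert r.runs[0, 3] == 4


def test_glrlm_pixel_partition_identity():
    rng = np.random.default_rng(2)
    q = quantize(rng.uniform(0, 255, (11, 14)))
    j = np.arange(1, 15)
    for d in GLRLM_DIRECTIONS:
        r = glrlm(q, d)
        assert (r.runs * np.arange(1, r.runs.shape[1] + 1)).sum() == q.levels.size


def test_glrlm_feature_arithmetic():
    runs = np.zeros((2, 3), dtype=int)
    runs[0, 1] = 1    # level 1, length 2
    runs[1, 2] = 1    # level 2, length 3
    f = glrlm_features(GLRLMatrix(runs, 0, 5))
    assert f["SRE"] == pytest.approx((1 / 4 + 1 / 9) / 2, abs=1e-5)
    assert f["LRE"] == pytest.approx(6.5)
    assert f["RP"] == pytest.approx(0.4)
    assert f["GLN"] == pytest.approx(1.0)
    assert f["HGRE"] == pytest.approx((1 + 4) / 2)


def test_glrlm_degenerate_single_run():
    runs = np.zeros((1, 1), dtype=int)
    runs[0, 0] = 1
    f = glrlm_features(GLRLMatrix(runs, 0, 1))
    for name in ("SRE", "LRE", "LGRE", "HGRE"):
        assert f[name] == 1.0
    assert f["SRE"] <= 1.0 <= f["LRE"]


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

def test_lbp_constant_all_ones_pattern():
    h = lbp_histogram(np.full((5, 5), 3.0))
    assert h.shape == (10,)
    assert h[8] == 1.0            # neighbours >= centre everywhere


def test_lbp_histogram_sums_to_one():
    h = lbp_histogram(np.random.default_rng(0).uniform(0, 1, (16, 16)))
    assert h.sum() == pytest.approx(1.0)
    assert len(h) == 10


def test_lbp_matches_bruteforce_oracle():
    for seed in range(5):
        roi = np.random.default_rng(seed).uniform(0, 255, (16, 16))
        np.testing.assert_allclose(lbp_histogram(roi), lbp_oracle(roi),
                                   rtol=1e-12)


def test_lbp_too_small_rejected():
    with pytest.raises(ValueError):
        lbp_histogram(np.zeros((2, 5)))


# ---------------------------------------------------------------------------
# oracle equality across families (seeded random rasters)
# ---------------------------------------------------------------------------

def test_glcm_glrlm_match_bruteforce_on_random_rasters():
    for seed in range(10):
        roi = np.random.default_rng(100 + seed).uniform(0, 255, (16, 16))
        q = quantize(roi)
        for off in GLCM_OFFSETS:
            np.testing.assert_array_equal(
                glcm(q, off).counts, glcm_oracle(q.levels, 8, off))
        for d in GLRLM_DIRECTIONS:
            r = glrlm(q, d)
            np.testing.assert_array_equal(
                r.runs, glrlm_oracle(q.levels, 8, d, r.runs.shape[1]))


def test_glcm_glrlm_not_permutation_invariant():
    """Spatial families must react to pixel rearrangement."""
    rng = np.random.default_rng(8)
    roi = np.sort(rng.uniform(0, 255, (12, 12)), axis=1)  # strong structure
    perm = rng.permutation(roi.ravel()).reshape(12, 12)
    q, qp = quantize(roi), quantize(perm)
    assert not np.array_equal(glcm(q, (0, 1)).counts,
                              glcm(qp, (0, 1)).counts)
    assert not np.array_equal(glrlm(q, 0).runs, glrlm(qp, 0).runs)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _meta():
    return SampleMeta("S1", "S1-V1", 0, "Normal", "R1", 30.0, 30.5, 3.0)


def test_feature_vector_count_and_name_consistency():
    img = np.random.default_rng(0).uniform(0, 255, (128, 128))
    fv = extract_features(dtcwt_forward(img, levels=3), _meta())
    # 3 + 18 rasters, 2 regions each, +3 full-region blocks for M bands
    n_regions = 21 * 2 + 3
    per_region = 5 + 5 * 6 + 11 * 4 + 10
    assert len(fv.names) == n_regions * per_region + 3
    assert len(set(fv.names)) == len(fv.names)
    assert fv.names[-3:] == ["ga_weeks", "cgats_weeks", "dol_days"]
    assert len(fv.names) == fv.values.size


def test_constant_image_degenerate_features():
    fv = extract_features(dtcwt_forward(np.full((64, 64), 9.0), levels=2),
                          _meta())
    vals = dict(zip(fv.names, fv.values))
    for name, v in vals.items():
        if "glcm_contrast" in name or "_stat_sd" in name:
            assert abs(v) < 1e-9, name


def test_m2_full_mean_is_global_mean_of_level2_lowpass():
    img = np.random.default_rng(3).uniform(0, 255, (128, 128))
    s = dtcwt_forward(img, levels=3)
    fv = extract_features(s, _meta())
    vals = dict(zip(fv.names, fv.values))
    assert vals["M2_full_stat_mean"] == pytest.approx(
        float(np.clip(s.lowpass[1], 0, None).mean()), rel=1e-12)


def test_feature_names_stable_across_runs():
    img = np.random.default_rng(1).uniform(0, 255, (64, 64))
    a = extract_features(dtcwt_forward(img, levels=2), _meta())
    b = extract_features(dtcwt_forward(img + 1.0, levels=2), _meta())
    assert a.names == b.names
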