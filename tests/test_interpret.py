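"""Grad-CAM maps, difference maps, pixel-wise rank statistics, hot spots
and the Kaplan-Meier median-split follow-up."""

import itertools

import numpy as np
import pytest

from pathcnn.datatypes import LTS, NON_LTS, ClinicalTable, LabelSet
from pathcnn.interpret import (
    DifferenceMapSet,
    PixelTestResult,
    difference_maps,
    find_hotspots,
    gradcam_map,
    gradcam_weights,
    km_logrank_median_split,
    pixelwise_test,
    rank_sum_p,
    upsample,
)
from pathcnn.model import ModelConfig, build_cnn
from conftest import make_image_set


class LinearHeadNet:
    """Test double with an analytically known head: logit_c = sum_k c_k A^k
    on fixed feature maps, for toy cases that assume a direct linear
    readout of the conv layer."""

    use_age = False

    def __init__(self, A, coef):
        self.A = np.asarray(A, dtype=float)  # h x w x K
        self.coef = np.asarray(coef, dtype=float)  # 2 x K
        self.image_shape = self.A.shape[:2]

    def conv_activations_and_grad(self, x, class_idx, age=None):
        h, w, k = self.A.shape
        da = np.broadcast_to(self.coef[class_idx], (1, h, w, k)).copy()
        return self.A[None, ...], da


# ---------------------------------------------------------------- weights

def test_gradcam_weights_linear_toy():
    # y = 3 * A^1 on a single 1x1 map -> w_1 = 3 exactly
    net = LinearHeadNet(np.ones((1, 1, 1)), coef=[[0.0], [3.0]])
    w = gradcam_weights(net, np.zeros((1, 1)), LTS)
    assert w == pytest.approx([3.0])


def test_gradcam_weights_zero_gradient():
    net = LinearHeadNet(np.ones((2, 3, 4)), coef=np.zeros((2, 4)))
    w = gradcam_weights(net, np.zeros((2, 3)), NON_LTS)
    np.testing.assert_allclose(w, 0.0)


def test_gradcam_weights_unknown_class_errors():
    net = LinearHeadNet(np.ones((1, 1, 1)), coef=[[1.0], [1.0]])
    with pytest.raises(ValueError, match="unknown class"):
        gradcam_weights(net, np.zeros((1, 1)), "mystery")


def test_gradcam_weights_match_finite_differences_on_cnn():
    """Analytic spatially-averaged gradients vs a central finite-difference
    oracle (uniform shift of each feature map) on a real trained-size net."""
    cfg = ModelConfig(conv_filters=(4, 6), dense_units=8, seed=2)
    net = build_cnn((12, 6), cfg, rng=np.random.default_rng(2))
    rng = np.random.default_rng(3)
    eps = 1e-6
    for _ in range(10):
        x = rng.random((1, 12, 6))
        acts, da = net.conv_activations_and_grad(x, class_idx=1)
        A = acts.astype(np.float64)
        z = A.shape[1] * A.shape[2]
        w_analytic = da[0].mean(axis=(0, 1))
        for k in range(A.shape[3]):
            ap, am = A.copy(), A.copy()
            ap[..., k] += eps
            am[..., k] -= eps
            fd = (net.logit_from_conv(ap)[0, 1] - net.logit_from_conv(am)[0, 1]) / (2 * eps * z)
            assert w_analytic[k] == pytest.approx(fd, rel=1e-3, abs=1e-7)


# ---------------------------------------------------------------- maps

def test_gradcam_map_relu_clamps_negative_sum():
    # y = 2*A^1 - 3*A^2 with A = (1, 1) on 1x1 maps -> ReLU(-1) = 0 map
    net = LinearHeadNet(np.ones((1, 1, 2)), coef=[[0.0, 0.0], [2.0, -3.0]])
    res = gradcam_map(net, np.zeros((1, 1)), LTS, out_shape=(1, 1))
    np.testing.assert_allclose(res.raw_map, 0.0)
    np.testing.assert_allclose(res.upsampled_map, 0.0)


def test_gradcam_map_zero_weights_give_zero_map():
    net = LinearHeadNet(np.random.default_rng(0).random((2, 2, 3)), coef=np.zeros((2, 3)))
    res = gradcam_map(net, np.zeros((2, 2)), LTS)
    np.testing.assert_allclose(res.upsampled_map, 0.0)


def test_gradcam_map_range_and_nonnegativity():
    cfg = ModelConfig(conv_filters=(4, 6), dense_units=8, seed=0)
    net = build_cnn((12, 6), cfg, rng=np.random.default_rng(0))
    rng = np.random.default_rng(5)
    for cls in (LTS, NON_LTS):
        res = gradcam_map(net, rng.random((12, 6)), cls)
        assert np.all(res.raw_map >= 0)
        assert res.upsampled_map.min() >= 0 and res.upsampled_map.max() <= 1
        assert res.upsampled_map.shape == (12, 6)


def test_upsample_corner_aligned_linear():
    m = np.array([[0.0], [1.0]])
    np.testing.assert_allclose(upsample(m, (4, 1)), [[0], [1 / 3], [2 / 3], [1.0]])
    np.testing.assert_allclose(upsample(np.array([[0.0, 1.0]]), (1, 3)), [[0, 0.5, 1.0]])
    # nearest mode and degenerate 1-pixel input
    np.testing.assert_allclose(upsample(np.array([[0.7]]), (2, 2), mode="nearest"), 0.7)


# ---------------------------------------------------------------- D maps

def test_difference_maps_symmetry_and_range():
    cfg = ModelConfig(conv_filters=(4, 6), dense_units=8, seed=1)
    net = build_cnn((8, 4), cfg, rng=np.random.default_rng(1))
    rng = np.random.default_rng(2)
    imgs = make_image_set(rng.random((6, 8, 4)), tags=("EXP",), q=4)
    labels = LabelSet(sample_ids=list(imgs.sample_ids),
                      labels=[LTS, LTS, LTS, NON_LTS, NON_LTS, NON_LTS],
                      excluded_ids=[])
    diffs = difference_maps(net, imgs, labels)
    assert diffs.maps.shape == (6, 8, 4)
    assert diffs.maps.min() >= 0 and diffs.maps.max() <= 1
    # |a-b| symmetry: recompute with the class order swapped manually
    from pathcnn.interpret import gradcam_map as gm

    i = 0
    a = gm(net, imgs.images[i], LTS).upsampled_map
    b = gm(net, imgs.images[i], NON_LTS).upsampled_map
    np.testing.assert_allclose(diffs.maps[i], np.abs(b - a))


def test_difference_maps_reject_age_model():
    cfg = ModelConfig(conv_filters=(4, 6), dense_units=8, use_age=True, seed=1)
    net = build_cnn((8, 4), cfg, rng=np.random.default_rng(1))
    imgs = make_image_set(np.zeros((4, 8, 4)), q=4)
    labels = LabelSet(list(imgs.sample_ids), [LTS, LTS, NON_LTS, NON_LTS], [])
    with pytest.raises(ValueError, match="without the age"):
        difference_maps(net, imgs, labels)


# ---------------------------------------------------------------- rank tests

def exact_rank_sum_p_by_enumeration(x, y):
    """Two-sided exact rank-sum p-value by enumerating all C(n+m, n)
    assignments of ranks to the first group."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1  # no ties assumed
    n = len(x)
    obs = ranks[:n].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n)]
    mean = np.mean(sums)
    p = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-12 for s in sums])
    return p


def test_rank_sum_exact_example():
    x = np.array([0.9, 0.8, 0.7])
    y = np.array([0.1, 0.2, 0.3])
    assert rank_sum_p(x, y) == pytest.approx(0.1)
    assert exact_rank_sum_p_by_enumeration(x, y) == pytest.approx(0.1)


def test_rank_sum_matches_enumeration_oracle():
    rng = np.random.default_rng(6)
    for _ in range(10):
        x = rng.random(4)
        y = rng.random(5)
        assert rank_sum_p(x, y) == pytest.approx(exact_rank_sum_p_by_enumeration(x, y))


def test_rank_sum_degenerate_identical_values():
    assert rank_sum_p(np.full(5, 0.3), np.full(7, 0.3)) == 1.0


def test_pixelwise_bonferroni_arithmetic():
    # raw p = 0.0005 with 876 tests -> adjusted 0.438
    n = 12
    rng = np.random.default_rng(7)
    maps = rng.random((n, 146, 6))
    diffs = DifferenceMapSet(sample_ids=[f"s{i}" for i in range(n)], maps=maps,
                             group=[LTS] * 6 + [NON_LTS] * 6)
    res = pixelwise_test(diffs, alpha=0.001)
    assert res.n_tests == 876
    np.testing.assert_allclose(res.adjusted_p, np.minimum(1.0, res.raw_p * 876))
    assert np.all(res.adjusted_p >= res.raw_p)
    assert 0.0005 * 876 == pytest.approx(0.438)


def test_pixelwise_null_p_values_are_uniform():
    """Under identical group distributions the raw p-values are ~uniform:
    the fraction below 0.05 is about 0.05 over many pixels."""
    rng = np.random.default_rng(8)
    maps = rng.random((30, 25, 20))  # 500 independent pixels
    diffs = DifferenceMapSet([f"s{i}" for i in range(30)], maps,
                             [LTS] * 14 + [NON_LTS] * 16)
    res = pixelwise_test(diffs)
    frac = float((res.raw_p < 0.05).mean())
    assert abs(frac - 0.05) < 0.03


def test_pixelwise_requires_two_per_group():
    diffs = DifferenceMapSet(["a", "b", "c"], np.zeros((3, 2, 2)), [LTS, NON_LTS, NON_LTS])
    with pytest.raises(ValueError):
        pixelwise_test(diffs)


# ---------------------------------------------------------------- hot spots

def _ptest_from_mask(mask):
    adj = np.where(mask, 1e-6, 1.0)
    return PixelTestResult(raw_p=adj, adjusted_p=adj, n_tests=mask.size, alpha=0.001,
                           row_labels=[f"PW{i}" for i in range(mask.shape[0])],
                           col_labels=[("EXP", 1), ("EXP", 2), ("CNV", 1)])


def test_hotspots_four_connectivity():
    mask = np.zeros((60, 3), dtype=bool)
    for r, c in [(3, 0), (4, 0), (5, 0), (3, 1), (4, 1)]:
        mask[r, c] = True
    mask[50, 2] = True
    spots = find_hotspots(_ptest_from_mask(mask))
    assert sorted(s.size for s in spots) == [1, 5]
    big = max(spots, key=lambda s: s.size)
    assert big.pathways == ["PW3", "PW4", "PW5"]


def test_hotspots_empty_and_full_mask():
    assert find_hotspots(_ptest_from_mask(np.zeros((5, 3), dtype=bool))) == []
    full = find_hotspots(_ptest_from_mask(np.ones((5, 3), dtype=bool)))
    assert len(full) == 1 and full[0].size == 15


# ---------------------------------------------------------------- KM split

def test_km_identical_groups_give_null_logrank():
    clinical = ClinicalTable(
        sample_id=[f"s{i}" for i in range(8)],
        survival_years=[1, 2, 3, 4, 1, 2, 3, 4],
        event=[1] * 8,
        age=[60] * 8,
    )
    values = [0, 0, 0, 0, 1, 1, 1, 1]
    res = km_logrank_median_split(values, clinical)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.p_value == pytest.approx(1.0)
    assert (res.n_low, res.n_high) == (4, 4)


def test_km_median_split_rule():
    clinical = ClinicalTable([f"s{i}" for i in range(4)], [1, 2, 3, 4], [1, 1, 1, 1], [60] * 4)
    res = km_logrank_median_split([0.1, 0.2, 0.3, 0.4], clinical)
    assert (res.n_low, res.n_high) == (2, 2)


def test_km_degenerate_values_error():
    clinical = ClinicalTable([f"s{i}" for i in range(4)], [1, 2, 3, 4], [1, 1, 1, 1], [60] * 4)
    with pytest.raises(ValueError, match="degenerate"):
        km_logrank_median_split([0.5, 0.5, 0.5, 0.5], clinical)


def test_km_detects_group_survival_difference():
    from pathcnn.images import assign_labels
    from pathcnn.synthetic import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(n_samples=200, n_pathways=4, genes_per_pathway=4, seed=9)
    _, _, clinical = generate_cohort(cfg)
    labels = assign_labels(clinical)
    clin = clinical.subset(labels.sample_ids)
    values = labels.y.astype(float)  # pixel value == group membership
    res = km_logrank_median_split(values, clin)
    assert res.p_value < 0.01
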