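"""Metrics, folds, Grad-CAM scoring and statistical tests."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import oracles
from fcaunet import evaluation as ev
from fcaunet.model import ModelConfig, build_fcau_net
from fcaunet.nn.engine import Tensor


class TestConfusionAndMetrics:
    def test_all_correct_has_empty_off_diagonal(self):
        y = [1, 1, 1, 0, 0, 0, 0, 1, 0, 1]
        cm = ev.confusion(y, y)
        assert cm.fp == 0 and cm.fn == 0 and cm.total == 10

    def test_enumerated_two_by_two(self):
        cm = ev.confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion([], [])

    def test_hand_arithmetic_metrics(self):
        m = ev.classification_metrics(ev.ConfusionMatrix(tp=3, fp=1, fn=2, tn=4))
        assert m["precision"] == pytest.approx(75.0)
        assert m["recall"] == pytest.approx(60.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["accuracy"] == pytest.approx(70.0)
        assert m["f1"] == pytest.approx(2 * 75.0 * 60.0 / (75.0 + 60.0), abs=1e-9)

    def test_perfect_matrix_and_zero_error_f1(self):
        m = ev.classification_metrics(ev.ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_zero_denominators_flagged_as_null(self):
        m = ev.classification_metrics(ev.ConfusionMatrix(tp=0, fp=0, fn=0, tn=4))
        assert m["precision"] is None and m["recall"] is None
        assert m["accuracy"] == pytest.approx(100.0)


class TestRocPr:
    def test_perfect_separation_auc_one(self):
        out = ev.roc_pr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert out["roc"]["auc"] == pytest.approx(1.0)

    def test_inverted_scores_auc_zero(self):
        out = ev.roc_pr([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert out["roc"]["auc"] == pytest.approx(0.0)

    def test_four_point_trapezoid_by_hand(self):
        # scores 0.9(+), 0.8(-), 0.7(+), 0.1(-): ROC hits (0,.5),(0.5,1),(1,1)
        out = ev.roc_pr([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert out["roc"]["auc"] == pytest.approx(0.75)


class TestKFold:
    def test_five_folds_of_ten_are_disjoint_pairs(self):
        folds = ev.kfold_split(10, ev.FoldPlan(k=5, seed=0))
        assert [len(f) for f in folds] == [2] * 5
        assert sorted(np.concatenate(folds).tolist()) == list(range(10))

    def test_sizes_within_one_and_seeded(self):
        a = ev.kfold_split(13, ev.FoldPlan(k=5, seed=2))
        b = ev.kfold_split(13, ev.FoldPlan(k=5, seed=2))
        assert max(map(len, a)) - min(map(len, a)) <= 1
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_aggregate_identical_folds_is_that_fold(self):
        t = {"accuracy": 80.0, "f1": 79.0}
        assert ev.aggregate_folds([t, t, t]) == t

    def test_round_half_up_convention(self):
        assert ev.round_half_up(83.45) == 83.5
        assert ev.round_half_up(69.24) == 69.2


class TestRegionScores:
    def test_identical_nonempty_regions(self):
        g = np.zeros((4, 4), int)
        g[1:3, 1:3] = 1
        assert ev.iou(g, g) == 1.0 and ev.dsc(g, g) == 1.0

    def test_disjoint_nonempty_regions(self):
        p = np.zeros((4, 4), int)
        g = np.zeros((4, 4), int)
        p[0, 0] = 1
        g[3, 3] = 1
        assert ev.iou(p, g) == 0.0 and ev.dsc(p, g) == 0.0

    def test_half_overlap_counting_example(self):
        g = np.ones((4, 4), int)
        p = np.zeros((4, 4), int)
        p[:, :2] = 1
        assert ev.iou(p, g) == pytest.approx(0.5)
        assert ev.dsc(p, g) == pytest.approx(2 / 3)

    def test_iou_never_exceeds_dsc_and_symmetry(self, rng):
        for _ in range(50):
            p = (rng.random((6, 6)) < 0.4).astype(int)
            g = (rng.random((6, 6)) < 0.4).astype(int)
            i, d = ev.iou(p, g), ev.dsc(p, g)
            assert 0.0 <= i <= d <= 1.0
            assert i == ev.iou(g, p) and d == ev.dsc(g, p)

    def test_pointing_game_counting(self):
        g_in = np.zeros((3, 3), int); g_in[0, 0] = 1
        g_out = np.zeros((3, 3), int); g_out[2, 2] = 1
        h = np.zeros((3, 3)); h[0, 0] = 1.0
        assert ev.pointing_game([(h, g_in)] * 4) == 100.0
        assert ev.pointing_game([(h, g_out)] * 4) == 0.0
        assert ev.pointing_game([(h, g_in)] * 3 + [(h, g_out)]) == 75.0

    def test_energy_score_uniform_quarter(self):
        h = np.ones((4, 4))
        g = np.zeros((4, 4), int)
        g[:2, :2] = 1
        assert ev.energy_score(h, g) == pytest.approx(25.0)
        assert ev.energy_score(np.zeros((4, 4)), g) is None
        assert ev.energy_score(h, np.zeros((4, 4), int)) == 0.0

    def test_heatmap_region_top_quantile(self):
        h = np.arange(16, dtype=float).reshape(4, 4) / 15
        p = ev.heatmap_region(h, keep_fraction=0.25)
        assert p.sum() == 4 and p[3, 3] == 1 and p[0, 0] == 0


@pytest.fixture(scope="module")
def model_and_image(easy_dataset):
    model = build_fcau_net(ModelConfig(base_channels=2, seed=1))
    return model, easy_dataset[0].image


class TestGradCam:
    def test_heatmap_range_and_determinism(self, model_and_image):
        model, img = model_and_image
        h1 = ev.grad_cam(model, img)
        h2 = ev.grad_cam(model, img)
        assert h1.shape == img.shape
        assert h1.min() >= 0.0 and h1.max() <= 1.0
        np.testing.assert_array_equal(h1, h2)

    def test_unknown_layer_rejected(self, model_and_image):
        model, img = model_and_image
        with pytest.raises(KeyError):
            ev.grad_cam(model, img, "nonexistent")

    def test_single_positive_channel_head_recovers_that_channel(self, model_and_image):
        # score = mean of decoder channel 0 only => heatmap proportional to
        # that channel's rectified activation
        model, img = model_and_image
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        model.head.weight.data[0, 1] = 1.0  # class 'infected' reads channel 0
        heat = ev.grad_cam(model, img)
        act = model.activations[f"decoder{len(model.decoders) - 1}"].data[0, 0]
        expected = np.maximum(act, 0)
        if expected.max() > 0:
            expected = expected / expected.max()
        np.testing.assert_allclose(heat, expected, atol=1e-10)


class TestPairedT:
    def test_zero_diffs_flagged(self):
        res = ev.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_value == 0.0 and res.p_value == 1.0 and res.flag

    def test_textbook_closed_form(self):
        res = ev.paired_t_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.mean_diff == pytest.approx(2.0)
        assert res.sd == pytest.approx(1.0)
        assert res.t_value == pytest.approx(2 * math.sqrt(3))
        assert res.dof == 2

    def test_matches_spreadsheet_oracle_on_fce_gain_runs(self):
        diffs = [9.3, 9.4, 9.5, 9.3, 9.4]
        res = ev.paired_t_test([0.0] * 5, diffs)
        want = oracles.paired_t_oracle(diffs)
        assert res.mean_diff == pytest.approx(want["mean"], abs=1e-12)
        assert res.variance == pytest.approx(want["var"], abs=1e-12)
        assert res.sd == pytest.approx(want["sd"], abs=1e-12)
        assert res.t_value == pytest.approx(want["t"], abs=1e-9)
        assert res.p_value == pytest.approx(want["p"], abs=1e-12)
        assert (res.ci_low, res.ci_high) == pytest.approx(want["ci"], abs=1e-9)

    def test_agrees_with_scipy_on_random_vectors(self, rng):
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            res = ev.paired_t_test(a, b)
            t, p = sps.ttest_rel(b, a)
            assert res.t_value == pytest.approx(float(t), abs=1e-9)
            assert res.p_value == pytest.approx(float(p), abs=1e-9)

    def test_requires_two_runs(self):
        with pytest.raises(ValueError):
            ev.paired_t_test([1.0], [2.0])


class TestMcNemar:
    def test_identical_predictions(self):
        y = [0, 1, 0, 1]
        out = ev.mcnemar(y, y, y)
        assert out["statistic"] == 0.0 and out["p_value"] == 1.0

    def test_one_sided_discordants_corrected_chi2(self):
        # a correct on 10 samples where b is wrong, none the reverse
        y = [1] * 10 + [0] * 10
        pa = y[:]
        pb = [0] * 10 + [0] * 10
        out = ev.mcnemar(pa, pb, y)
        assert out["discordant"] == (10, 0)
        assert out["statistic"] == pytest.approx((10 - 1) ** 2 / 10)  # 8.1

    def test_symmetric_discordants_near_null(self):
        y = [1] * 10 + [0] * 10
        pa = [1] * 5 + [0] * 5 + [0] * 10   # wrong on 5..9
        pb = [0] * 5 + [1] * 5 + [0] * 10   # wrong on 0..4
        out = ev.mcnemar(pa, pb, y)
        assert out["discordant"] == (5, 5)
        assert out["statistic"] <= 0.1
        assert out["p_value"] == pytest.approx(1.0)

    def test_exact_fallback_below_threshold(self):
        y = [1] * 8 + [0] * 8
        pa = y[:]
        pb = [0] * 3 + [1] * 5 + [0] * 8
        out = ev.mcnemar(pa, pb, y)
        assert out["method"] == "exact-binomial"
        # exact two-sided binomial p for 3 of 3 discordants one way
        assert out["p_value"] == pytest.approx(2 * 0.5 ** 3)
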