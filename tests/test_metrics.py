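"""Evaluation metrics against brute-force oracles and algebraic identities."""

import numpy as np
import pytest

from pspgleason.metrics import (ConfusionCounts, cohen_kappa, combined_score, dice,
                                evaluate_masks, hausdorff, prf_ja, boundary_points)


class TestDice:
    def test_identity(self, rng):
        a = rng.random((8, 8)) < 0.5
        assert dice(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[1, 1] = True
        assert dice(a, b) == 0.0

    def test_drawn_grid_example(self):
        # |A| = 4, |B| = 6, |A ∩ B| = 3 -> 2*3/10 = 0.6
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True
        b[0, 1:4] = True
        b[1, :3] = True
        assert a.sum() == 4 and b.sum() == 6 and (a & b).sum() == 3
        assert dice(a, b) == pytest.approx(0.6)

    def test_empty_vs_empty_is_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert dice(np.zeros((2, 2)), np.zeros((2, 2))) == 1.0

    def test_symmetry(self, rng):
        a = rng.random((10, 10)) < 0.3
        b = rng.random((10, 10)) < 0.3
        assert dice(a, b) == dice(b, a)


class TestHausdorff:
    def test_identical_sets_zero(self, rng):
        pts = rng.integers(0, 10, size=(5, 2))
        assert hausdorff(pts, pts) == 0.0

    def test_single_pair_euclidean(self):
        assert hausdorff([(0, 0)], [(3, 4)]) == pytest.approx(5.0)

    def test_matches_brute_force_double_loop(self, rng):
        xs = rng.random((10, 2)) * 20
        ys = rng.random((10, 2)) * 20
        d_xy = max(min(np.hypot(*(x - y)) for y in ys) for x in xs)
        d_yx = max(min(np.hypot(*(y - x)) for x in xs) for y in ys)
        assert hausdorff(xs, ys) == pytest.approx(max(d_xy, d_yx), abs=1e-12)

    def test_symmetry(self, rng):
        xs = rng.random((6, 2))
        ys = rng.random((8, 2))
        assert hausdorff(xs, ys) == hausdorff(ys, xs)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            hausdorff(np.empty((0, 2)), [(0, 0)])


class TestKappa:
    def test_perfect_agreement_is_one(self, rng):
        a = rng.integers(0, 4, size=100)
        k, p0, _ = cohen_kappa(a, a)
        assert k == 1.0 and p0 == 1.0

    def test_independent_raters_near_zero(self):
        g = np.random.default_rng(0)
        a = g.integers(0, 4, size=100_000)
        b = g.integers(0, 4, size=100_000)
        k, _, _ = cohen_kappa(a, b)
        se = np.sqrt(1 / (100_000 * (1 - 0.25)))        # rough SE under independence
        assert abs(k) < 3 * se

    def test_hand_computed_2x2_table(self):
        # table [[20, 5], [10, 15]]: p0 = 0.7, pe = 0.5*0.6 + 0.5*0.4 = 0.5
        a = np.array([0] * 25 + [1] * 25)
        b = np.array([0] * 20 + [1] * 5 + [0] * 10 + [1] * 15)
        k, p0, pe = cohen_kappa(a, b)
        assert p0 == pytest.approx(0.7)
        assert pe == pytest.approx(0.5)
        assert k == pytest.approx(0.4)

    def test_unweighted_invariant_under_relabeling(self, rng):
        a = rng.integers(0, 4, size=500)
        b = rng.integers(0, 4, size=500)
        k1, _, _ = cohen_kappa(a, b)
        perm = np.array([2, 0, 3, 1])
        k2, _, _ = cohen_kappa(perm[a], perm[b])
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_quadratic_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score
        a = rng.integers(0, 4, size=300)
        b = np.clip(a + rng.integers(-1, 2, size=300), 0, 3)
        k, _, _ = cohen_kappa(a, b, weighting="quadratic")
        assert k == pytest.approx(cohen_kappa_score(a, b, weights="quadratic"), abs=1e-12)

    def test_single_category_identical(self):
        k, _, _ = cohen_kappa([2, 2, 2], [2, 2, 2])
        assert k == 1.0


class TestPrfJa:
    def test_perfect(self):
        assert prf_ja(ConfusionCounts(10, 0, 0, 5)) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_zero_convention(self):
        assert prf_ja(ConfusionCounts(0, 3, 4, 5)) == (0.0, 0.0, 0.0, 0.0)

    def test_worked_arithmetic(self):
        p, r, ja, f1 = prf_ja(ConfusionCounts(6, 2, 4, 0))
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(0.6)
        assert ja == pytest.approx(0.5)
        assert f1 == pytest.approx(2 * 0.45 / 1.35)


class TestCombinedScore:
    @pytest.mark.parametrize("k,f1,expected", [(1, 1, 1), (0, 0, 0), (0.8, 0.6, 0.7)])
    def test_default_mean_rule(self, k, f1, expected):
        assert combined_score(k, f1) == pytest.approx(expected)

    def test_pluggable_combiner(self):
        assert combined_score(0.5, 0.8, combiner=max) == 0.8


class TestEvaluateMasks:
    def test_perfect_prediction(self, rng):
        truth = rng.choice([0, 3, 4, 5], size=(16, 16))
        rep = evaluate_masks(truth, truth)
        for c in np.unique(truth):
            assert rep.dsc[c] == 1.0
            assert rep.ja[c] == 1.0
            assert rep.hd[c] == 0.0
        assert rep.kappa == 1.0
        assert rep.mean_dsc == 1.0

    def test_constant_wrong_class(self):
        truth = np.full((8, 8), 3)
        pred = np.full((8, 8), 4)
        rep = evaluate_masks(pred, truth)
        assert rep.dsc[3] == 0.0 and rep.dsc[4] == 0.0

    def test_all_ignore_rejected(self):
        m = np.full((4, 4), 255)
        with pytest.raises(ValueError):
            evaluate_masks(m, m)

    def test_matches_counting_oracle_on_random_pairs(self, rng):
        for _ in range(20):
            truth = rng.choice([0, 3, 4, 5], size=(32, 32))
            pred = rng.choice([0, 3, 4, 5], size=(32, 32))
            rep = evaluate_masks(pred, truth)
            for c in (0, 3, 4, 5):
                tp = int(((pred == c) & (truth == c)).sum())
                fp = int(((pred == c) & (truth != c)).sum())
                fn = int(((pred != c) & (truth == c)).sum())
                assert rep.counts[c].tp == tp
                assert rep.counts[c].fp == fp
                assert rep.counts[c].fn == fn
                if tp + fp + fn:
                    assert rep.dsc[c] == pytest.approx(2 * tp / (2 * tp + fp + fn))
                    assert rep.ja[c] == pytest.approx(tp / (tp + fp + fn))

    def test_dsc_ja_algebraic_identity(self, rng):
        for _ in range(20):
            truth = rng.choice([0, 3, 4, 5], size=(32, 32))
            pred = rng.choice([0, 3, 4, 5], size=(32, 32))
            rep = evaluate_masks(pred, truth)
            for c in (0, 3, 4, 5):
                ja = rep.ja[c]
                assert rep.dsc[c] == pytest.approx(2 * ja / (1 + ja), abs=1e-12)

    def test_binary_f1_equals_dice(self, rng):
        for _ in range(20):
            a = rng.random((16, 16)) < 0.4
            b = rng.random((16, 16)) < 0.4
            if not (a.any() or b.any()):
                continue
            tp = int((a & b).sum())
            fp = int((a & ~b).sum())
            fn = int((~a & b).sum())
            _, _, _, f1 = prf_ja(ConfusionCounts(tp, fp, fn, 0))
            if tp + fp + fn:
                assert f1 == pytest.approx(dice(a, b), abs=1e-12)

    def test_micro_f1_equals_pixel_accuracy(self, rng):
        truth = rng.choice([0, 3, 4, 5], size=(32, 32))
        pred = rng.choice([0, 3, 4, 5], size=(32, 32))
        rep = evaluate_masks(pred, truth)
        assert rep.f1_micro == pytest.approx((pred == truth).mean(), abs=1e-12)

    def test_hd_matches_boundary_double_loop(self, rng):
        truth = rng.choice([0, 3], size=(16, 16))
        pred = rng.choice([0, 3], size=(16, 16))
        rep = evaluate_masks(pred, truth, classes=(0, 3))
        pb = boundary_points(pred == 3)
        tb = boundary_points(truth == 3)
        brute = max(max(min(np.hypot(*(x - y)) for y in tb) for x in pb),
                    max(min(np.hypot(*(x - y)) for y in pb) for x in tb))
        assert rep.hd[3] == pytest.approx(brute, abs=1e-12)
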