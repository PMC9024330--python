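"""STAPLE fusion: Bayes-posterior oracle, reference-implementation
equivalence, EM behaviour, seniority tie-breaking, majority vote."""

import itertools

import numpy as np
import pytest

from pspgleason.fusion import (AnnotationSet, majority_vote, resolve_ties,
                               staple_binary, staple_multiclass)
from pspgleason.synthetic import (RaterProfile, SyntheticCoreSpec, generate_core,
                                  simulate_raters)


def bayes_posterior_oracle(masks, p, q, prior):
    """Per-pixel enumeration of the two hypotheses with plain loops."""
    masks = [np.asarray(m) for m in masks]
    out = np.zeros_like(masks[0], dtype=float)
    for idx in np.ndindex(out.shape):
        a = prior
        b = 1 - prior
        for j, m in enumerate(masks):
            if m[idx] == 1:
                a *= p[j]
                b *= 1 - q[j]
            else:
                a *= 1 - p[j]
                b *= q[j]
        out[idx] = a / (a + b)
    return out


class TestStapleBinary:
    def test_single_rater_dominance(self, rng):
        m = (rng.random((6, 6)) < 0.4).astype(float)
        w, _, _ = staple_binary([m], prior=0.5, init_p=0.99, init_q=0.99,
                                estimate_performance=False)
        assert np.all(w[m == 1] > 0.5)
        assert np.all(w[m == 0] < 0.5)

    def test_unanimous_raters_recover_mask_and_perfect_performance(self, rng):
        m = (rng.random((8, 8)) < 0.5).astype(float)
        w, perfs, info = staple_binary([m, m, m], tol=1e-8, max_iter=200)
        assert np.array_equal((w > 0.5).astype(float), m)
        for p, q in perfs:
            assert p > 1 - 1e-3 and q > 1 - 1e-3

    def test_fixed_pq_matches_bayes_oracle(self, rng):
        masks = [(rng.random((4, 4)) < 0.5).astype(float) for _ in range(3)]
        p = [0.9, 0.8, 0.95]
        q = [0.85, 0.9, 0.7]
        for j, m in enumerate(masks):
            w, _, _ = staple_binary(masks[:j + 1], prior=0.3,
                                    init_p=p[:j + 1], init_q=q[:j + 1],
                                    estimate_performance=False)
            oracle = bayes_posterior_oracle(masks[:j + 1], p[:j + 1], q[:j + 1], 0.3)
            assert np.abs(w - oracle).max() < 1e-10

    def test_em_matches_reference_staple(self, rng):
        sitk = pytest.importorskip("SimpleITK")
        truth = rng.random((8, 8)) < 0.4
        masks = []
        for _ in range(3):
            flip = rng.random((8, 8)) < 0.15
            masks.append(np.where(flip, ~truth, truth).astype(np.uint8))
        w, _, _ = staple_binary([m.astype(float) for m in masks],
                                tol=1e-9, max_iter=500)
        f = sitk.STAPLEImageFilter()
        f.SetForegroundValue(1)
        f.SetMaximumIterations(500)
        ref = sitk.GetArrayFromImage(f.Execute([sitk.GetImageFromArray(m) for m in masks]))
        assert np.abs(w - ref).max() < 1e-4

    def test_log_likelihood_non_decreasing(self, rng):
        masks = [(rng.random((12, 12)) < 0.4).astype(float) for _ in range(4)]
        _, _, info = staple_binary(masks, tol=1e-10, max_iter=100)
        ll = info["log_likelihood"]
        assert len(ll) > 2
        assert all(b >= a - 1e-9 for a, b in zip(ll, ll[1:]))

    def test_parameter_recovery_known_sensitivity_specificity(self, rng):
        truth = rng.random((120, 120)) < 0.45           # >1e4 pixels
        ps = [0.99, 0.95, 0.92, 0.90, 0.88, 0.85]
        qs = [0.97, 0.93, 0.95, 0.88, 0.90, 0.86]
        masks = []
        for p, q in zip(ps, qs):
            r = rng.random(truth.shape)
            m = np.where(truth, r < p, r > q)           # sens on fg, spec on bg
            masks.append(m.astype(float))
        _, perfs, _ = staple_binary(masks, tol=1e-8, max_iter=300)
        for (p_hat, q_hat), p, q in zip(perfs, ps, qs):
            assert abs(p_hat - p) < 0.03
            assert abs(q_hat - q) < 0.03

    def test_mixed_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            staple_binary([np.zeros((2, 2)), np.zeros((3, 3))])

    def test_all_empty_zero_prior_degenerate(self):
        w, _, info = staple_binary([np.zeros((4, 4)), np.zeros((4, 4))], prior=0.0)
        assert info["degenerate"]
        assert np.all(w == 0)

    def test_bad_tol_rejected(self):
        with pytest.raises(ValueError):
            staple_binary([np.zeros((2, 2))], tol=0.0)


def _ann(masks_by_rater, seniority=None):
    seniority = seniority or {r: i + 1 for i, r in enumerate(masks_by_rater)}
    return AnnotationSet("img", {r: np.asarray(m) for r, m in masks_by_rater.items()},
                         seniority)


class TestStapleMulticlass:
    def test_unanimous_annotation_recovered(self):
        m = np.array([[0, 3], [4, 5]])
        fused = staple_multiclass(_ann({"a": m, "b": m, "c": m}))
        assert np.array_equal(fused.hard_mask, m)
        assert fused.tie_pixels == set()

    def test_single_annotator_identity(self):
        m = np.array([[0, 3, 3], [4, 5, 0]])
        fused = staple_multiclass(_ann({"solo": m}))
        assert np.array_equal(fused.hard_mask, m)

    def test_prob_fields_normalized(self, rng):
        masks = {f"r{i}": rng.choice([0, 3, 4, 5], size=(6, 6)) for i in range(3)}
        fused = staple_multiclass(_ann(masks))
        total = sum(fused.prob_fields.values())
        assert np.abs(total - 1.0).max() < 1e-6

    def test_rater_order_does_not_change_result(self, rng):
        masks = {f"r{i}": rng.choice([0, 3, 4, 5], size=(8, 8)) for i in range(4)}
        sen = {"r0": 1, "r1": 2, "r2": 3, "r3": 4}
        a = staple_multiclass(_ann(masks, sen))
        rev = dict(reversed(list(masks.items())))
        b = staple_multiclass(_ann(rev, sen))
        assert np.array_equal(a.hard_mask, b.hard_mask)

    def test_unknown_label_rejected_naming_rater(self):
        with pytest.raises(ValueError, match="bad_rater"):
            staple_multiclass(_ann({"bad_rater": np.array([[7]])}))

    def test_ignore_pixels_copied_through(self):
        m = np.array([[255, 3], [4, 255]])
        fused = staple_multiclass(_ann({"a": m, "b": m}))
        assert fused.hard_mask[0, 0] == 255
        assert fused.hard_mask[1, 1] == 255

    def test_beats_or_matches_majority_vote_on_simulation(self):
        _, truth = generate_core(SyntheticCoreSpec(image_size=128, seed=5))
        diags = [0.97, 0.93, 0.9, 0.88, 0.85, 0.8]
        profs = [RaterProfile(f"r{i}", i + 1,
                              np.eye(4) * d + (1 - d) / 3 * (1 - np.eye(4)),
                              boundary_jitter_px=1.0)
                 for i, d in enumerate(diags)]
        ann = simulate_raters(truth, profs, seed=9)
        fused = staple_multiclass(ann)
        mv = majority_vote(ann)
        tissue = truth != 255
        acc_staple = (fused.hard_mask[tissue] == truth[tissue]).mean()
        acc_mv = (mv[tissue] == truth[tissue]).mean()
        assert acc_staple >= acc_mv
        assert acc_mv > 0.9


class TestTieResolution:
    def test_senior_rater_decides(self):
        # two raters disagree 3 vs 4 everywhere: per-class posteriors tie
        a = np.full((2, 2), 3)
        b = np.full((2, 2), 4)
        fused = staple_multiclass(_ann({"senior": b, "junior": a},
                                       {"senior": 1, "junior": 2}))
        assert len(fused.tie_pixels) > 0
        assert np.all(fused.hard_mask[tuple(zip(*fused.tie_pixels))] == 4)

    def test_no_ties_mask_unchanged(self):
        m = np.array([[3, 4]])
        ann = _ann({"a": m})
        out = resolve_ties(m, set(), ann)
        assert np.array_equal(out, m)

    def test_fallback_to_next_senior_when_rank1_absent(self):
        # rank-1 rater did not annotate this image at all
        a = np.full((2, 2), 3)
        b = np.full((2, 2), 4)
        ann = AnnotationSet("img", {"second": a, "third": b},
                            {"first": 1, "second": 2, "third": 3})
        out = resolve_ties(np.full((2, 2), 5), {(0, 0), (1, 1)}, ann)
        assert out[0, 0] == 3 and out[1, 1] == 3       # next-most-senior present
        assert out[0, 1] == 5                           # non-tie untouched

    def test_fallback_when_senior_pixel_is_ignore(self):
        a = np.array([[255, 3]])
        b = np.array([[4, 4]])
        ann = _ann({"senior": a, "junior": b}, {"senior": 1, "junior": 2})
        out = resolve_ties(np.array([[0, 0]]), {(0, 0), (0, 1)}, ann)
        assert out[0, 0] == 4                           # senior says ignore -> junior
        assert out[0, 1] == 3                           # senior label wins


class TestMajorityVote:
    def test_strict_majority(self):
        ann = _ann({"a": np.array([[3]]), "b": np.array([[3]]), "c": np.array([[4]])})
        assert majority_vote(ann)[0, 0] == 3

    def test_unanimous(self):
        ann = _ann({"a": np.array([[5]]), "b": np.array([[5]])})
        assert majority_vote(ann)[0, 0] == 5

    def test_two_two_tie_broken_by_seniority(self):
        masks = {"r1": np.array([[3]]), "r2": np.array([[3]]),
                 "r3": np.array([[4]]), "r4": np.array([[4]])}
        out = majority_vote(_ann(masks, {"r1": 4, "r2": 3, "r3": 1, "r4": 2}))
        assert out[0, 0] == 4                           # most senior (r3) says 4

    def test_matches_counting_oracle_on_small_vote_tables(self):
        # enumerate all 3-rater label combinations on a single pixel
        labels = (0, 3, 4, 5)
        sen = {"a": 1, "b": 2, "c": 3}
        for va, vb, vc in itertools.product(labels, repeat=3):
            ann = _ann({"a": np.array([[va]]), "b": np.array([[vb]]),
                        "c": np.array([[vc]])}, sen)
            out = majority_vote(ann)[0, 0]
            counts = {l: [va, vb, vc].count(l) for l in labels}
            top = max(counts.values())
            winners = [l for l, n in counts.items() if n == top]
            if len(winners) == 1:
                assert out == winners[0]
            else:
                assert out == va                        # most senior rater's label
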