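"""Spectral recall, threshold selection and PCA realism."""

import numpy as np
import pytest

from tissuelight.realism import (
    RecallConfig,
    SpectraSet,
    hierarchical_recall,
    nearest_distances,
    pca_realism,
    select_threshold,
    spectral_mae,
    spectral_recall,
    subsample_equal,
)


def make_set(spectra, **kw):
    spectra = np.asarray(spectra, float)
    return SpectraSet(spectra, np.arange(spectra.shape[1], dtype=float), **kw)


def brute_force_min_distances(a, b):
    """Independent double-loop oracle for nearest spectral MAE."""
    out = np.empty(len(a))
    for i, ai in enumerate(a):
        best = np.inf
        for bj in b:
            d = np.mean(np.abs(np.asarray(ai) - np.asarray(bj)))
            best = min(best, d)
        out[i] = best
    return out


class TestSpectralMAE:
    def test_identical_is_zero(self):
        a = np.linspace(0, 1, 8)
        assert spectral_mae(a, a) == 0.0

    def test_constant_offset(self):
        a = np.full(10, 0.4)
        assert spectral_mae(a, a + 0.05) == pytest.approx(0.05)

    def test_maximal_on_unit_range(self):
        assert spectral_mae(np.array([0.0, 1.0]), np.array([1.0, 0.0])) == 1.0

    def test_symmetry_and_grid_check(self, rng):
        a, b = rng.random(16), rng.random(16)
        assert spectral_mae(a, b) == spectral_mae(b, a)
        with pytest.raises(ValueError):
            spectral_mae(a, rng.random(8))


class TestSpectralRecall:
    def test_superset_gives_full_recall(self, rng):
        a = make_set(rng.random((20, 8)))
        b = make_set(np.vstack([a.spectra, rng.random((10, 8))]))
        assert spectral_recall(a, b, RecallConfig(0.001)) == 1.0

    def test_all_far_gives_zero(self):
        a = make_set(np.zeros((5, 6)))
        b = make_set(np.ones((4, 6)))
        assert spectral_recall(a, b, RecallConfig(0.02)) == 0.0

    def test_matches_brute_force_exactly(self, rng):
        a = rng.random((50, 8))
        b = rng.random((70, 8))
        oracle = brute_force_min_distances(a, b)
        fast = nearest_distances(a, b)
        assert np.array_equal(fast, oracle)
        for d_max in (0.05, 0.1, 0.2):
            expected = float(np.mean(oracle < d_max))
            assert spectral_recall(make_set(a), make_set(b),
                                   RecallConfig(d_max)) == expected

    def test_strict_inequality_at_threshold(self):
        """A candidate at exactly d_max counts as a miss."""
        a = make_set([[0.5, 0.5]])
        b = make_set([[0.52, 0.52]])  # MAE exactly 0.02
        assert spectral_recall(a, b, RecallConfig(0.02)) == 0.0
        assert spectral_recall(a, b, RecallConfig(0.020001)) == 1.0

    def test_monotone_in_threshold_and_candidates(self, rng):
        a = make_set(rng.random((30, 10)))
        b_small = rng.random((10, 10))
        b_big = np.vstack([b_small, rng.random((40, 10))])
        prev = 0.0
        for d_max in (0.01, 0.05, 0.1, 0.3):
            r = spectral_recall(a, make_set(b_small), RecallConfig(d_max))
            assert r >= prev
            prev = r
            assert spectral_recall(a, make_set(b_big), RecallConfig(d_max)) >= r

    def test_empty_sets_rejected(self, rng):
        a = make_set(rng.random((3, 4)))
        with pytest.raises(ValueError):
            spectral_recall(a, make_set(np.empty((0, 4))))


class TestHierarchicalRecall:
    def test_degenerate_hierarchy_equals_plain_recall(self, rng):
        spectra = rng.random((25, 6))
        ann = make_set(spectra, subject_id=np.full(25, "s1"),
                       class_label=np.full(25, "liver"))
        b = make_set(rng.random((40, 6)))
        cfg = RecallConfig(0.08)
        assert hierarchical_recall(ann, b, cfg) == {
            "liver": spectral_recall(ann, b, cfg)}

    def test_subjects_weighted_equally(self):
        """Per-subject recalls 1.0 and 0.0 average to 0.5 regardless of size."""
        hits = np.full((30, 4), 0.5)
        misses = np.full((3, 4), 0.9)
        a = make_set(np.vstack([hits, misses]),
                     subject_id=np.array(["p1"] * 30 + ["p2"] * 3),
                     class_label=np.full(33, "colon"))
        b = make_set(np.full((5, 4), 0.5))
        assert hierarchical_recall(a, b, RecallConfig(0.01)) == {"colon": 0.5}

    def test_hand_computed_three_subject_enumeration(self, rng):
        subjects = np.array(["p1"] * 6 + ["p2"] * 6 + ["p3"] * 4)
        classes = np.array(["a", "a", "b", "b", "c", "d"] * 2 + ["a", "b", "c", "d"])
        spectra = rng.random((16, 5))
        a = make_set(spectra, subject_id=subjects, class_label=classes)
        b = make_set(rng.random((30, 5)))
        cfg = RecallConfig(0.12)
        hits = nearest_distances(spectra, b.spectra) < cfg.d_max
        expected = {}
        for cls in "abcd":
            per_subject = []
            for s in ("p1", "p2", "p3"):
                m = (subjects == s) & (classes == cls)
                if m.any():
                    per_subject.append(hits[m].mean())
            expected[cls] = float(np.mean(per_subject))
        assert hierarchical_recall(a, b, cfg) == expected

    def test_missing_annotations_rejected(self, rng):
        a = make_set(rng.random((4, 5)))
        with pytest.raises(ValueError):
            hierarchical_recall(a, a)


class TestSelectThreshold:
    def test_single_step_curve(self):
        a = make_set(np.zeros((10, 4)))
        b = make_set(np.full((10, 4), 0.019))  # all distances exactly 0.019
        grid = np.array([0.005, 0.01, 0.02, 0.05])
        # recall jumps 0 -> 1 between 0.01 and 0.02: steepest point is 0.02
        assert select_threshold(a, [b], grid) == 0.02

    def test_lowest_across_candidates(self):
        a = make_set(np.zeros((10, 4)))
        near = make_set(np.full((10, 4), 0.015))
        far = make_set(np.full((10, 4), 0.045))
        grid = np.array([0.01, 0.02, 0.05, 0.08])
        assert select_threshold(a, [near, far], grid) == 0.02
        assert select_threshold(a, [far], grid) == 0.05

    def test_flat_curve_signals_smallest_point(self):
        a = make_set(np.zeros((5, 4)))
        b = make_set(np.ones((5, 4)))  # no recall anywhere on the grid
        grid = np.array([0.001, 0.01, 0.1])
        assert select_threshold(a, [b], grid) == 0.001

    def test_gaussian_perturbation_scale_detected(self, rng):
        """Steepest increase sits near the noise scale of perturbed copies."""
        base = rng.random((200, 20)) * 0.5 + 0.25
        noise = rng.normal(0, 0.01, base.shape)
        a = make_set(np.clip(base, 0, 1))
        b = make_set(np.clip(base + noise, 0, 1))
        grid = np.logspace(-3, -1, 50)
        t = select_threshold(a, [b], grid)
        # mean |N(0, 0.01)| ~ 0.008; steepest recall increase within a factor 2
        assert 0.004 < t < 0.016


class TestSubsampleEqual:
    def test_sizes_and_determinism(self, rng):
        sets = [make_set(rng.random((30, 5))), make_set(rng.random((50, 5)))]
        out1 = subsample_equal(sets, 20, seed=4)
        out2 = subsample_equal(sets, 20, seed=4)
        assert all(len(s) == 20 for s in out1)
        assert np.array_equal(out1[0].spectra, out2[0].spectra)
        with pytest.raises(ValueError):
            subsample_equal(sets, 40, seed=4)


class TestPCARealism:
    def _annotated(self, spectra, n_images=4):
        n = spectra.shape[0]
        return make_set(spectra,
                        subject_id=np.array([f"p{i % 2}" for i in range(n)]),
                        class_label=np.array([f"c{i % 2}" for i in range(n)]),
                        image_id=np.array([f"im{i % n_images}" for i in range(n)]))

    def test_self_candidate_identical_embedding(self, rng):
        spectra = rng.random((40, 12))
        ref = self._annotated(spectra)
        res = pca_realism(ref, [make_set(spectra)])
        assert np.allclose(res.candidate_embeddings[0], res.project(spectra))

    def test_constant_shift_projects_linearly(self, rng):
        spectra = rng.random((40, 12)) * 0.5
        ref = self._annotated(spectra)
        shift = np.full(12, 0.1)
        res = pca_realism(ref, [make_set(spectra), make_set(spectra + shift)])
        delta = res.candidate_embeddings[1] - res.candidate_embeddings[0]
        assert np.allclose(delta, shift @ res.components.T, atol=1e-9)

    def test_rank_two_reference_fully_explained(self, rng):
        u = rng.random((60, 2))
        basis = rng.random((2, 15))
        spectra = np.clip(0.2 + u @ basis * 0.3, 0, 1)
        ref = self._annotated(spectra, n_images=10)
        res = pca_realism(ref, [])
        assert res.explained_variance_ratio.sum() >= 0.999

    def test_too_few_averaged_spectra_rejected(self, rng):
        spectra = rng.random((4, 6))
        ref = make_set(spectra, subject_id=np.full(4, "p"),
                       class_label=np.full(4, "c"), image_id=np.full(4, "im0"))
        with pytest.raises(ValueError):
            pca_realism(ref, [])  # single averaged spectrum < 2 components
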