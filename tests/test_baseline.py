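"""Behaviour baseline: posterior, saliency maps, candidate set, hit test."""

import math

import numpy as np
import pytest

from glimpsekit.baseline import (
    DEFAULT_EPSILON,
    Belief,
    SalientTriple,
    build_saliency,
    candidate_locations,
    class_posterior,
    gaussian_kernel,
    location_hit,
    pairwise_score,
    predict_session,
    top_k_classes,
)
from glimpsekit.stimuli import ClassTemplate
from glimpsekit.task_env import Episode, Session, reveal

from conftest import toy_templates

# ---------------------------------------------------------------------------
# independent oracles


def bruteforce_posterior(observed, templates):
    obs = observed.ravel() / np.linalg.norm(observed)
    sims = []
    for t in templates:
        tv = t.mean_image.ravel()
        sims.append(float(obs @ (tv / np.linalg.norm(tv))))
    total = sum(sims)
    return np.array([s / total for s in sims])


def bruteforce_convolve_reflect(score, kernel):
    """Naive O(P*K) sliding-window convolution with edge-reflect padding
    (half-sample symmetric, i.e. the boundary pixel is repeated)."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(score, ((ph, ph), (pw, pw)), mode="symmetric")
    out = np.zeros_like(score, dtype=float)
    for r in range(score.shape[0]):
        for c in range(score.shape[1]):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    # convolution flips the kernel (symmetric here, but keep it honest)
                    acc += padded[r + kh - 1 - i, c + kw - 1 - j] * kernel[i, j]
            out[r, c] = acc
    return out


def bruteforce_gamma(sal, c_t, visited):
    triples = set()
    for (i, j), m in sal.maps.items():
        if i not in c_t and j not in c_t:
            continue
        for r in range(m.shape[0]):
            for c in range(m.shape[1]):
                if m[r, c] > sal.theta and (r, c) not in visited:
                    triples.add(SalientTriple((r, c), i, j))
    return triples


# ---------------------------------------------------------------------------


class TestClassPosterior:
    def test_two_identical_templates_split_evenly(self, rng):
        img = rng.uniform(0.1, 1, size=(6, 5))
        tpls = [ClassTemplate(img.copy(), 1), ClassTemplate(img.copy(), 2)]
        belief = class_posterior(rng.uniform(0.1, 1, size=(6, 5)), tpls)
        np.testing.assert_allclose(belief.probs, [0.5, 0.5])

    def test_disjoint_support_gets_zero(self):
        t1 = np.zeros((4, 4))
        t1[:2] = 1.0
        t2 = np.zeros((4, 4))
        t2[2:] = 1.0
        tpls = [ClassTemplate(t1, 1), ClassTemplate(t2, 2)]
        belief = class_posterior(t1.copy(), tpls)
        np.testing.assert_allclose(belief.probs, [1.0, 0.0], atol=1e-12)

    def test_matches_bruteforce_on_random_toys(self, rng):
        for _ in range(30):
            tpls = toy_templates(3, seed=int(rng.integers(1 << 30)))
            obs = rng.uniform(0, 1, size=(6, 5))
            obs[obs < 0.3] = 0.0
            if not obs.any():
                continue
            belief = class_posterior(obs, tpls)
            np.testing.assert_allclose(belief.probs, bruteforce_posterior(obs, tpls), atol=1e-12)
            assert belief.probs.sum() == pytest.approx(1.0)

    def test_invariant_to_positive_rescaling(self, rng):
        tpls = toy_templates(4, seed=3)
        obs = rng.uniform(0.1, 1, size=(6, 5))
        a = class_posterior(obs, tpls).probs
        b = class_posterior(37.5 * obs, tpls).probs
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_allzero_observation_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            class_posterior(np.zeros((6, 5)), toy_templates(2))

    def test_monotone_evidence_for_exclusive_pixels(self):
        # pixels present only in class 1's template never hurt class 1
        t1 = np.array([[1.0, 0.8, 0.0], [0.5, 0.0, 0.0]])
        t2 = np.array([[0.0, 0.8, 0.5], [0.5, 0.0, 0.9]])
        tpls = [ClassTemplate(t1, 1), ClassTemplate(t2, 2)]
        shared_only = np.array([[0.0, 0.8, 0.0], [0.5, 0.0, 0.0]])
        with_exclusive = shared_only.copy()
        with_exclusive[0, 0] = 1.0  # only class 1 has ink here
        before = class_posterior(shared_only, tpls).probs[0]
        after = class_posterior(with_exclusive, tpls).probs[0]
        assert after > before


class TestTopK:
    def test_examples(self):
        b = Belief((1, 2, 3), np.array([0.5, 0.3, 0.2]))
        assert top_k_classes(b, 2) == {1, 2}
        assert top_k_classes(b, 3) == {1, 2, 3}

    def test_uniform_tie_breaks_to_small_ids(self):
        b = Belief.uniform((1, 2, 3, 4))
        assert top_k_classes(b, 1) == {1}
        assert top_k_classes(b, 2) == {1, 2}

    def test_k_out_of_range(self):
        b = Belief.uniform((1, 2))
        with pytest.raises(ValueError, match="k must be"):
            top_k_classes(b, 0)
        with pytest.raises(ValueError, match="k must be"):
            top_k_classes(b, 3)


class TestPairwiseScore:
    def test_diff_of_identical_is_zero(self, rng):
        img = rng.uniform(0, 1, size=(5, 5))
        assert not pairwise_score(img, img, mode="diff").any()

    def test_kl_of_identical_is_tiny(self, rng):
        img = rng.uniform(0, 1, size=(5, 5))
        out = pairwise_score(img, img, mode="kl", delta=1e-7)
        assert np.abs(out).max() < 1e-5

    def test_single_pixel_diff(self):
        out = pairwise_score(np.array([[0.8]]), np.array([[0.2]]), mode="diff")
        assert out[0, 0] == pytest.approx(0.6)

    def test_diff_antisymmetry(self, rng):
        a, b = rng.uniform(0, 1, size=(2, 5, 5))
        np.testing.assert_allclose(
            pairwise_score(a, b, "diff"), -pairwise_score(b, a, "diff")
        )

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown saliency mode"):
            pairwise_score(np.ones((2, 2)), np.ones((2, 2)), mode="l2")


class TestBuildSaliency:
    def test_kernel_normalised(self):
        k = gaussian_kernel(5, 6.0)
        assert k.shape == (5, 5)
        assert k.sum() == pytest.approx(1.0)
        # sigma=6 over a 5x5 support: nearly uniform
        assert k.max() / k.min() < 1.2

    def test_identical_templates_give_zero_maps_and_theta(self, rng):
        img = rng.uniform(0, 1, size=(6, 5))
        tpls = [ClassTemplate(img.copy(), i) for i in (1, 2, 3)]
        sal = build_saliency(tpls, mode="diff")
        assert sal.theta == 0.0
        assert all(not m.any() for m in sal.maps.values())

    def test_impulse_smoothing_preserves_mass(self):
        t1 = np.zeros((9, 9))
        t1[4, 4] = 1.0
        t2 = np.zeros((9, 9))
        tpls = [ClassTemplate(t1, 1), ClassTemplate(t2, 2)]
        sal = build_saliency(tpls, mode="diff")
        assert sal.maps[(1, 2)].sum() == pytest.approx(1.0)

    def test_matches_naive_convolution(self, rng):
        tpls = toy_templates(2, shape=(8, 7), seed=77)
        for mode in ("diff", "kl"):
            sal = build_saliency(tpls, mode=mode)
            kernel = gaussian_kernel(5, 6.0)
            for (i, j), got in sal.maps.items():
                ti = tpls[i - 1].mean_image
                tj = tpls[j - 1].mean_image
                score = pairwise_score(ti, tj, mode=mode)
                np.testing.assert_allclose(
                    got, bruteforce_convolve_reflect(score, kernel), atol=1e-10
                )

    def test_theta_is_half_global_max(self, small_saliency):
        global_max = max(float(m.max()) for m in small_saliency.maps.values())
        assert small_saliency.theta == pytest.approx(0.5 * global_max)


class TestCandidateLocations:
    def test_unreachable_theta_gives_empty_gamma(self, rng):
        tpls = toy_templates(2, seed=5)
        sal = build_saliency(tpls, mode="diff")
        sal.theta = max(float(m.max()) for m in sal.maps.values()) + 1.0
        assert candidate_locations(sal, {1}, []) == set()

    def test_visited_locations_excluded(self, rng):
        tpls = toy_templates(2, seed=6)
        sal = build_saliency(tpls, mode="diff")
        everything = [(r, c) for r in range(6) for c in range(5)]
        assert candidate_locations(sal, {1, 2}, everything) == set()

    def test_matches_bruteforce_scan(self, rng):
        tpls = toy_templates(3, shape=(7, 6), seed=8)
        sal = build_saliency(tpls, mode="diff")
        visited = [(0, 0), (3, 3), (6, 5)]
        got = candidate_locations(sal, {2}, visited)
        assert got == bruteforce_gamma(sal, {2}, set(visited))
        assert all(t.for_class == 2 or t.against_class == 2 for t in got)


class TestLocationHit:
    triple = SalientTriple((10, 10), 1, 2)

    def test_exact_location_hit(self):
        assert location_hit({self.triple}, (10, 10), {1, 3})

    def test_distance_three_misses_default_epsilon(self):
        assert not location_hit({self.triple}, (13, 10), {1})
        assert DEFAULT_EPSILON == pytest.approx(2 * math.sqrt(2))

    def test_strict_inequality_at_epsilon(self):
        # distance exactly 2*sqrt(2) must miss
        assert not location_hit({self.triple}, (12, 12), {1})
        assert location_hit({self.triple}, (12, 11), {1})

    def test_class_clauses(self):
        assert not location_hit({self.triple}, (10, 10), {3})  # i not selected
        assert not location_hit({self.triple}, (10, 10), {1, 2})  # j not rejected


class TestPredictSession:
    def test_aligned_outputs_and_copycat_similarity(self, small_set, small_saliency):
        stimuli, templates = small_set
        stim = stimuli[0]
        locs = [(13, 12), (5, 5), (20, 18), (8, 16)]
        episodes = [
            Episode(t=k + 1, row=r, col=c, classes=frozenset({stim.class_id}))
            for k, (r, c) in enumerate(locs)
        ]
        session = Session.from_episodes("x", "synthetic", stim.class_id, episodes)
        pred = predict_session(session, stim, templates, small_saliency)
        assert len(pred.pred_classes) == 4
        assert len(pred.loc_hits) == 4
        assert pred.loc_hits[-1] is None
        assert all(len(c) == 1 for c in pred.pred_classes)  # k = |c_t| = 1
        # the model sees what the participant saw
        observed = reveal(stim, locs)
        assert observed.any()
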