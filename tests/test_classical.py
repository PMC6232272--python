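"""Random forest, HMM Viterbi smoothing and median filter tests.

The Viterbi decoder is checked against exhaustive path enumeration, the
only authority needed for a discrete MAP path.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from somnostage.classical import (
    PosteriorMatrix,
    TransitionModel,
    estimate_transition_model,
    median_smooth,
    predict_proba,
    train_rf,
    viterbi_smooth,
)
from somnostage.core import STAGES, Hypnogram, n_stage_transitions
from somnostage.features import FEATURE_NAMES, FeatureMatrix


def _fm(X):
    names = tuple(f"f{i}" for i in range(X.shape[1]))
    return FeatureMatrix(X, names, 20)


def brute_force_map_path(posteriors: np.ndarray, tm: TransitionModel) -> list[int]:
    """Enumerate every stage path and maximize the HMM score (oracle)."""
    n, k = posteriors.shape
    em = posteriors / tm.priors[None, :]
    best, best_score = None, -np.inf
    for path in itertools.product(range(k), repeat=n):
        score = tm.initial[path[0]] * em[0, path[0]]
        for t in range(1, n):
            score *= tm.transitions[path[t - 1], path[t]] * em[t, path[t]]
        if score > best_score:  # strict: first (lowest-index) path wins ties
            best, best_score = path, score
    return list(best)


def _random_tm(rng, n_active=3):
    k = len(STAGES)
    trans = rng.random((k, k)) + 0.05
    trans /= trans.sum(axis=1, keepdims=True)
    init = rng.random(k) + 0.05
    prior = rng.random(k) + 0.05
    return TransitionModel(trans, init / init.sum(), prior / prior.sum())


class TestTrainRF:
    def _clouds(self, rng, n=200):
        X = np.concatenate([rng.normal(0, 1, (n // 2, 5)), rng.normal(6, 1, (n // 2, 5))])
        y = ["W"] * (n // 2) + ["N2"] * (n // 2)
        return _fm(X), y

    def test_separable_clouds_high_training_accuracy(self, rng):
        fm, y = self._clouds(rng)
        model = train_rf(fm, y, n_trees=50, seed=0)
        pred = predict_proba(model, fm).argmax_stages()
        assert np.mean([a == b for a, b in zip(pred, y)]) >= 0.95

    def test_same_seed_identical_predictions(self, rng):
        fm, y = self._clouds(rng)
        probe = _fm(rng.normal(3, 2, (50, 5)))
        p1 = predict_proba(train_rf(fm, y, n_trees=50, seed=1), probe).probs
        p2 = predict_proba(train_rf(fm, y, n_trees=50, seed=1), probe).probs
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (30, 5))
        with pytest.raises(ValueError, match="single class"):
            train_rf(_fm(X), ["N2"] * 30, n_trees=10, seed=0)


class TestPredictProba:
    def test_rows_sum_to_one_and_absent_classes_zero(self, rng):
        X = np.concatenate([rng.normal(0, 1, (40, 4)), rng.normal(5, 1, (40, 4))])
        y = ["N1"] * 40 + ["N3"] * 40
        model = train_rf(_fm(X), y, n_trees=30, seed=0)
        post = predict_proba(model, _fm(rng.normal(2, 2, (20, 4))))
        assert np.allclose(post.probs.sum(axis=1), 1.0)
        assert np.all(post.probs[:, [0, 2, 4]] == 0)  # W, N2, R unseen

    def test_argmax_matches_forest_prediction(self, rng):
        X = np.concatenate([rng.normal(0, 1, (40, 4)), rng.normal(5, 1, (40, 4))])
        y = ["W"] * 40 + ["R"] * 40
        model = train_rf(_fm(X), y, n_trees=30, seed=0)
        probe = _fm(rng.normal(2, 2, (30, 4)))
        stages = predict_proba(model, probe).argmax_stages()
        direct = [STAGES[int(c)] for c in model.forest.predict(probe.values)]
        assert stages == direct

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.normal(0, 1, (40, 4))
        model = train_rf(_fm(X), ["W"] * 20 + ["R"] * 20, n_trees=10, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            predict_proba(model, _fm(rng.normal(0, 1, (5, 6))))


class TestTransitionModel:
    def test_add_one_counts_single_hypnogram(self):
        tm = estimate_transition_model([Hypnogram(["W", "W", "N1", "N2", "N2"], 20)], add_k=1)
        # W row: counts W->W 1, W->N1 1, plus add-one over five states
        np.testing.assert_allclose(tm.transitions[0], np.array([2, 2, 1, 1, 1]) / 7)

    def test_rows_positive_and_stochastic(self):
        tm = estimate_transition_model([Hypnogram(["W"] * 50, 20)])
        assert np.allclose(tm.transitions.sum(axis=1), 1.0)
        assert np.all(tm.transitions > 0)
        assert tm.transitions[0].argmax() == 0


class TestViterbiSmooth:
    def test_single_epoch_is_rescaled_argmax(self, rng):
        tm = _random_tm(rng)
        post = rng.random((1, 5)) + 0.01
        post /= post.sum()
        out = viterbi_smooth(PosteriorMatrix(post), tm)
        expected = STAGES[int(np.argmax(tm.initial * post[0] / tm.priors))]
        assert out == [expected]

    def test_uniform_model_reduces_to_per_epoch_argmax(self, rng):
        k = len(STAGES)
        tm = TransitionModel(np.full((k, k), 1 / k), np.full(k, 1 / k), np.full(k, 1 / k))
        post = rng.random((20, k)) + 0.01
        post /= post.sum(axis=1, keepdims=True)
        assert viterbi_smooth(PosteriorMatrix(post), tm) == PosteriorMatrix(post).argmax_stages()

    def test_sticky_two_state_example(self):
        """Self-transition 0.9 outweighs the middle epoch's 0.6 posterior;
        verified by enumerating all eight paths."""
        k = len(STAGES)
        trans = np.full((k, k), 1e-6)
        trans[0, 0] = trans[1, 1] = 0.9
        trans[0, 1] = trans[1, 0] = 0.1
        trans /= trans.sum(axis=1, keepdims=True)
        tm = TransitionModel(trans, np.full(k, 1 / k), np.full(k, 1 / k))
        post = np.full((3, k), 1e-9)
        post[0, :2] = [0.6, 0.4]
        post[1, :2] = [0.4, 0.6]
        post[2, :2] = [0.6, 0.4]
        post /= post.sum(axis=1, keepdims=True)
        pm = PosteriorMatrix(post)
        assert viterbi_smooth(pm, tm) == ["W", "W", "W"]
        assert [STAGES.index(s) for s in viterbi_smooth(pm, tm)] == brute_force_map_path(pm.probs, tm)

    @pytest.mark.parametrize("case", range(50))
    def test_matches_exhaustive_enumeration(self, case):
        """Randomized instances up to 8 epochs / 3 active states."""
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(1, 9))
        active = rng.choice(5, size=int(rng.integers(2, 4)), replace=False)
        post = np.full((n, 5), 1e-12)
        post[:, active] = rng.random((n, active.size)) + 0.05
        post /= post.sum(axis=1, keepdims=True)
        tm = _random_tm(rng)
        ours = [STAGES.index(s) for s in viterbi_smooth(PosteriorMatrix(post), tm)]
        assert ours == brute_force_map_path(post, tm)


class TestMedianSmoothProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    stage_seqs = st.lists(st.sampled_from(STAGES), min_size=1, max_size=60)

    @given(stage_seqs)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_output_stages_come_from_the_local_window(self, stages):
        out = median_smooth(stages)
        assert out[0] == stages[0] and out[-1] == stages[-1]
        for i in range(1, len(out) - 1):
            assert out[i] in stages[i - 1 : i + 2]

    @given(stage_seqs)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_smoothing_never_adds_transitions(self, stages):
        assert n_stage_transitions(median_smooth(stages)) <= n_stage_transitions(stages)


class TestMedianSmooth:
    def test_despikes_isolated_epoch(self):
        assert median_smooth(["N2", "N2", "W", "N2", "N2"]) == ["N2"] * 5

    def test_constant_unchanged(self):
        assert median_smooth(["R"] * 7) == ["R"] * 7

    def test_all_distinct_window_keeps_centre(self):
        assert median_smooth(["W", "N1", "N2"]) == ["W", "N1", "N2"]

    def test_never_introduces_foreign_stage(self, rng):
        stages = [STAGES[i] for i in rng.integers(0, 5, 60)]
        out = median_smooth(stages)
        for i in range(1, len(out) - 1):
            assert out[i] in stages[i - 1 : i + 2]

    def test_never_increases_transitions(self, rng):
        for _ in range(20):
            stages = [STAGES[i] for i in rng.integers(0, 5, 50)]
            assert n_stage_transitions(median_smooth(stages)) <= n_stage_transitions(stages)
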