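"""Random-forest staging with temporal smoothing.

A random forest predicts a per-epoch probability vector over the five
stages (the fraction of trees voting for each class). Because the forest
treats epochs independently, its output is smoothed in time in one of two
ways, mirroring how experts use context when scoring:

* a hidden Markov model whose transition matrix is estimated from training
  hypnograms; the most probable stage path is decoded with the Viterbi
  algorithm, using posterior-to-likelihood rescaling (posteriors divided by
  the training class priors) as emission scores;
* a three-epoch median filter that removes isolated single-epoch stages.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import STAGES, Hypnogram, stage_index, stages_to_indices
from .features import FeatureMatrix

_N = len(STAGES)

RF_DEFAULT_TREES = 500


@dataclass
class PosteriorMatrix:
    """Epochs x 5 class probabilities over (W, N1, N2, N3, R)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != _N:
            raise ValueError("posterior matrix must be epochs x 5")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")

    @property
    def n_epochs(self) -> int:
        return self.probs.shape[0]

    def argmax_stages(self) -> list[str]:
        return [STAGES[i] for i in self.probs.argmax(axis=1)]


@dataclass
class TransitionModel:
    """Stage-transition statistics for HMM smoothing.

    ``transitions`` is row-stochastic over (W, N1, N2, N3, R); ``initial``
    is the first-epoch distribution and ``priors`` the pooled stage
    frequencies used to rescale classifier posteriors into likelihoods.
    All entries are strictly positive after add-k smoothing.
    """

    transitions: np.ndarray
    initial: np.ndarray
    priors: np.ndarray

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if self.transitions.shape != (_N, _N):
            raise ValueError("transition matrix must be 5x5")
        for name, v in (("initial", self.initial), ("priors", self.priors)):
            if v.shape != (_N,):
                raise ValueError(f"{name} must be a 5-vector")
            if not np.isclose(v.sum(), 1.0, atol=1e-12):
                raise ValueError(f"{name} must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.transitions <= 0) or np.any(self.initial <= 0) or np.any(self.priors <= 0):
            raise ValueError("smoothed model entries must be strictly positive")


@dataclass
class RFModel:
    """Trained forest plus the metadata needed to apply it consistently."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    class_order: tuple[str, ...] = STAGES

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "wb") as f:
            pickle.dump(self, f)

    @staticmethod
    def load(path: Union[str, Path]) -> "RFModel":
        with open(path, "rb") as f:
            model = pickle.load(f)
        if not isinstance(model, RFModel):
            raise TypeError(f"{path} does not contain an RFModel")
        return model


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------


def train_rf(
    features: FeatureMatrix,
    labels: Sequence[str],
    n_trees: int = RF_DEFAULT_TREES,
    seed: int = 0,
) -> RFModel:
    """Train a bootstrap forest with sqrt-of-20 feature subsets per split."""
    y = stages_to_indices(labels)
    if features.n_epochs != y.size:
        raise ValueError("feature rows and labels must align")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class; at least two stages required")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(features.values, y)
    return RFModel(forest=forest, feature_names=features.feature_names)


def predict_proba(model: RFModel, features: FeatureMatrix) -> PosteriorMatrix:
    """Vote fractions over all five stages; absent training classes get 0."""
    if features.values.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature dimension {features.values.shape[1]} does not match the "
            f"model's {len(model.feature_names)}"
        )
    raw = model.forest.predict_proba(features.values)
    probs = np.zeros((features.n_epochs, _N))
    for col, cls in enumerate(model.forest.classes_):
        probs[:, int(cls)] = raw[:, col]
    return PosteriorMatrix(probs)


# ---------------------------------------------------------------------------
# HMM smoothing
# ---------------------------------------------------------------------------


def estimate_transition_model(
    training_hypnograms: Sequence[Hypnogram],
    add_k: float = 1.0,
) -> TransitionModel:
    """Pool bigram counts over hypnograms with add-k smoothing."""
    if len(training_hypnograms) < 1:
        raise ValueError("at least one training hypnogram is required")
    trans = np.full((_N, _N), add_k, dtype=float)
    init = np.full(_N, add_k, dtype=float)
    prior = np.full(_N, add_k, dtype=float)
    for hyp in training_hypnograms:
        idx = hyp.as_indices()
        init[idx[0]] += 1
        np.add.at(prior, idx, 1)
        np.add.at(trans, (idx[:-1], idx[1:]), 1)
    return TransitionModel(
        transitions=trans / trans.sum(axis=1, keepdims=True),
        initial=init / init.sum(),
        priors=prior / prior.sum(),
    )


def viterbi_smooth(posteriors: PosteriorMatrix, tm: TransitionModel) -> list[str]:
    """Maximum-a-posteriori stage path under the HMM.

    Emission scores are the classifier posteriors divided by the training
    priors (posterior-to-likelihood rescaling); decoding runs in log space.
    Ties break toward the lower stage index in (W, N1, N2, N3, R).
    """
    with np.errstate(divide="ignore"):
        log_em = np.log(posteriors.probs) - np.log(tm.priors)[None, :]
        log_tr = np.log(tm.transitions)
        log_init = np.log(tm.initial)
    n = posteriors.n_epochs
    delta = log_init + log_em[0]
    back = np.zeros((n, _N), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + log_tr  # cand[i, j]: best-so-far into j via i
        back[t] = cand.argmax(axis=0)  # argmax takes the lowest index on ties
        delta = cand[back[t], np.arange(_N)] + log_em[t]
    if not np.any(np.isfinite(delta)):
        raise ValueError("all paths have zero probability; cannot decode")
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return [STAGES[i] for i in path]


# ---------------------------------------------------------------------------
# Median filter
# ---------------------------------------------------------------------------


def median_smooth(stages: Sequence[str], window: int = 3) -> list[str]:
    """Three-epoch median filter for categorical stage sequences.

    An interior epoch whose two neighbours agree on a different stage is
    replaced by that stage; everything else (including the first and last
    epochs) is kept. Single pass. This equals a true running median for
    every window-3 case with a repeated value and is invariant to how the
    stages would be ordered numerically.
    """
    if window != 3:
        raise ValueError("only the three-epoch window is defined")
    out = list(stages)
    for i in range(1, len(out) - 1):
        if stages[i - 1] == stages[i + 1] and stages[i - 1] != stages[i]:
            out[i] = stages[i - 1]
    return out
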