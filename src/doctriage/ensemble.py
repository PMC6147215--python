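"""Three combiners over per-model predictions: majority vote, weighted
majority vote with an exhaustive grid search over simplex weights, and
logistic-regression stacking on the models' class probabilities.

Throughout, an exact tie between the two classes resolves to the
negative class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .evaluation import confusion, metrics
from .nn.models import PredictionRecord

__all__ = [
    "majority_vote",
    "weighted_vote",
    "enumerate_weight_grid",
    "grid_search_weights",
    "stack_features",
    "StackingModel",
    "fit_stacker",
    "stacker_predict",
    "ensemble_majority",
    "ensemble_weighted",
    "ensemble_stacking",
]


def majority_vote(decisions: Sequence[int]) -> int:
    """Class with the most votes; an equal split elects the negative class."""
    if len(decisions) == 0:
        raise ValueError("no votes")
    ones = sum(1 for d in decisions if d == 1)
    zeros = len(decisions) - ones
    return 1 if ones > zeros else 0


def weighted_vote(decisions: Sequence[int], weights: Sequence[float]) -> int:
    """Class with the largest weighted vote mass; ties are negative.
    Uniform weights reduce to majority_vote."""
    if len(decisions) != len(weights):
        raise ValueError("weights and votes differ in length")
    mass_pos = sum(w for d, w in zip(decisions, weights) if d == 1)
    mass_neg = sum(w for d, w in zip(decisions, weights) if d == 0)
    return 1 if mass_pos > mass_neg else 0


def enumerate_weight_grid(T: int, steps: int = 10) -> list[tuple[float, ...]]:
    """Every weight vector on the simplex grid {0, 1/steps, ..., 1} with
    sum exactly 1, in lexicographic order.  Generated as integer parts of
    `steps` divided once, so the sum is bit-exact."""
    if T < 1:
        raise ValueError("need at least one classifier")
    out: list[tuple[float, ...]] = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            out.append(tuple((*prefix, remaining)))
            return
        for v in range(remaining + 1):
            rec(prefix + [v], remaining - v, slots - 1)

    rec([], steps, T)
    return [tuple(v / steps for v in w) for w in out]


def _decision_matrix(per_model: Sequence[Sequence[PredictionRecord]]) -> np.ndarray:
    """(n_docs, T) hard decisions; checks document alignment."""
    T = len(per_model)
    if T == 0:
        raise ValueError("no models")
    ids = [r.doc_id for r in per_model[0]]
    for preds in per_model[1:]:
        if [r.doc_id for r in preds] != ids:
            raise ValueError("prediction files are not aligned on doc_id")
    return np.array([[r.decision for r in preds] for preds in per_model]).T


def grid_search_weights(
    dev_predictions: Sequence[Sequence[PredictionRecord]],
    dev_labels: Sequence[int],
    steps: int = 10,
) -> tuple[tuple[float, ...], float]:
    """Exhaustively search the quantized simplex for the weights that
    maximize dev F1 (percent).  Ties prefer the lexicographically
    smallest weight tuple."""
    if len(dev_labels) == 0:
        raise ValueError("empty development set")
    D = _decision_matrix(dev_predictions)  # (n, T)
    if D.shape[0] != len(dev_labels):
        raise ValueError("predictions and labels differ in length")
    best_w: tuple[float, ...] | None = None
    best_f1 = -1.0
    for w in enumerate_weight_grid(D.shape[1], steps=steps):
        decisions = [weighted_vote(row, w) for row in D]
        f1 = metrics(confusion(decisions, dev_labels)).f1
        if f1 > best_f1:
            best_f1, best_w = f1, w
    assert best_w is not None
    return best_w, best_f1


def stack_features(per_model_probs: Sequence[tuple[float, float]]) -> np.ndarray:
    """Concatenate (p_neg, p_pos) per model in fixed order: 2N features."""
    if len(per_model_probs) == 0:
        raise ValueError("no model predictions")
    return np.array([p for pair in per_model_probs for p in pair], dtype=np.float64)


@dataclass
class StackingModel:
    """Intercept-free logistic regression over the 2N probability features."""

    theta: np.ndarray
    n_models: int


def fit_stacker(
    dev_features: np.ndarray, dev_labels: Sequence[int], l2: float = 1e-4
) -> StackingModel:
    """Maximum-likelihood fit with a small ridge stabilizer."""
    X = np.asarray(dev_features, dtype=np.float64)
    y = np.asarray(dev_labels, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] % 2 != 0:
        raise ValueError("features must be (n, 2N)")
    if len(set(y.tolist())) < 2:
        raise ValueError("development labels are all one class")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        z = X @ theta
        # log(1 + exp(z)) - y z, computed stably
        nll = float(np.sum(np.logaddexp(0.0, z) - y * z)) + l2 * float(theta @ theta)
        p = 1.0 / (1.0 + np.exp(-z))
        grad = X.T @ (p - y) + 2 * l2 * theta
        return nll, grad

    res = minimize(objective, np.zeros(X.shape[1]), jac=True, method="L-BFGS-B")
    return StackingModel(theta=res.x, n_models=X.shape[1] // 2)


def stacker_predict(model: StackingModel, features: np.ndarray) -> np.ndarray:
    """P(positive) = exp(theta.x) / (1 + exp(theta.x)) per row."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != 2 * model.n_models:
        raise ValueError("feature width does not match the fitted model")
    return 1.0 / (1.0 + np.exp(-(X @ model.theta)))


# ---------------------------------------------------------------------------
# corpus-level combiners producing prediction records


def _check_alignment(per_model: Sequence[Sequence[PredictionRecord]]) -> list[str]:
    ids = [r.doc_id for r in per_model[0]]
    for preds in per_model[1:]:
        if [r.doc_id for r in preds] != ids:
            raise ValueError("prediction files are not aligned on doc_id")
    return ids


def ensemble_majority(per_model: Sequence[Sequence[PredictionRecord]]) -> list[PredictionRecord]:
    ids = _check_alignment(per_model)
    T = len(per_model)
    out = []
    for i, doc_id in enumerate(ids):
        votes = [preds[i].decision for preds in per_model]
        share = sum(votes) / T
        out.append(PredictionRecord(doc_id, 1.0 - share, share, majority_vote(votes)))
    return out


def ensemble_weighted(
    per_model: Sequence[Sequence[PredictionRecord]], weights: Sequence[float]
) -> list[PredictionRecord]:
    ids = _check_alignment(per_model)
    out = []
    for i, doc_id in enumerate(ids):
        votes = [preds[i].decision for preds in per_model]
        mass = sum(w for d, w in zip(votes, weights) if d == 1)
        out.append(PredictionRecord(doc_id, 1.0 - mass, mass, weighted_vote(votes, weights)))
    return out


def stack_feature_matrix(per_model: Sequence[Sequence[PredictionRecord]]) -> np.ndarray:
    _check_alignment(per_model)
    n = len(per_model[0])
    return np.stack(
        [stack_features([(preds[i].p_neg, preds[i].p_pos) for preds in per_model]) for i in range(n)]
    )


def ensemble_stacking(
    per_model: Sequence[Sequence[PredictionRecord]], model: StackingModel
) -> list[PredictionRecord]:
    ids = _check_alignment(per_model)
    probs = stacker_predict(model, stack_feature_matrix(per_model))
    return [
        PredictionRecord(doc_id, 1.0 - p, float(p), 1 if p >= 0.5 else 0)
        for doc_id, p in zip(ids, probs)
    ]
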