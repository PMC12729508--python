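"""Prediction fusion between two models' class-probability matrices.

Four ensembling strategies:

* **weighted average** -- ``P_fusion = w * P_A + (1 - w) * P_B`` with the
  weight selected by maximising a metric over the grid {0, 0.1, ..., 1}
  on held-out selection labels (ties break to the smallest w);
* **simple average** -- the fixed midpoint w = 0.5;
* **logistic / two-layer neural network meta-learners** -- stacking on
  the concatenated probability rows of the two models.

Because the weight grid contains both endpoints, the selected weighted
average can never score below either single model on the selection split.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .evaluation import balanced_accuracy, confusion, macro_f1
from .gat_classifier import ProbabilityMatrix

__all__ = [
    "FusionConfig",
    "FusionResult",
    "weighted_average",
    "simple_average",
    "weight_grid",
    "grid_search_weight",
    "stack_meta",
    "save_probabilities",
    "load_probabilities",
]

METHODS = ("weighted_average", "simple_average", "logistic", "two_layer_nn")


def _metric_fn(name: str) -> Callable[[np.ndarray, np.ndarray], float]:
    def score(y_true: np.ndarray, probs: np.ndarray) -> float:
        counts = confusion(y_true, probs.argmax(axis=1), probs.shape[1])
        if name == "macro_f1":
            return macro_f1(counts)
        if name == "balanced_accuracy":
            return balanced_accuracy(counts)
        raise ValueError(f"unknown selection metric {name!r}")

    return score


@dataclass(frozen=True)
class FusionConfig:
    method: str = "weighted_average"
    grid_step: float = 0.1
    selection_metric: str = "macro_f1"
    seed: int = 0
    nn_hidden: int = 16

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        n = 1.0 / self.grid_step
        if self.grid_step <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("grid_step must divide 1 evenly")


@dataclass
class FusionResult:
    fused: ProbabilityMatrix
    chosen_weight: float | None
    metrics: dict[str, float]


def _check_aligned(p_a: ProbabilityMatrix, p_b: ProbabilityMatrix) -> None:
    if p_a.probs.shape != p_b.probs.shape:
        raise ValueError("probability matrices must have identical shapes")
    if p_a.sample_ids != p_b.sample_ids:
        raise ValueError("probability matrices must cover the same samples in the same order")


def weighted_average(
    p_a: ProbabilityMatrix, p_b: ProbabilityMatrix, w: float
) -> ProbabilityMatrix:
    """Row-wise convex combination ``w * P_A + (1 - w) * P_B``."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    _check_aligned(p_a, p_b)
    fused = w * p_a.probs + (1.0 - w) * p_b.probs
    return ProbabilityMatrix(probs=fused, sample_ids=list(p_a.sample_ids))


def simple_average(p_a: ProbabilityMatrix, p_b: ProbabilityMatrix) -> ProbabilityMatrix:
    return weighted_average(p_a, p_b, 0.5)


def weight_grid(step: float = 0.1) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.round(np.arange(n + 1) * step, 10)


def grid_search_weight(
    p_a: ProbabilityMatrix,
    p_b: ProbabilityMatrix,
    y_true: Sequence[int],
    config: FusionConfig = FusionConfig(),
) -> float:
    """Weight maximising the selection metric over the grid; ties break to
    the smallest w.  ``y_true`` are the held-out selection labels."""
    y = np.asarray(y_true, dtype=np.int64)
    if y.size == 0:
        raise ValueError("empty selection split")
    if y.size != p_a.probs.shape[0]:
        raise ValueError("labels do not match the probability rows")
    score = _metric_fn(config.selection_metric)
    best_w, best_val = 0.0, -np.inf
    for w in weight_grid(config.grid_step):
        val = score(y, weighted_average(p_a, p_b, float(w)).probs)
        if val > best_val + 1e-12:
            best_w, best_val = float(w), val
    return best_w


class _MetaModel:
    """Fitted stacking model over the concatenated probability rows."""

    def __init__(self, estimator, n_classes: int) -> None:
        self._est = estimator
        self._n_classes = n_classes

    def predict_proba(
        self, p_a: ProbabilityMatrix, p_b: ProbabilityMatrix
    ) -> ProbabilityMatrix:
        _check_aligned(p_a, p_b)
        x = np.concatenate([p_a.probs, p_b.probs], axis=1)
        raw = self._est.predict_proba(x)
        # classes absent from meta-training get probability 0
        probs = np.zeros((x.shape[0], self._n_classes))
        for j, c in enumerate(self._est.classes_):
            probs[:, int(c)] = raw[:, j]
        return ProbabilityMatrix(probs=probs, sample_ids=list(p_a.sample_ids))


def stack_meta(
    p_a: ProbabilityMatrix,
    p_b: ProbabilityMatrix,
    y_train: Sequence[int],
    method: str = "logistic",
    seed: int = 0,
    nn_hidden: int = 16,
) -> _MetaModel:
    """Fit a stacking meta-learner on training probabilities and labels.

    ``logistic`` is multinomial logistic regression; ``two_layer_nn`` is a
    one-hidden-layer (16-unit ReLU) network trained with Adam.
    """
    _check_aligned(p_a, p_b)
    y = np.asarray(y_train, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("meta-training labels contain a single class")
    x = np.concatenate([p_a.probs, p_b.probs], axis=1)
    if method == "logistic":
        est = LogisticRegression(max_iter=2000, random_state=seed)
    elif method == "two_layer_nn":
        est = MLPClassifier(
            hidden_layer_sizes=(nn_hidden,),
            activation="relu",
            solver="adam",
            learning_rate_init=1e-4,
            max_iter=300,
            random_state=seed,
        )
    else:
        raise ValueError("method must be 'logistic' or 'two_layer_nn'")
    est.fit(x, y)
    return _MetaModel(est, n_classes=p_a.probs.shape[1])


# ---------------------------------------------------------------------------
# prediction CSV IO: sample_id, p0 .. p{C-1}
# ---------------------------------------------------------------------------

def save_probabilities(pm: ProbabilityMatrix, path: str | os.PathLike) -> Path:
    path = Path(path)
    cols = {f"p{c}": pm.probs[:, c] for c in range(pm.n_classes)}
    pd.DataFrame({"sample_id": pm.sample_ids, **cols}).to_csv(path, index=False)
    return path


def load_probabilities(path: str | os.PathLike) -> ProbabilityMatrix:
    df = pd.read_csv(path)
    pcols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    pcols = sorted(pcols, key=lambda c: int(c[1:]))
    return ProbabilityMatrix(
        probs=df[pcols].to_numpy(dtype=np.float64),
        sample_ids=[str(s) for s in df["sample_id"]],
    )
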