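"""Classification metrics, stratified 5-fold CV, and t-distribution CIs.

Metrics are computed from explicit one-vs-rest confusion counts: per-class
precision/recall/F1, macro F1 (unweighted class mean), balanced accuracy
(mean per-class recall), plus specificity, one-vs-rest macro AUC (midrank
tie handling) and the multiclass Matthews correlation coefficient.  Fold
summaries report mean, sample standard deviation and the Student-t 95%
confidence interval ``mean +/- t_{0.975, n-1} * sd / sqrt(n)``.

Convention: any 0/0 in precision, recall or F1 is defined as 0 so macro
averages stay finite when a class is never predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "CVSummary",
    "confusion",
    "precision",
    "recall",
    "f1",
    "macro_f1",
    "balanced_accuracy",
    "specificity",
    "roc_auc",
    "mcc",
    "extra_metrics",
    "compute_metrics",
    "stratified_kfold",
    "t_confidence_interval",
    "format_mean_sd",
]


@dataclass
class ConfusionCounts:
    """Full confusion matrix plus derived one-vs-rest counts per class."""

    matrix: np.ndarray  # C x C, rows = true class, cols = predicted class
    n_classes: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (self.n_classes, self.n_classes):
            raise ValueError("confusion matrix shape mismatch")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fp - self.fn


def confusion(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains a label outside 0..{n_classes - 1}")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (y_true, y_pred), 1)
    return ConfusionCounts(matrix=m, n_classes=n_classes)


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else 0.0


def precision(counts: ConfusionCounts, i: int) -> float:
    return _safe_div(counts.tp[i], counts.tp[i] + counts.fp[i])


def recall(counts: ConfusionCounts, i: int) -> float:
    return _safe_div(counts.tp[i], counts.tp[i] + counts.fn[i])


def f1(counts: ConfusionCounts, i: int) -> float:
    p, r = precision(counts, i), recall(counts, i)
    return _safe_div(2.0 * p * r, p + r)


def macro_f1(counts: ConfusionCounts) -> float:
    return float(np.mean([f1(counts, i) for i in range(counts.n_classes)]))


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """Unweighted mean of per-class recalls; undefined when a class has no
    true members."""
    support = counts.tp + counts.fn
    if np.any(support == 0):
        raise ValueError("balanced accuracy undefined: a class has no true samples")
    return float(np.mean(counts.tp / support))


def specificity(counts: ConfusionCounts) -> float:
    """Macro-averaged TN / (TN + FP)."""
    return float(
        np.mean([_safe_div(counts.tn[i], counts.tn[i] + counts.fp[i])
                 for i in range(counts.n_classes)])
    )


def roc_auc(y_true: Sequence[int], scores: np.ndarray) -> float:
    """One-vs-rest macro AUC via the midrank Mann-Whitney statistic.

    Ties get rank averages, so constant scores give exactly 0.5.  Classes
    with no positive examples are skipped; fewer than two distinct true
    labels is an error.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(y_true).size < 2:
        raise ValueError("AUC undefined: ground truth has a single class")
    aucs = []
    for c in range(scores.shape[1]):
        pos = y_true == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = stats.rankdata(scores[:, c])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        aucs.append(u / (n_pos * n_neg))
    return float(np.mean(aucs))


def mcc(counts: ConfusionCounts) -> float:
    """Multiclass Matthews correlation coefficient from the confusion
    matrix (reduces to the familiar binary formula for C = 2); a zero
    denominator yields 0."""
    m = counts.matrix.astype(np.float64)
    s = m.sum()
    c = np.trace(m)
    t = m.sum(axis=1)  # true-class counts
    p = m.sum(axis=0)  # predicted-class counts
    num = c * s - float(t @ p)
    den = np.sqrt((s**2 - float(p @ p)) * (s**2 - float(t @ t)))
    return float(num / den) if den > 0 else 0.0


def extra_metrics(
    counts: ConfusionCounts,
    y_true: Sequence[int] | None = None,
    scores: np.ndarray | None = None,
) -> dict[str, float]:
    """Macro precision/recall, sensitivity, specificity, MCC, and (when
    probability scores are supplied) one-vs-rest macro AUC."""
    out = {
        "precision": float(np.mean([precision(counts, i) for i in range(counts.n_classes)])),
        "recall": float(np.mean([recall(counts, i) for i in range(counts.n_classes)])),
        "specificity": specificity(counts),
        "mcc": mcc(counts),
    }
    out["sensitivity"] = out["recall"]
    if scores is not None:
        if y_true is None:
            raise ValueError("AUC needs y_true alongside the scores")
        out["auc"] = roc_auc(y_true, scores)
    return out


def compute_metrics(y_true: Sequence[int], probs: np.ndarray) -> dict[str, float]:
    """Full metric report for one fold from true labels and probability
    rows (predictions are the row argmax)."""
    probs = np.asarray(probs, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64)
    n_classes = probs.shape[1]
    counts = confusion(y_true, probs.argmax(axis=1), n_classes)
    out = {"macro_f1": macro_f1(counts), "balanced_accuracy": balanced_accuracy(counts)}
    out.update(extra_metrics(counts, y_true=y_true, scores=probs))
    return out


def stratified_kfold(
    labels: Sequence[int], k: int = 5, seed: int = 0, stratified: bool = True
) -> np.ndarray:
    """Deterministic fold assignment, one fold id in ``0..k-1`` per sample.

    Stratified mode shuffles each class with the seeded generator and
    deals its members round-robin across folds through a single global
    rotation, so fold sizes differ by at most one overall and per-class
    proportions are preserved up to rounding -- even for classes smaller
    than ``k`` (best effort).  Unstratified mode deals the shuffled
    samples directly.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n = labels.size
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.int64)
    if not stratified:
        perm = rng.permutation(n)
        for pos, i in enumerate(perm):
            folds[i] = pos % k
        return folds
    counter = 0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        members = members[rng.permutation(members.size)]
        for i in members:
            folds[i] = counter % k
            counter += 1
    return folds


def t_confidence_interval(
    values: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Two-sided Student-t interval for the mean of ``values`` (sample sd,
    n - 1 degrees of freedom)."""
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    if n < 2:
        raise ValueError("confidence interval needs at least two values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    t = float(stats.t.ppf((1.0 + level) / 2.0, df=n - 1))
    half = t * sd / np.sqrt(n)
    return (mean - half, mean + half)


@dataclass
class CVSummary:
    """Per-fold metric values with mean, sample sd, and t-interval."""

    per_fold_values: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    level: float = 0.95

    def __post_init__(self) -> None:
        v = np.asarray(self.per_fold_values, dtype=np.float64)
        self.mean = float(v.mean())
        self.sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        if v.size > 1:
            self.ci_low, self.ci_high = t_confidence_interval(v, self.level)
        else:
            self.ci_low = self.ci_high = self.mean

    def as_dict(self) -> dict[str, object]:
        return {
            "per_fold_values": [float(x) for x in self.per_fold_values],
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
        }


def format_mean_sd(summary: CVSummary, decimals: int = 2, percent: bool = True) -> str:
    """Render a summary the way results tables print it: ``95.77 (±0.61)``."""
    scale = 100.0 if percent else 1.0
    return f"{summary.mean * scale:.{decimals}f} (±{summary.sd * scale:.{decimals}f})"
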