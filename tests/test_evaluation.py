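"""Metric formulas against independent oracles; folds and t-intervals."""

import numpy as np
import pytest
from sklearn import metrics as skm

from histogat.evaluation import (
    ConfusionCounts,
    CVSummary,
    balanced_accuracy,
    compute_metrics,
    confusion,
    extra_metrics,
    f1,
    format_mean_sd,
    macro_f1,
    mcc,
    precision,
    recall,
    roc_auc,
    specificity,
    stratified_kfold,
    t_confidence_interval,
)


class TestConfusion:
    def test_constructed_binary_counts(self):
        # 10 samples engineered to give TP=3, FP=1, FN=2, TN=4 for class 1
        y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        c = confusion(y_true, y_pred, 2)
        assert (c.tp[1], c.fp[1], c.fn[1], c.tn[1]) == (3, 1, 2, 4)
        # one-vs-rest counts always partition the sample total
        for i in range(2):
            assert c.tp[i] + c.fp[i] + c.fn[i] + c.tn[i] == 10

    def test_perfect_predictions(self):
        c = confusion([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert np.all(c.fp == 0) and np.all(c.fn == 0)
        assert macro_f1(c) == 1.0 and balanced_accuracy(c) == 1.0

    def test_all_one_class_predictions(self):
        c = confusion([0, 0, 1, 1, 1], [0, 0, 0, 0, 0], 2)
        assert c.fn[1] == 3  # the other class's support is all missed
        assert f1(c, 1) == 0.0  # 0/0 convention

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 3], [0, 1], 2)
        with pytest.raises(ValueError):
            confusion([0, 1], [0, 1, 1], 2)


class TestF1:
    def test_direct_substitution(self):
        # precision 0.75, recall 0.6 -> F1 = 2 * 0.45 / 1.35 = 2/3
        y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        c = confusion(y_true, y_pred, 2)
        assert precision(c, 1) == pytest.approx(0.75)
        assert recall(c, 1) == pytest.approx(0.6)
        assert f1(c, 1) == pytest.approx(2 / 3)

    def test_macro_is_unweighted_mean_of_per_class_f1(self, rng):
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        c = confusion(y_true, y_pred, 3)
        assert macro_f1(c) == pytest.approx(np.mean([f1(c, i) for i in range(3)]))


def test_balanced_accuracy_binary_recalls():
    # recalls 1.0 and 0.5 -> balanced accuracy 0.75
    y_true = [0, 0, 1, 1, 1, 1]
    y_pred = [0, 0, 1, 1, 0, 0]
    assert balanced_accuracy(confusion(y_true, y_pred, 2)) == pytest.approx(0.75)


def test_balanced_accuracy_requires_all_classes():
    with pytest.raises(ValueError):
        balanced_accuracy(confusion([0, 0], [0, 1], 2))


def test_metrics_match_sklearn_on_random_vectors(rng):
    """Macro F1, balanced accuracy and MCC agree with scikit-learn on many
    random label vectors (2-4 classes)."""
    for _ in range(300):
        n_classes = int(rng.integers(2, 5))
        n = int(rng.integers(10, 40))
        y_true = rng.integers(0, n_classes, n)
        y_pred = rng.integers(0, n_classes, n)
        if np.unique(y_true).size < n_classes:
            continue
        c = confusion(y_true, y_pred, n_classes)
        assert macro_f1(c) == pytest.approx(
            skm.f1_score(y_true, y_pred, average="macro", zero_division=0)
        )
        assert balanced_accuracy(c) == pytest.approx(
            skm.balanced_accuracy_score(y_true, y_pred)
        )
        assert mcc(c) == pytest.approx(skm.matthews_corrcoef(y_true, y_pred), abs=1e-12)
        # balanced accuracy is macro-averaged recall by construction
        assert balanced_accuracy(c) == pytest.approx(
            np.mean([recall(c, i) for i in range(n_classes)])
        )


class TestExtraMetrics:
    def test_perfect_scores(self):
        y = np.array([0, 1, 0, 1])
        probs = np.eye(2)[y]
        out = extra_metrics(confusion(y, y, 2), y_true=y, scores=probs)
        assert out["auc"] == 1.0 and out["mcc"] == 1.0
        assert out["precision"] == 1.0 and out["specificity"] == 1.0
        assert out["sensitivity"] == out["recall"]

    def test_constant_scores_give_half_auc(self):
        y = np.array([0, 1, 0, 1, 1])
        probs = np.full((5, 2), 0.5)
        assert roc_auc(y, probs) == pytest.approx(0.5)

    def test_auc_matches_sklearn(self, rng):
        for n_classes in (2, 3):
            y = rng.integers(0, n_classes, 50)
            while np.unique(y).size < n_classes:
                y = rng.integers(0, n_classes, 50)
            raw = rng.random((50, n_classes))
            probs = raw / raw.sum(axis=1, keepdims=True)
            if n_classes == 2:
                expected = skm.roc_auc_score(y, probs[:, 1])
            else:
                expected = skm.roc_auc_score(y, probs, multi_class="ovr", average="macro")
            assert roc_auc(y, probs) == pytest.approx(expected)

    def test_binary_mcc_closed_form(self):
        y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        c = confusion(y_true, y_pred, 2)
        tp, fp, fn, tn = 3, 1, 2, 4
        expected = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert mcc(c) == pytest.approx(expected)

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], np.full((3, 2), 0.5))

    def test_specificity_macro(self):
        c = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        # class 0: TN=2, FP=0 -> 1.0 ; class 1: TN=1, FP=1 -> 0.5
        assert specificity(c) == pytest.approx(0.75)


class TestStratifiedKFold:
    def test_balanced_binary_hundred_samples(self):
        labels = np.array([0, 1] * 50)
        folds = stratified_kfold(labels, k=5, seed=0)
        for f in range(5):
            members = labels[folds == f]
            assert members.size == 20
            assert (members == 0).sum() == 10 and (members == 1).sum() == 10

    def test_seven_samples_five_folds_sizes(self):
        folds = stratified_kfold(np.zeros(7, dtype=int), k=5, seed=1)
        sizes = sorted(np.bincount(folds, minlength=5), reverse=True)
        assert sizes == [2, 2, 1, 1, 1]

    def test_deterministic_and_permutation_structure(self, rng):
        labels = rng.integers(0, 3, 45)
        f1_ = stratified_kfold(labels, k=5, seed=7)
        f2_ = stratified_kfold(labels, k=5, seed=7)
        np.testing.assert_array_equal(f1_, f2_)
        # permuting the samples (same seed) preserves the per-class fold
        # composition up to relabeling of sample positions
        perm = rng.permutation(labels.size)
        f3_ = stratified_kfold(labels[perm], k=5, seed=7)
        for f in range(5):
            a = np.bincount(labels[f1_ == f], minlength=3)
            b = np.bincount(labels[perm][f3_ == f], minlength=3)
            np.testing.assert_array_equal(a, b)

    def test_config_errors(self):
        with pytest.raises(ValueError):
            stratified_kfold([0, 1], k=1)
        with pytest.raises(ValueError):
            stratified_kfold([0, 1], k=3)

    def test_unstratified_mode(self):
        folds = stratified_kfold(np.arange(10) % 2, k=5, seed=0, stratified=False)
        assert sorted(np.bincount(folds, minlength=5).tolist()) == [2] * 5


class TestTInterval:
    def _values(self, mean, sd):
        base = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        base = (base - base.mean()) / base.std(ddof=1)
        return mean + sd * base

    def test_published_style_interval(self):
        lo, hi = t_confidence_interval(self._values(95.77, 0.61))
        assert round(lo, 2) == 95.01 and round(hi, 2) == 96.53
        lo, hi = t_confidence_interval(self._values(91.24, 1.03))
        assert round(lo, 2) == 89.96 and round(hi, 2) == 92.52

    def test_equal_values_zero_width(self):
        lo, hi = t_confidence_interval([3.0, 3.0, 3.0])
        assert lo == hi == 3.0

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            t_confidence_interval([1.0])


def test_cv_summary_interval_symmetric_about_mean():
    s = CVSummary([0.9, 0.92, 0.91, 0.95, 0.89])
    assert s.ci_low <= s.mean <= s.ci_high
    assert (s.mean - s.ci_low) == pytest.approx(s.ci_high - s.mean)
    assert format_mean_sd(s) == f"{s.mean*100:.2f} (±{s.sd*100:.2f})"


def test_compute_metrics_report_keys(rng):
    y = rng.integers(0, 2, 30)
    while np.unique(y).size < 2:
        y = rng.integers(0, 2, 30)
    raw = rng.random((30, 2))
    probs = raw / raw.sum(axis=1, keepdims=True)
    out = compute_metrics(y, probs)
    assert set(out) >= {"macro_f1", "balanced_accuracy", "precision", "recall",
                        "sensitivity", "specificity", "auc", "mcc"}
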