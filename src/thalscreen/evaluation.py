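"""Evaluation harness: splits, confusion-matrix metrics, ROC/PR, paired t-test.

Metric layout mirrors standard clinical-ML reporting: per-class precision,
recall (sensitivity), F1, specificity, FPR, FNR and support, plus overall
accuracy and macro/weighted averages, with AUC attached when a continuous
score is available.  Repeated random splits aligned by seed feed a paired
t-test for model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import (
    auc,
    confusion_matrix,
    precision_recall_curve,
    roc_curve,
)
from sklearn.model_selection import train_test_split

__all__ = [
    "MetricsReport",
    "PairedTestResult",
    "split",
    "confusion_and_metrics",
    "roc_pr",
    "paired_t_test",
    "repeated_runs",
    "MentzerBaseline",
]


@dataclass
class MetricsReport:
    """Two-class confusion-matrix metrics in a Table-style layout."""

    per_class: dict
    accuracy: float
    macro: dict
    weighted: dict
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): dict(v) for k, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro_avg": dict(self.macro),
            "weighted_avg": dict(self.weighted),
            "auc": self.auc,
        }


@dataclass
class PairedTestResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


def split(
    table: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
):
    """Random train/test partition of a table (80/20 by default).

    Deterministic per seed; disjoint and exhaustive.  Stratification on
    the ``decision`` column is off by default.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to split")
    strat = table["decision"] if stratify and "decision" in table.columns else None
    train, test = train_test_split(
        table, train_size=train_fraction, random_state=seed, stratify=strat
    )
    return train, test


def confusion_and_metrics(truth, predictions) -> MetricsReport:
    """Standard two-class metrics computed from the confusion matrix alone."""
    y_true = np.asarray(truth)
    y_pred = np.asarray(predictions)
    if y_true.shape != y_pred.shape:
        raise ValueError("truth and predictions must have equal length")
    bad = set(np.unique(np.concatenate([y_true, y_pred])).tolist()) - {0, 1}
    if bad:
        raise ValueError(f"labels outside {{0, 1}}: {sorted(bad)}")
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])

    per_class = {}
    for cls in (0, 1):
        other = 1 - cls
        tp = cm[cls, cls]
        fn = cm[cls, other]
        fp = cm[other, cls]
        tn = cm[other, other]
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        specificity = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[cls] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "specificity": specificity,
            "fpr": 1.0 - specificity,
            "fnr": 1.0 - recall,
            "support": int(tp + fn),
        }
    n = cm.sum()
    accuracy = float(np.trace(cm)) / n if n else 0.0
    keys = ("precision", "recall", "f1", "specificity", "fpr", "fnr")
    macro = {k: float(np.mean([per_class[c][k] for c in (0, 1)])) for k in keys}
    supports = np.array([per_class[c]["support"] for c in (0, 1)], dtype=float)
    if supports.sum():
        weights = supports / supports.sum()
    else:
        weights = np.array([0.5, 0.5])
    weighted = {
        k: float(np.dot(weights, [per_class[c][k] for c in (0, 1)])) for k in keys
    }
    return MetricsReport(per_class=per_class, accuracy=accuracy, macro=macro, weighted=weighted)


def roc_pr(truth, scores) -> dict:
    """ROC and precision-recall curves with their areas.

    ROC AUC is the trapezoidal area over the unique score thresholds; the
    PR curve reports precision at each recall step.
    """
    y_true = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC/PR require both classes present in truth")
    fpr, tpr, roc_thresholds = roc_curve(y_true, s)
    precision, recall, pr_thresholds = precision_recall_curve(y_true, s)
    return {
        "roc": {"fpr": fpr, "tpr": tpr, "thresholds": roc_thresholds},
        "roc_auc": float(auc(fpr, tpr)),
        "pr": {"precision": precision, "recall": recall, "thresholds": pr_thresholds},
        "pr_auc": float(auc(recall, precision)),
    }


def paired_t_test(accuracies_a, accuracies_b) -> PairedTestResult:
    """Classical paired t-test on per-run accuracy differences.

    Two-sided p-value with n-1 degrees of freedom.  Zero variance of the
    differences is reported as degenerate rather than raised: t = 0, p = 1
    when the models tie exactly, otherwise an infinite t with p = 0.
    """
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d and equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired runs")
    d = a - b
    common = dict(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        n_pairs=len(a),
    )
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTestResult(t_statistic=0.0, p_value=1.0, degenerate=True, **common)
        t = float(np.sign(d.mean()) * np.inf)
        return PairedTestResult(t_statistic=t, p_value=0.0, degenerate=True, **common)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        t_statistic=float(res.statistic), p_value=float(res.pvalue), **common
    )


def repeated_runs(
    models: Mapping[str, BaseEstimator],
    table: pd.DataFrame,
    k: int = 10,
    seeds: Optional[Sequence[int]] = None,
    train_fraction: float = 0.8,
    feature_cols: Optional[Sequence[str]] = None,
) -> dict[str, np.ndarray]:
    """Per-model test-accuracy vectors over k seed-aligned random splits.

    Each model is cloned and refit per split, so vectors pair by seed for
    the t-test.  A model failure on a run is recorded as NaN with a
    warning and should be excluded pairwise downstream.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if seeds is None:
        seeds = list(range(k))
    seeds = list(seeds)[:k]
    cols = list(feature_cols) if feature_cols is not None else [
        c for c in table.columns if c != "decision"
    ]
    out = {name: np.full(k, np.nan) for name in models}
    for i, seed in enumerate(seeds):
        train, test = split(table, train_fraction=train_fraction, seed=seed)
        for name, model in models.items():
            try:
                est = clone(model)
                est.fit(train[cols], train["decision"].to_numpy())
                pred = est.predict(test[cols])
                out[name][i] = float(
                    (np.asarray(pred) == test["decision"].to_numpy()).mean()
                )
            except Exception as exc:  # noqa: BLE001 - harness must survive a model
                warnings.warn(f"model {name!r} failed on seed {seed}: {exc}")
    return out


class MentzerBaseline(ClassifierMixin, BaseEstimator):
    """Non-core comparator: flag carrier when Mentzer MCV/RBC <= threshold.

    A fixed-threshold screening rule, not a learned model; ``fit`` only
    records metadata.  Expects ``mcv`` and ``rbc`` columns (or a
    precomputed ``mi`` column).
    """

    def __init__(self, threshold: float = 13.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _mentzer(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if "mi" in X.columns:
                return X["mi"].to_numpy(dtype=float)
            return X["mcv"].to_numpy(dtype=float) / X["rbc"].to_numpy(dtype=float)
        raise ValueError("MentzerBaseline needs a DataFrame with mi or mcv/rbc columns")

    def predict(self, X) -> np.ndarray:
        return (self._mentzer(X) <= self.threshold).astype(int)

    def decision_function(self, X) -> np.ndarray:
        return -self._mentzer(X)  # lower Mentzer, more carrier-like
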