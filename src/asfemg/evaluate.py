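"""Accuracy, F1, confusion-count reductions, paired t-tests, summaries.

Headline accuracy is the micro average trace/total of the multiclass
confusion matrix (equivalently the micro average of the one-vs-rest
(TP+TN)/(TP+TN+FP+FN) reduction); model-level F1 is the macro mean of
per-class F1 = 2TP / (2TP + FP + FN). Classifier comparisons use
two-sided paired t-tests over per-gesture-combination mean scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest reduction of a multiclass confusion matrix."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "ConfusionCounts":
        m = np.asarray(matrix, dtype=float)
        total = m.sum()
        tp = np.diag(m)
        fp = m.sum(axis=0) - tp
        fn = m.sum(axis=1) - tp
        tn = total - tp - fp - fn
        return cls(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(matrix: np.ndarray) -> float:
    """Micro-averaged accuracy: trace / total."""
    m = np.asarray(matrix, float)
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(m) / total)


def per_class_accuracy(matrix: np.ndarray) -> np.ndarray:
    """One-vs-rest (TP+TN)/(TP+TN+FP+FN) per class."""
    c = ConfusionCounts.from_matrix(matrix)
    return (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn)


def per_class_f1(matrix: np.ndarray) -> np.ndarray:
    """Per-class F1 = 2TP/(2TP+FP+FN); NaN where the class never occurs."""
    c = ConfusionCounts.from_matrix(matrix)
    denom = 2 * c.tp + c.fp + c.fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * c.tp / denom, np.nan)
    return f1


def macro_f1(matrix: np.ndarray) -> float:
    """Macro mean of per-class F1, skipping undefined classes."""
    f1 = per_class_f1(matrix)
    defined = f1[~np.isnan(f1)]
    if defined.size == 0:
        raise ValueError("F1 undefined for every class")
    if defined.size < f1.size:
        log.info("%d class(es) without occurrences skipped in macro F1", f1.size - defined.size)
    return float(defined.mean())


def paired_ttests(results_a, results_b, alpha: float = 0.05):
    """Two-sided paired t-test over matched per-combination scores.

    Returns (t, p, significant). A zero-difference series is reported as
    non-significant with p = 1.
    """
    a = np.asarray(results_a, float)
    b = np.asarray(results_b, float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    if np.allclose(diff, 0):
        return 0.0, 1.0, False
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), bool(p < alpha)


def summarize(records: list[dict]) -> pd.DataFrame:
    """Mean Acc / macro-F1 grid per (classifier, side, GL, pca) cell.

    ``records`` carry one entry per evaluated (model, partition) with keys
    classifier, side, gl, pca, acc, f1. Output is invariant to record
    order.
    """
    df = pd.DataFrame(records)
    required = {"classifier", "side", "gl", "pca", "acc", "f1"}
    if not required.issubset(df.columns):
        raise ValueError(f"records missing keys {sorted(required - set(df.columns))}")
    grid = (
        df.groupby(["classifier", "side", "gl", "pca"], sort=True)[["acc", "f1"]]
        .mean()
        .reset_index()
        .rename(columns={"acc": "mean_acc", "f1": "mean_f1"})
    )
    return grid
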