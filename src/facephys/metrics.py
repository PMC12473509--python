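"""Evaluation metrics for the classification and regression tasks.

Ratios with zero denominators (e.g. sensitivity with no positive samples)
are reported as ``None`` rather than NaN so downstream aggregation can skip
them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClassificationMetrics", "RegressionMetrics",
           "classification_metrics", "regression_metrics"]


@dataclass
class ClassificationMetrics:
    accuracy: float
    f1: float | None
    sensitivity: float | None
    specificity: float | None
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class RegressionMetrics:
    mae: float
    rmse: float
    pearson_r: float | None  # None for constant series


def classification_metrics(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ClassificationMetrics:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape or probs.size == 0:
        raise ValueError("probs and labels must be equal-length and non-empty")
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    n = tp + fp + fn + tn
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    prec = tp / (tp + fp) if tp + fp else None
    if prec is None or sens is None or prec + sens == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return ClassificationMetrics(acc, f1, sens, spec, tp, fp, fn, tn)


def regression_metrics(preds: np.ndarray, targets: np.ndarray) -> RegressionMetrics:
    preds = np.asarray(preds, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if preds.shape != targets.shape or preds.size == 0:
        raise ValueError("preds and targets must be equal-length and non-empty")
    e = preds - targets
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e * e)))
    if preds.size < 2 or np.std(preds) == 0 or np.std(targets) == 0:
        r = None
    else:
        r = float(np.corrcoef(preds, targets)[0, 1])
    return RegressionMetrics(mae, rmse, r)
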