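"""Classification metrics and cross-validation fold aggregation."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

METRIC_NAMES = ("accuracy", "f1", "auc")


@dataclass
class FoldEntry:
    """Metrics of one evaluation: accuracy in %, F1 and AUC unitless."""

    accuracy: float
    f1: float
    auc: float | None  # None when the test set contains a single class

    def as_tuple(self):
        return (self.accuracy, self.f1, self.auc)


def compute_metrics(y_true: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> FoldEntry:
    """accuracy (x100), malignant-class F1 (0 on zero division), and
    tie-corrected trapezoidal ROC AUC (undefined for single-class truth)."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have the same shape")
    pred = (scores >= threshold).astype(int)
    acc = 100.0 * float(np.mean(pred == y_true))
    f1 = float(f1_score(y_true, pred, zero_division=0))
    auc = None
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    return FoldEntry(acc, f1, auc)


@dataclass
class FoldMetrics:
    """Per-fold metrics with mean and sample standard deviation."""

    per_fold: list[FoldEntry]

    def __post_init__(self):
        if not self.per_fold:
            raise ValueError("at least one fold is required")

    def _values(self, name: str) -> list[float]:
        vals = [getattr(e, name) for e in self.per_fold]
        if any(v is None for v in vals):
            raise ValueError(f"metric {name!r} undefined for some fold")
        return vals

    def mean(self, name: str) -> float:
        return float(np.mean(self._values(name)))

    def sd(self, name: str) -> float | None:
        """Sample standard deviation (n - 1); None for a single fold."""
        vals = self._values(name)
        if len(vals) < 2:
            return None
        return float(np.std(vals, ddof=1))

    def summary(self) -> dict:
        out = {}
        for name in METRIC_NAMES:
            out[name] = {"mean": self.mean(name), "sd": self.sd(name),
                         "per_fold": self._values(name)}
        return out


def aggregate_folds(entries: list[FoldEntry]) -> FoldMetrics:
    return FoldMetrics(list(entries))
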