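"""Two-class malignancy calls from FD values, radiologist-annotation
consensus, and the evaluation metrics.

Radiologists grade nodules on a 5-point malignancy scale (1 highly unlikely
… 5 highly suspicious); grades 1–3 form the low-malignancy (probably
benign) class and 4–5 the high class.  An FD estimate is called *high*
(suspicious) when it strictly exceeds the method's cut-off — 1.214 for box
counting, 1.137 for the power spectrum, the upper end of the grade-3 FD
range.  Performance is summarised by sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and accuracy (TP+TN)/total, plus the Pearson correlation between
FD and consensus grade.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import floor

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import (InvalidParameterError, UndefinedCorrelationError,
                         UndefinedMetricError)

__all__ = [
    "Thresholds",
    "ConfusionCounts",
    "PerformanceReport",
    "NoduleRecord",
    "consensus_grade",
    "true_class",
    "classify_fd",
    "confusion",
    "metrics",
    "pearson_correlation",
    "format_percent",
    "FDThresholdClassifier",
]

LOW, HIGH = "low", "high"


@dataclass(frozen=True)
class Thresholds:
    """FD cut-offs above which a nodule is called suspicious."""

    box_cutoff: float = 1.214
    spectrum_cutoff: float = 1.137

    def __post_init__(self):
        for name, v in (("box_cutoff", self.box_cutoff),
                        ("spectrum_cutoff", self.spectrum_cutoff)):
            if not 1.0 < v < 2.0:
                raise InvalidParameterError(f"{name} must lie strictly in (1, 2)")

    def for_method(self, method: str) -> float:
        if method in ("box", "box_counting"):
            return self.box_cutoff
        if method in ("spectrum", "power_spectrum"):
            return self.spectrum_cutoff
        raise InvalidParameterError(f"unknown method tag {method!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0 or int(v) != v:
                raise InvalidParameterError("confusion counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceReport:
    """Metrics stored as fractions in [0, 1]; use :func:`format_percent`
    for the one-decimal percentage rendering used in printed tables."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    pearson_r: float | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "pearson_r": self.pearson_r,
            "sensitivity_pct": format_percent(self.sensitivity),
            "specificity_pct": format_percent(self.specificity),
            "accuracy_pct": format_percent(self.accuracy),
        }


@dataclass(frozen=True)
class NoduleRecord:
    nodule_id: str
    annotations: tuple[int, ...]
    consensus: int
    fd_box: float | None = None
    fd_spectrum: float | None = None


def format_percent(fraction: float) -> float:
    """Render a fraction as a percentage truncated to one decimal place
    (0.9375 -> 93.7), matching the reporting convention of the printed
    performance tables."""
    return floor(fraction * 1000.0 + 1e-9) / 10.0


def consensus_grade(annotations, tie_break: str = "high") -> int:
    """Most repeated malignancy grade among 1–4 radiologist annotations.

    Ties break toward the higher grade by default (clinically conservative
    toward malignancy); ``tie_break`` may be 'high', 'low' or 'mean-round'.
    """
    ann = list(annotations)
    if not 1 <= len(ann) <= 4:
        raise InvalidParameterError("expected 1 to 4 annotations")
    for a in ann:
        if int(a) != a or not 1 <= a <= 5:
            raise InvalidParameterError(f"annotation {a!r} outside the 1-5 scale")
    counts = Counter(int(a) for a in ann)
    top = max(counts.values())
    modes = sorted(g for g, c in counts.items() if c == top)
    if tie_break == "high":
        return modes[-1]
    if tie_break == "low":
        return modes[0]
    if tie_break == "mean-round":
        return int(round(float(np.mean(modes))))
    raise InvalidParameterError(f"unknown tie_break {tie_break!r}")


def true_class(grade: int) -> str:
    """Grades 1–3 -> 'low' (probably benign); 4–5 -> 'high'."""
    if int(grade) != grade or not 1 <= grade <= 5:
        raise InvalidParameterError(f"grade {grade!r} outside the 1-5 scale")
    return HIGH if grade >= 4 else LOW


def classify_fd(fd: float, method: str, thresholds: Thresholds | None = None) -> str:
    """'high' iff fd strictly exceeds the method's cut-off."""
    if not np.isfinite(fd):
        raise InvalidParameterError("fd must be finite")
    thresholds = thresholds or Thresholds()
    return HIGH if fd > thresholds.for_method(method) else LOW


def confusion(predicted, truth) -> ConfusionCounts:
    """Tally a 2x2 confusion table; 'high' is the positive class."""
    pred = list(predicted)
    true = list(truth)
    if len(pred) != len(true) or len(pred) == 0:
        raise InvalidParameterError("predicted and truth must align and be non-empty")
    for lab in (*pred, *true):
        if lab not in (LOW, HIGH):
            raise InvalidParameterError(f"unknown class label {lab!r}")
    tp = sum(1 for p, t in zip(pred, true) if p == HIGH and t == HIGH)
    tn = sum(1 for p, t in zip(pred, true) if p == LOW and t == LOW)
    fp = sum(1 for p, t in zip(pred, true) if p == HIGH and t == LOW)
    fn = sum(1 for p, t in zip(pred, true) if p == LOW and t == HIGH)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts, pearson_r: float | None = None) -> PerformanceReport:
    """Sensitivity, specificity and accuracy from confusion counts."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity")
    if c.total == 0:
        raise UndefinedMetricError("accuracy")
    return PerformanceReport(
        counts=c,
        sensitivity=c.tp / (c.tp + c.fn),
        specificity=c.tn / (c.tn + c.fp),
        accuracy=(c.tp + c.tn) / c.total,
        pearson_r=pearson_r,
    )


def pearson_correlation(fd_values, grades) -> float:
    """Sample Pearson product-moment correlation between FD and grade."""
    x = np.asarray(fd_values, dtype=float)
    y = np.asarray(grades, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidParameterError("need two aligned samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("one of the samples has zero variance")
    return float(stats.pearsonr(x, y).statistic)


class FDThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Fixed-cut-off malignancy classifier over FD features.

    ``X`` is an (n, 1) array (or list) of FD values; ``predict`` returns
    'low'/'high' labels using the cut-off of the configured ``method``.
    ``fit`` validates parameters and records ``classes_``; no parameter is
    learned from data — the cut-offs are clinical constants.
    """

    def __init__(self, method: str = "box_counting",
                 box_cutoff: float = 1.214, spectrum_cutoff: float = 1.137):
        self.method = method
        self.box_cutoff = box_cutoff
        self.spectrum_cutoff = spectrum_cutoff

    def _thresholds(self) -> Thresholds:
        return Thresholds(box_cutoff=self.box_cutoff,
                          spectrum_cutoff=self.spectrum_cutoff)

    def fit(self, X, y=None):
        self._thresholds().for_method(self.method)  # validates
        self.classes_ = np.array([HIGH, LOW])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "classes_"):
            self.fit(X)
        thr = self._thresholds()
        fds = np.asarray(X, dtype=float).reshape(-1)
        return np.array([classify_fd(fd, self.method, thr) for fd in fds])

    def score(self, X, y):
        """Accuracy against 'low'/'high' truth labels."""
        pred = self.predict(X)
        c = confusion(pred, list(y))
        return (c.tp + c.tn) / c.total
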