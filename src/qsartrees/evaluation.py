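"""Confusion-matrix metrics and ROC analysis for the RB/NRB problem.

RB (ready biodegradable) is the positive class throughout. The seven
reported measures are sensitivity, specificity, accuracy, precision,
F1-score, false positive rate and false negative rate; sensitivity/FNR and
specificity/FPR are complements, and F1 is the harmonic mean of precision
and sensitivity. Report-time rounding is half-up to 2 decimals, matching
the presentation convention of the study's tables; internal values keep
full precision.

The ROC curve sweeps thresholds over the descending distinct RB scores,
grouping tied scores into single points, and the AUROC is the trapezoidal
area — which under that tie convention equals the Mann-Whitney concordance
probability (ties counting one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .datatable import NRB, RB

#: table column order used by all reports
METRIC_COLUMNS = (
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "f1",
    "fpr",
    "fnr",
)


class EvaluationError(ValueError):
    pass


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (report parity with printed tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with RB as the positive class."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise EvaluationError("predictions and truth must have equal length")
    for arr, name in ((predictions, "predictions"), (truth, "truth")):
        bad = set(arr.tolist()) - {RB, NRB}
        if bad:
            raise EvaluationError(f"{name} contain non-RB/NRB labels: {sorted(bad)}")
    pos = truth == RB
    pred_pos = predictions == RB
    return ConfusionMatrix(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    fpr: float
    fnr: float

    def as_row(self, rounded: bool = True) -> dict[str, float]:
        vals = {k: getattr(self, k) for k in METRIC_COLUMNS}
        if rounded:
            vals = {k: round2(v) for k, v in vals.items()}
        return vals


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The seven confusion-matrix measures at full precision."""
    if cm.n == 0:
        raise EvaluationError("empty confusion matrix")
    n_pos = cm.tp + cm.fn
    n_neg = cm.tn + cm.fp
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both truth classes must be present")
    sens = cm.tp / n_pos
    spec = cm.tn / n_neg
    acc = (cm.tp + cm.tn) / cm.n
    if cm.tp + cm.fp == 0:
        warnings.warn("no positive predictions; precision reported as 0", stacklevel=2)
        prec = 0.0
    else:
        prec = cm.tp / (cm.tp + cm.fp)
    f1 = 0.0 if prec + sens == 0 else 2 * prec * sens / (prec + sens)
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        precision=prec,
        f1=f1,
        fpr=1.0 - spec,
        fnr=1.0 - sens,
    )


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> MetricsReport:
    return metrics(confusion(predictions, truth))


def accuracy_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> float:
    """Reconstruct overall accuracy from class-wise rates and class sizes.

    accuracy = (sens * n_pos + spec * n_neg) / (n_pos + n_neg); used to check
    the internal consistency of printed results tables given the test-split
    class sizes (263 RB / 625 NRB in the study).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise EvaluationError("class sizes must be positive")
    return (sensitivity * n_pos + specificity * n_neg) / (n_pos + n_neg)


def f1_from_rates(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    if precision + sensitivity == 0:
        return 0.0
    return 2 * precision * sensitivity / (precision + sensitivity)


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (fpr, tpr) points from (0,0) to (1,1) and the trapezoid area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


def roc_curve(scores: np.ndarray, truth: np.ndarray) -> ROCCurve:
    """ROC over descending distinct scores; tied scores share one point."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise EvaluationError("scores and truth must have equal length")
    if not np.isfinite(scores).all():
        raise EvaluationError("scores must be finite")
    pos = truth == RB
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC requires both classes in the truth")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = pos[order]
    # last index of each tied block of scores
    boundary = np.nonzero(np.diff(s) < 0)[0]
    idx = np.concatenate([boundary, [len(s) - 1]])
    tp = np.cumsum(y)[idx]
    fp = np.cumsum(~y)[idx]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thr = np.concatenate([[np.inf], s[idx]])
    if tpr[-1] != 1.0 or fpr[-1] != 1.0:  # pragma: no cover - always reached
        tpr = np.append(tpr, 1.0)
        fpr = np.append(fpr, 1.0)
        thr = np.append(thr, -np.inf)
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auroc=auroc)


def metrics_table(rows: dict[str, MetricsReport], rounded: bool = True) -> pd.DataFrame:
    """Stack named MetricsReports into a model-by-measure table."""
    return pd.DataFrame(
        {name: rep.as_row(rounded=rounded) for name, rep in rows.items()}
    ).T[list(METRIC_COLUMNS)]
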