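"""Binary classification metrics.

Seven metrics summarize a model on one dataset: sensitivity, specificity,
precision, accuracy, Matthews correlation coefficient, F1 and ROC AUC.
The positive class is cytoplasm throughout.  Undefined 0/0 ratios are
reported as 0, which matches how a degenerate all-negative predictor is
conventionally tabulated (sens 0, spec 1, prec 0, mcc 0, f1 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import UndefinedMetricError


@dataclass(frozen=True)
class MetricSet:
    sens: float
    spec: float
    prec: float
    acc: float
    mcc: float
    f1: float
    auc: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("sens", "spec", "prec", "acc", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.mcc <= 1.0:
            raise ValueError(f"mcc={self.mcc} outside [-1, 1]")
        if self.auc is not None and not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"auc={self.auc} outside [0, 1]")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def confusion_metrics(tp: int, fp: int, tn: int, fn: int, auc: Optional[float] = None) -> MetricSet:
    """Metrics from confusion-matrix counts.

    sens = TP/(TP+FN), spec = TN/(TN+FP), prec = TP/(TP+FP),
    acc = (TP+TN)/total, f1 = TP/(TP + 0.5(FN+FP)) and MCC with the
    standard four-factor radical; any 0/0 is reported as 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name}={v} must be non-negative")
    total = tp + fp + tn + fn
    if total < 1:
        raise ValueError("at least one prediction required")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0
    return MetricSet(
        sens=_ratio(tp, tp + fn),
        spec=_ratio(tn, tn + fp),
        prec=_ratio(tp, tp + fp),
        acc=(tp + tn) / total,
        mcc=mcc,
        f1=_ratio(tp, tp + 0.5 * (fn + fp)),
        auc=auc,
    )


def auc_score(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; tied scores contribute 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(labels) != len(scores):
        raise ValueError("labels and scores must have equal length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise UndefinedMetricError("AUC undefined with a single class present")
    return float(roc_auc_score(labels, scores))


def score_predictions(
    y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricSet:
    """Full MetricSet from true labels and positive-class scores."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return confusion_metrics(tp, fp, tn, fn, auc=auc_score(y_true, scores))


def mean_metrics(sets: Sequence[MetricSet]) -> MetricSet:
    """Per-metric arithmetic mean (AUC averaged when present everywhere)."""
    if not sets:
        raise ValueError("no metric sets to average")
    aucs = [m.auc for m in sets]
    return MetricSet(
        sens=float(np.mean([m.sens for m in sets])),
        spec=float(np.mean([m.spec for m in sets])),
        prec=float(np.mean([m.prec for m in sets])),
        acc=float(np.mean([m.acc for m in sets])),
        mcc=float(np.mean([m.mcc for m in sets])),
        f1=float(np.mean([m.f1 for m in sets])),
        auc=float(np.mean(aucs)) if all(a is not None for a in aucs) else None,
    )
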