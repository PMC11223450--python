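"""Confusion matrix and the ten standard binary-classification metrics.

Class 1 is disease presence.  ``recall`` is reported as an alias of
sensitivity (they are the same quantity, tp / (tp + fn)).  Entries with a
zero denominator are nan and listed in ``undefined``; MCC with a zero
denominator is 0 (and flagged).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricReport", "confusion", "compute_metrics"]

METRIC_ORDER = [
    "accuracy", "sensitivity", "specificity", "precision",
    "f1", "mcc", "npv", "fpr", "fnr",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        counts = (self.tp, self.tn, self.fp, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    npv: float
    fpr: float
    fnr: float
    undefined: list = field(default_factory=list)

    @property
    def recall(self) -> float:
        """Alias of sensitivity (identical by definition)."""
        return self.sensitivity

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_ORDER}

    def to_json(self) -> str:
        d = self.as_dict()
        d["undefined"] = list(self.undefined)
        return json.dumps(d)

    def to_csv_row(self) -> str:
        """One header + one value row in the reported column order."""
        header = ",".join(METRIC_ORDER)
        vals = ",".join(f"{getattr(self, m):.6f}" for m in METRIC_ORDER)
        return f"{header}\n{vals}\n"


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Standard binary confusion counts (class 1 = presence)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if not (np.all(np.isin(yt, [0, 1])) and np.all(np.isin(yp, [0, 1]))):
        raise ValueError("labels must be binary {0,1}")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num, den, name, undefined):
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """All ten reported metrics from the confusion counts."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    undefined: list = []
    acc = (tp + tn) / cm.total
    sens = _ratio(tp, tp + fn, "sensitivity", undefined)
    spec = _ratio(tn, tn + fp, "specificity", undefined)
    prec = _ratio(tp, tp + fp, "precision", undefined)
    if math.isnan(sens) or math.isnan(prec) or (prec + sens) == 0:
        undefined.append("f1")
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    npv = _ratio(tn, tn + fn, "npv", undefined)
    fpr = _ratio(fp, fp + tn, "fpr", undefined)
    fnr = _ratio(fn, fn + tp, "fnr", undefined)
    return MetricReport(
        accuracy=acc, sensitivity=sens, specificity=spec, precision=prec,
        f1=f1, mcc=mcc, npv=npv, fpr=fpr, fnr=fnr, undefined=undefined,
    )
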