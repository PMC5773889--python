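"""Confusion-matrix metrics and ROC/AUC.

Metric conventions: SN (recall) = TP/(TP+FN), SP = TN/(TN+FP),
Precision = TP/(TP+FP), ACC = (TP+TN)/total,
F = 2·SN·Pre/(SN+Pre), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Any metric whose denominator is zero is reported as 0 and flagged, so fold
aggregation never fails on a degenerate fold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_measure: float
    mcc: float
    auc: float | None = None
    roc_points: np.ndarray | None = None  # (k, 2) of (FPR, TPR)
    zero_denominator: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
             "SN": self.sensitivity, "SP": self.specificity,
             "Precision": self.precision, "ACC": self.accuracy,
             "F": self.f_measure, "MCC": self.mcc}
        if self.auc is not None:
            d["AUC"] = self.auc
        if self.zero_denominator:
            d["zero_denominator"] = list(self.zero_denominator)
        return d

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def roc_tsv(self) -> str:
        if self.roc_points is None:
            raise ValueError("no ROC points in this report")
        lines = ["FPR\tTPR"]
        lines += [f"{fpr:.6f}\t{tpr:.6f}" for fpr, tpr in self.roc_points]
        return "\n".join(lines) + "\n"


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> EvalReport:
    """Metrics from raw confusion counts (zero denominators → 0, flagged)."""
    for name, v in (("TP", tp), ("TN", tn), ("FP", fp), ("FN", fn)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    sn = safe(tp, tp + fn, "SN")
    sp = safe(tn, tn + fp, "SP")
    pre = safe(tp, tp + fp, "Precision")
    acc = (tp + tn) / total
    f = safe(2 * sn * pre, sn + pre, "F")
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = safe(tp * tn - fp * fn, mcc_den, "MCC")
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, sensitivity=sn,
                      specificity=sp, precision=pre, accuracy=acc,
                      f_measure=f, mcc=mcc, zero_denominator=flags)


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """ROC curve and trapezoid AUC from continuous scores and ±1 labels.

    The threshold sweep runs over the unique scores; the trapezoid area
    equals the Mann–Whitney pairwise statistic with ties counted 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, scores, pos_label=classes.max())
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def metrics_from_scores(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full report (confusion metrics at ``threshold`` plus ROC/AUC) from
    continuous scores in (0, 1) and ±1 labels."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = np.where(scores > threshold, 1, -1)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == -1) & (y == -1)))
    fp = int(np.sum((pred == 1) & (y == -1)))
    fn = int(np.sum((pred == -1) & (y == 1)))
    report = confusion_metrics(tp, tn, fp, fn)
    report.auc, report.roc_points = roc_auc(scores, y)
    return report


def summarize_folds(reports: list[EvalReport]) -> dict[str, tuple[float, float]]:
    """Mean ± sample standard deviation per metric across CV folds."""
    keys = ["SN", "SP", "Precision", "ACC", "F", "MCC", "AUC"]
    out = {}
    for k in keys:
        vals = [r.as_dict().get(k) for r in reports]
        vals = [v for v in vals if v is not None]
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out[k] = (float(arr.mean()), sd)
    return out
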