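"""Binary-classification metrics: Sn, Sp, Acc, MCC, ROC/AUC.

Sensitivity, specificity and accuracy are reported on the 0-100 scale, as
customary in the enhancer-prediction literature:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

The MCC denominator carries the square root (MCC is the phi correlation of
the two binary label vectors); a zero denominator yields 0 by convention.
Undefined rate metrics (empty class) are reported as NaN rather than a
silent zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/TN/FP/FN for parallel 0/1 label lists (positive class = 1)."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError(f"shape mismatch: y_true {yt.shape} vs y_pred {yp.shape}")
    if yt.size == 0:
        raise ValueError("empty input")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be 0/1")
    return ConfusionMatrix(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def sn_sp_acc(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(Sn, Sp, Acc) as percentages; NaN where a denominator is zero."""
    sn = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else math.nan
    sp = 100.0 * cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else math.nan
    acc = 100.0 * (cm.tp + cm.tn) / cm.total if cm.total else math.nan
    if math.isnan(sn) or math.isnan(sp):
        logger.warning("undefined rate metric for %s (empty class)", cm)
    return sn, sp, acc


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient with the square-rooted denominator."""
    num = cm.tp * cm.tn - cm.fp * cm.fn
    den = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if den == 0:
        logger.warning("degenerate confusion matrix %s: MCC set to 0", cm)
        return 0.0
    return num / math.sqrt(den)


def roc_auc(y_true, scores) -> tuple[float, np.ndarray]:
    """Trapezoidal AUC (rank/Mann-Whitney tie handling) plus ROC points.

    Returns (auc, points) where points is an (n, 3) array of
    (false-positive rate, true-positive rate, threshold).
    """
    yt = np.asarray(y_true, dtype=int)
    if len(set(yt.tolist())) < 2:
        logger.warning("single-class truth: AUC undefined")
        return math.nan, np.zeros((0, 3))
    auc = float(roc_auc_score(yt, np.asarray(scores, dtype=float)))
    fpr, tpr, thr = roc_curve(yt, scores)
    return auc, np.column_stack([fpr, tpr, thr])


@dataclass
class MetricsReport:
    """Sn/Sp/Acc in percent, MCC in [-1, 1], AUC in [0, 1], plus counts."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    confusion: ConfusionMatrix

    @classmethod
    def from_predictions(cls, y_true, y_pred, scores=None) -> "MetricsReport":
        cm = confusion(y_true, y_pred)
        sn, sp, acc = sn_sp_acc(cm)
        auc = roc_auc(y_true, scores)[0] if scores is not None else math.nan
        return cls(sn=sn, sp=sp, acc=acc, mcc=mcc(cm), auc=auc, confusion=cm)

    def to_dict(self) -> dict:
        return {
            "Sn": self.sn,
            "Sp": self.sp,
            "Acc": self.acc,
            "MCC": self.mcc,
            "AUC": self.auc,
            "confusion": {
                "TP": self.confusion.tp,
                "TN": self.confusion.tn,
                "FP": self.confusion.fp,
                "FN": self.confusion.fn,
            },
        }


def summarize(values) -> tuple[float, float]:
    """Mean and population standard deviation (divisor N) of a metric series."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))
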