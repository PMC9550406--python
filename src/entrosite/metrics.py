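"""Binary-classification metrics: SE, SP, ACC, MCC and ROC/AUC.

Conventions
-----------
* SE = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total.
* MCC is the standard Matthews correlation,
  (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
  defined as 0 when any marginal is zero.
* For a test set with equal numbers of positives and negatives, MCC has the
  closed form (SE+SP-1)/sqrt((1+SE-SP)(1+SP-SE)) and ACC = (SE+SP)/2;
  :func:`mcc_balanced` implements the closed form (and raises on a zero
  denominator rather than adopting the convention above).
* ROC is the threshold sweep over unique scores with ties crossing
  simultaneously; trapezoidal AUC is then the Mann-Whitney statistic with
  half-credit for score ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def se(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def mcc(self) -> float:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            return 0.0
        return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")


def confusion(
    scores: Iterable[float], labels: Iterable[int], threshold: float = 0.5
) -> ConfusionMetrics:
    """Confusion counts at a threshold (score >= threshold predicts binding)."""
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(y)
    pred = s >= threshold
    return ConfusionMetrics(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        threshold=threshold,
    )


def mcc_balanced(se: float, sp: float) -> float:
    """MCC from (SE, SP) alone, valid for equal-sized classes.

    MCC = (SE+SP-1) / sqrt((1+SE-SP)(1+SP-SE)).
    """
    if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("SE and SP must lie in [0, 1]")
    denom = (1.0 + se - sp) * (1.0 + sp - se)
    if denom == 0.0:
        raise ValueError("undefined at SE-SP = +/-1 (zero denominator)")
    return (se + sp - 1.0) / math.sqrt(denom)


def roc_auc(scores: Iterable[float], labels: Iterable[int]) -> RocCurve:
    """ROC curve and trapezoidal AUC from continuous scores."""
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=int)
    _check_two_classes(y)
    fpr, tpr, _ = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


REPORT_COLUMNS = ["group", "protein", "SE", "SP", "ACC", "MCC", "AUC_train", "AUC_test"]


def report(per_protein: Iterable[Mapping[str, object]]) -> pd.DataFrame:
    """Per-protein metric table plus a macro-average row.

    Each input mapping supplies group, protein and the five metric columns;
    the final row averages every numeric column arithmetically.
    """
    rows = list(per_protein)
    if not rows:
        raise ValueError("at least one evaluated protein is required")
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    mean = df[REPORT_COLUMNS[2:]].mean()
    avg = {"group": "", "protein": "average", **mean.to_dict()}
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
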