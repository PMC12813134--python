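"""Classification metric battery for PASS/FAIL variant refinement.

PASS is the positive class throughout: tp = predicted PASS & labeled
PASS, tn = predicted FAIL & labeled FAIL. Precision, recall and F1 are
reported per class and as support-weighted two-class averages (the
convention under which weighted recall equals accuracy). MCC is computed
with factored square roots so counts in the tens of millions cannot
overflow, and ROC AUC is the Mann-Whitney statistic with midrank tie
handling.

Zero-denominator metrics are defined as 0 with a warning, matching the
"random prediction" convention for MCC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .vcf_io import FAIL, PASS


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; defining it as 0", stacklevel=3)
        return 0.0
    return num / den


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with PASS as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def support_pass(self) -> int:
        return self.tp + self.fn

    @property
    def support_fail(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def confusion(labels: Sequence[str], predictions: Sequence[str]) -> ConfusionCounts:
    """Count the 2x2 table from parallel PASS/FAIL label streams."""
    if len(labels) != len(predictions):
        raise ValueError(
            f"labels ({len(labels)}) and predictions ({len(predictions)}) differ in length"
        )
    tp = fp = fn = tn = 0
    for y, p in zip(labels, predictions):
        if p == PASS:
            if y == PASS:
                tp += 1
            else:
                fp += 1
        else:
            if y == PASS:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def accuracy(c: ConfusionCounts) -> float:
    """(tp + tn) / total — fraction of records whose PASS/FAIL call matches."""
    return _safe_div(c.tp + c.tn, c.total, "accuracy")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient, in [-1, 1].

    +1 is ideal, 0 a random prediction (including any degenerate margin,
    where a factor of the denominator vanishes), -1 a perfectly reversed
    prediction. Each denominator factor is rooted before multiplying so
    products of ~1e7-scale counts cannot overflow.
    """
    f1_, f2, f3, f4 = c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn
    if 0 in (f1_, f2, f3, f4):
        return 0.0
    num = float(c.tp) * c.tn - float(c.fp) * c.fn
    den = math.sqrt(f1_) * math.sqrt(f2) * math.sqrt(f3) * math.sqrt(f4)
    return num / den


@dataclass(frozen=True)
class MetricsReport:
    """All derived metrics for one evaluated record set."""

    counts: ConfusionCounts
    accuracy: float
    precision_pass: float
    precision_fail: float
    recall_pass: float
    recall_fail: float
    f1_pass: float
    f1_fail: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    mcc: float
    roc_auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "support_pass": self.counts.support_pass,
            "support_fail": self.counts.support_fail,
            "accuracy": self.accuracy,
            "precision_pass": self.precision_pass,
            "precision_fail": self.precision_fail,
            "recall_pass": self.recall_pass,
            "recall_fail": self.recall_fail,
            "f1_pass": self.f1_pass,
            "f1_fail": self.f1_fail,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
            "mcc": self.mcc,
        }
        if self.roc_auc is not None:
            d["roc_auc"] = self.roc_auc
        return d


def weighted_metrics(c: ConfusionCounts, roc_auc_value: float | None = None) -> MetricsReport:
    """Per-class and support-weighted precision/recall/F1 (+ accuracy, MCC).

    Weights are the true-class supports (PASS: tp+fn, FAIL: fp+tn), the
    scikit-learn ``average="weighted"`` convention. For two classes the
    weighted recall is identically the accuracy.
    """
    prec_p = _safe_div(c.tp, c.tp + c.fp, "PASS precision")
    prec_f = _safe_div(c.tn, c.tn + c.fn, "FAIL precision")
    rec_p = _safe_div(c.tp, c.tp + c.fn, "PASS recall")
    rec_f = _safe_div(c.tn, c.tn + c.fp, "FAIL recall")
    f1_p = _safe_div(2 * prec_p * rec_p, prec_p + rec_p, "PASS F1")
    f1_f = _safe_div(2 * prec_f * rec_f, prec_f + rec_f, "FAIL F1")
    n = c.total
    wp = _safe_div(c.support_pass * prec_p + c.support_fail * prec_f, n, "weighted precision")
    wr = _safe_div(c.support_pass * rec_p + c.support_fail * rec_f, n, "weighted recall")
    wf = _safe_div(c.support_pass * f1_p + c.support_fail * f1_f, n, "weighted F1")
    return MetricsReport(
        counts=c,
        accuracy=accuracy(c),
        precision_pass=prec_p,
        precision_fail=prec_f,
        recall_pass=rec_p,
        recall_fail=rec_f,
        f1_pass=f1_p,
        f1_fail=f1_f,
        precision_weighted=wp,
        recall_weighted=wr,
        f1_weighted=wf,
        mcc=mcc(c),
        roc_auc=roc_auc_value,
    )


def roc_auc(labels: Sequence[str], probabilities: Sequence[float]) -> float:
    """Area under the ROC curve from PASS probabilities.

    Computed as the Mann-Whitney statistic P(score_PASS > score_FAIL) +
    0.5 * P(tie) via midranks, equivalent to exhaustive enumeration of
    all PASS x FAIL score pairs. Degenerate single-class inputs return 0
    with a warning.
    """
    y = np.asarray([1 if l == PASS else 0 for l in labels])
    s = np.asarray(probabilities, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and probabilities differ in length")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("ROC AUC undefined with a single class; defining it as 0",
                      stacklevel=2)
        return 0.0
    ranks = rankdata(s)  # midranks
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
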