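"""Triage metrics (precision/recall/F1) and paired significance testing."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

__all__ = ["ConfusionMatrix", "Metrics", "confusion", "metrics", "mcnemar", "round_half_up"]


def round_half_up(x: float, decimals: int = 2) -> float:
    scale = 10**decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class Metrics:
    """Precision, recall and F1 as percentages (full precision)."""

    precision: float
    recall: float
    f1: float

    def rounded(self, decimals: int = 2) -> "Metrics":
        return Metrics(
            round_half_up(self.precision, decimals),
            round_half_up(self.recall, decimals),
            round_half_up(self.f1, decimals),
        )


def confusion(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionMatrix:
    """Count the four cells; the positive class is label 1."""
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    tp = fn = fp = tn = 0
    for p, y in zip(predictions, labels):
        if p not in (0, 1) or y not in (0, 1):
            raise ValueError("predictions and labels must be binary")
        if y == 1:
            if p == 1:
                tp += 1
            else:
                fn += 1
        else:
            if p == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def metrics(cm: ConfusionMatrix) -> Metrics:
    """precision = tp/(tp+fp), recall = tp/(tp+fn), F1 their harmonic
    mean; every 0/0 is defined as 0."""
    p = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    r = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return Metrics(precision=100.0 * p, recall=100.0 * r, f1=100.0 * f1)


def mcnemar(
    preds_a: Sequence[int], preds_b: Sequence[int], labels: Sequence[int]
) -> tuple[float, float]:
    """Paired McNemar test on two models' decisions.

    b = #(a correct, b wrong), c = #(a wrong, b correct).  The statistic
    is the continuity-corrected (|b-c|-1)^2/(b+c); the p-value comes from
    chi-square with 1 df, or the exact two-sided binomial when fewer
    than 25 discordant pairs are available.
    """
    if not (len(preds_a) == len(preds_b) == len(labels)):
        raise ValueError("prediction and label vectors differ in length")
    b = c = 0
    for pa, pb, y in zip(preds_a, preds_b, labels):
        a_ok, b_ok = pa == y, pb == y
        if a_ok and not b_ok:
            b += 1
        elif b_ok and not a_ok:
            c += 1
    if b + c == 0:
        return 0.0, 1.0
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    if b + c < 25:
        p_value = stats.binomtest(b, n=b + c, p=0.5).pvalue
    else:
        p_value = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), float(p_value)
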