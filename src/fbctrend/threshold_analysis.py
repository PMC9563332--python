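"""Percentile risk thresholds, confusion matrices, and ROC curves.

A screening threshold is set at a percentile of the predicted-risk
distribution (75th to 99th by default); "positive" means risk strictly
above the cut-off, so with distinct risks the flagged fraction at
percentile p is exactly (100 - p)%.  Patients censored before the
horizon count as negatives in the confusion matrix, so the four margins
always sum to the full cohort.  Sensitivity, specificity, PPV and NPV
are reported as percentages rounded half-up to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = float("nan")
    percentile: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AccuracyRow:
    """Diagnostic accuracy as percentages, two decimals, round-half-up."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    exact = Decimal(100) * Decimal(num) / Decimal(den)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percentile_threshold(risks, percentile: float) -> float:
    """Empirical quantile (type-1 / inverse-ECDF) of predicted risk.

    "Positive" is strictly above the returned cut-off, so at percentile 0
    everyone except exact-minimum ties is flagged, and at 100 nobody is.
    """
    risks = np.asarray(risks, float)
    if risks.size == 0:
        raise ValueError("empty risk vector")
    if not (0.0 <= percentile <= 100.0):
        raise ValueError("percentile must be in [0, 100]")
    s = np.sort(risks)
    k = max(1, math.ceil(risks.size * percentile / 100.0))
    return float(s[k - 1])


def confusion_at_threshold(risks, outcomes, cutoff: float, percentile: float = float("nan")) -> ConfusionCounts:
    """Cross-tabulate ``risk > cutoff`` against binary outcomes.

    Censored-before-horizon patients must already be coded 0, so the
    margins equal the full cohort size.
    """
    risks = np.asarray(risks, float)
    y = np.asarray(outcomes, int)
    if risks.shape != y.shape:
        raise ValueError(f"length mismatch: {risks.shape} risks vs {y.shape} outcomes")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    flag = risks > cutoff
    return ConfusionCounts(
        tp=int(np.sum(flag & (y == 1))),
        fp=int(np.sum(flag & (y == 0))),
        tn=int(np.sum(~flag & (y == 0))),
        fn=int(np.sum(~flag & (y == 1))),
        threshold=float(cutoff),
        percentile=percentile,
    )


def accuracy_measures(cc: ConfusionCounts) -> AccuracyRow:
    """Sens/spec/PPV/NPV as percentages to 2 dp; undefined ratios -> None."""
    if cc.total == 0:
        raise ValueError("empty confusion matrix")
    return AccuracyRow(
        sensitivity=_pct(cc.tp, cc.tp + cc.fn),
        specificity=_pct(cc.tn, cc.tn + cc.fp),
        ppv=_pct(cc.tp, cc.tp + cc.fp),
        npv=_pct(cc.tn, cc.tn + cc.fn),
    )


def roc_curve(risks, outcomes) -> tuple[pd.DataFrame, float]:
    """ROC points over all distinct thresholds and the trapezoidal area.

    The area equals the Mann-Whitney statistic (tied risks half credit).
    """
    risks = np.asarray(risks, float)
    y = np.asarray(outcomes, int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, risks)
    area = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), area


def threshold_table(
    risks, outcomes, percentiles=(75, 80, 85, 90, 95, 99)
) -> pd.DataFrame:
    """Diagnostic-accuracy table across risk percentiles.

    Columns mirror the standard screening layout: risk centile, cut-off,
    TP/FP/TN/FN, sensitivity, specificity, PPV, NPV.
    """
    rows = []
    for p in percentiles:
        cut = percentile_threshold(risks, p)
        cc = confusion_at_threshold(risks, outcomes, cut, percentile=p)
        acc = accuracy_measures(cc)
        rows.append(
            {
                "risk_centile": p,
                "risk_cutoff": cut,
                "tp": cc.tp,
                "fp": cc.fp,
                "tn": cc.tn,
                "fn": cc.fn,
                "sensitivity": acc.sensitivity,
                "specificity": acc.specificity,
                "ppv": acc.ppv,
                "npv": acc.npv,
            }
        )
    return pd.DataFrame(rows)
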