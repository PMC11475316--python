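"""ROC analysis and diagnostic threshold selection.

One-vs-rest contrasts over tissue classes (e.g. endometrial cancer of
any subtype versus non-tumorous tissue) are evaluated per modality:
sweep every distinct observed value as a candidate threshold, trace
(FPR, TPR), integrate the AUC, and select an operating threshold by the
Youden index (maximize TPR − FPR; ties resolved toward higher
specificity) or the closest-to-(0,1) rule.  Sensitivity and specificity
are reported in percent.  A value equal to the threshold counts as a
positive call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ContrastSpec, ROCResult

#: Endometrial cancer (any subtype) vs all non-tumorous tissue (hyperplasia
#: including EIN, and normal endometrium).
EC_CLASSES = frozenset({"EC_low", "EC_high", "EC_clear", "EC_serous"})
NON_TUMOROUS_CLASSES = frozenset(
    {"proliferative", "secretory", "atrophic", "non_atypical", "EIN"}
)
#: EIN (precancer) vs benign tissue (non-atypical hyperplasia + normal).
BENIGN_CLASSES = frozenset(
    {"proliferative", "secretory", "atrophic", "non_atypical"}
)

THRESHOLD_POLICIES = ("youden", "closest")


def ec_vs_non_tumorous(modality: str) -> ContrastSpec:
    return ContrastSpec(EC_CLASSES, NON_TUMOROUS_CLASSES, modality, "high")


def ein_vs_benign(modality: str) -> ContrastSpec:
    return ContrastSpec(frozenset({"EIN"}), BENIGN_CLASSES, modality, "high")


def roc_from_values(
    positives, negatives, direction: str = "high", modality: str | None = None
) -> ROCResult:
    """ROC sweep over all distinct observed values as candidate thresholds.

    Under ``direction="high"`` a value is called positive when it is >=
    the threshold (<= under ``"low"``).  The sweep includes the trivial
    all-negative and all-positive endpoints.  AUC is computed by
    trapezoidal integration of the sweep, which equals the pairwise
    probability P(pos ranked above neg) with ties counted half.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("roc requires at least one positive and one negative value")
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")

    values = np.unique(np.concatenate([pos, neg]))
    if direction == "high":
        # descending thresholds: strictest (call nothing) -> laxest
        thresholds = np.concatenate([[np.inf], values[::-1]])
        tpr = np.array([np.mean(pos >= t) for t in thresholds])
        fpr = np.array([np.mean(neg >= t) for t in thresholds])
    else:
        thresholds = np.concatenate([[-np.inf], values])
        tpr = np.array([np.mean(pos <= t) for t in thresholds])
        fpr = np.array([np.mean(neg <= t) for t in thresholds])

    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
        direction=direction, modality=modality,
    )


def roc(table: pd.DataFrame, contrast: ContrastSpec) -> ROCResult:
    """ROC for a class contrast from a measurement table."""
    sub = table[table["modality"] == contrast.modality]
    pos = sub[sub["tissue_class"].isin(contrast.positive_classes)]["value"].to_numpy()
    neg = sub[sub["tissue_class"].isin(contrast.negative_classes)]["value"].to_numpy()
    return roc_from_values(pos, neg, contrast.direction, contrast.modality)


def select_threshold(result: ROCResult, policy: str = "youden") -> ROCResult:
    """Operating threshold with sensitivity/specificity in percent.

    ``"youden"`` maximizes TPR − FPR; ``"closest"`` minimizes the distance
    to the ideal (FPR, TPR) = (0, 1) corner.  Ties are broken toward
    higher specificity (lower FPR), then higher sensitivity.
    """
    if policy not in THRESHOLD_POLICIES:
        raise ValueError(
            f"unknown policy {policy!r}; available: {', '.join(THRESHOLD_POLICIES)}"
        )
    finite = np.isfinite(result.thresholds)
    thr, tpr, fpr = (a[finite] for a in (result.thresholds, result.tpr, result.fpr))
    if thr.size == 0:
        thr, tpr, fpr = result.thresholds, result.tpr, result.fpr
    if policy == "youden":
        score = tpr - fpr
    else:
        score = -np.hypot(fpr, 1.0 - tpr)
    order = np.lexsort((-tpr, fpr, -score))  # best score, then low FPR, high TPR
    i = order[0]
    return ROCResult(
        thresholds=result.thresholds,
        tpr=result.tpr,
        fpr=result.fpr,
        auc=result.auc,
        direction=result.direction,
        modality=result.modality,
        chosen_threshold=float(thr[i]),
        se=float(tpr[i] * 100.0),
        sp=float((1.0 - fpr[i]) * 100.0),
    )


def classify(values, threshold: float, direction: str = "high") -> np.ndarray:
    """Binary labels by the threshold rule; the boundary counts positive."""
    values = np.asarray(values, dtype=float)
    if direction == "high":
        return values >= threshold
    if direction == "low":
        return values <= threshold
    raise ValueError("direction must be 'high' or 'low'")
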