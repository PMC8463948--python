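"""Evaluation statistics: ROC/PR, matched-specificity operating points,
the DeLong paired AUC test, and phrase-based categorization of commercial
ECG interpretation text.

AUROC is the trapezoidal area under the ROC curve over unique-score
thresholds (equivalently the Mann-Whitney pair statistic with ties counted
half).  AUPRC uses step-wise integration of the precision-recall curve (no
interpolation).  Classifiers are compared at matched specificity: each
model's threshold is set so its specificity reaches a common target and
sensitivities are compared at those thresholds.  Correlated AUROCs on the
same cases are compared with DeLong's nonparametric test via placement
values (structural components).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as skm


class SingleClassError(ValueError):
    """Both classes must be present."""


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise SingleClassError("need both positive and negative cases")
    return y


@dataclass
class EvalResult:
    roc_points: np.ndarray  # (n, 2) of (FPR, TPR), (0,0) .. (1,1)
    pr_points: np.ndarray   # (n, 2) of (recall, precision)
    auroc: float
    auprc: float
    thresholds: np.ndarray
    confusion: np.ndarray   # (n_thresholds, 4): TP, FP, TN, FN


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float


def roc_pr(scores: np.ndarray, labels: np.ndarray) -> EvalResult:
    """ROC and PR curves with areas and per-threshold confusion counts."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    fpr, tpr, roc_thr = skm.roc_curve(y, s)
    auroc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = skm.precision_recall_curve(y, s)
    # step-wise integration: sum precision * recall increments
    auprc = float(-np.sum(np.diff(recall) * precision[:-1]))
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    thresholds = np.unique(s)
    confusion = np.empty((len(thresholds), 4), dtype=int)
    order = np.argsort(s)
    s_sorted, y_sorted = s[order], y[order]
    cum_pos = np.cumsum(y_sorted)
    cum_neg = np.cumsum(1 - y_sorted)
    for i, t in enumerate(thresholds):
        below = np.searchsorted(s_sorted, t, side="left")
        fn = cum_pos[below - 1] if below else 0
        tn = cum_neg[below - 1] if below else 0
        confusion[i] = (n_pos - fn, n_neg - tn, tn, fn)
    return EvalResult(
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall, precision]),
        auroc=auroc,
        auprc=auprc,
        thresholds=thresholds,
        confusion=confusion,
    )


def sensitivity_at_specificity(
    scores: np.ndarray, labels: np.ndarray, target_specificity: float
) -> OperatingPoint:
    """Operating point at the smallest threshold whose specificity meets
    the target (classify positive when score >= threshold).

    Among thresholds with specificity >= target this picks the one with
    the highest sensitivity; the achieved specificity may exceed the
    target exactly as on a discrete ROC curve.
    """
    if not 0.0 < target_specificity < 1.0:
        raise ValueError("target_specificity must be in (0, 1)")
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    n_neg = int((y == 0).sum())
    best = None
    # candidate thresholds: unique scores and one above the max
    for t in np.append(np.unique(s), np.inf):
        pred = s >= t
        tn = int(((~pred) & (y == 0)).sum())
        spec = tn / n_neg
        if spec >= target_specificity:
            tp = int((pred & (y == 1)).sum())
            fp = int((pred & (y == 0)).sum())
            fn = int(((~pred) & (y == 1)).sum())
            sens = tp / (tp + fn)
            if best is None or sens > best.sensitivity:
                best = OperatingPoint(
                    threshold=float(t),
                    sensitivity=sens,
                    specificity=spec,
                    ppv=tp / (tp + fp) if tp + fp else 0.0,
                    npv=tn / (tn + fn) if tn + fn else 0.0,
                )
    if best is None:
        raise ValueError(
            f"specificity {target_specificity} unattainable on these scores"
        )
    return best


def placement_values(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components.

    V10[i] = fraction of negatives scored below positive i (ties half);
    V01[j] = fraction of positives scored above negative j (ties half).
    The AUC equals the mean of either vector.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(cmp.mean())


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> AucComparison:
    """Paired DeLong test for two correlated AUCs on the same cases."""
    y = _check_labels(labels)
    a10, a01, auc_a = placement_values(scores_a, y)
    b10, b01, auc_b = placement_values(scores_b, y)
    m, n = len(a10), len(a01)
    s10 = np.cov(np.stack([a10, b10]))
    s01 = np.cov(np.stack([a01, b01]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0 or diff == 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return AucComparison(
        auc_a=auc_a, auc_b=auc_b, var_diff=float(var), z=float(z), p_value=p
    )


# ---------------------------------------------------------------------------
# Commercial interpretation text

#: criterion 1: the machine interpretation is read as infarction
CRITERION_1_PHRASES = ("ACUTE MI", "ST elevation", "infarct")
#: criterion 2 extends criterion 1 with nonspecific repolarization phrases
CRITERION_2_PHRASES = CRITERION_1_PHRASES + (
    "T wave abnormality",
    "ST abnormality",
    "ST depression",
)


def categorize_interpretation(text: str, criterion: int) -> bool:
    """True iff any criterion phrase occurs in the interpretation text.

    Matching is case-insensitive substring matching after whitespace
    normalization, robust to report formatting; criterion 2's phrase set
    is a superset of criterion 1's, so its positives always include
    criterion 1's.
    """
    if criterion == 1:
        phrases = CRITERION_1_PHRASES
    elif criterion == 2:
        phrases = CRITERION_2_PHRASES
    else:
        raise ValueError(f"criterion must be 1 or 2, got {criterion}")
    norm = re.sub(r"\s+", " ", (text or "")).casefold()
    return any(re.sub(r"\s+", " ", p).casefold() in norm for p in phrases)
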