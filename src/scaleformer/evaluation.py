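"""Slide-level classification metrics.

Overall accuracy, micro-averaged F1/sensitivity/specificity and macro
one-vs-rest ROC-AUC, plus per-category records. For single-label multi-class
predictions, micro-F1 and micro-sensitivity are identical to accuracy; micro
specificity is the pooled one-vs-rest true-negative rate, which for C
categories equals ((C-2) + accuracy) / (C-1).

Per-category "accuracy" is reported as the one-vs-rest recall
(= sensitivity), the convention used in per-category diagnostic tables.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score


def confusion_matrix(
    y_true: list[int] | np.ndarray,
    y_pred: list[int] | np.ndarray,
    n_classes: int = 4,
) -> np.ndarray:
    """C x C matrix, rows = true 1-based category, cols = predicted."""
    labels = list(range(1, n_classes + 1))
    return _sk_confusion(y_true, y_pred, labels=labels)


def _ovr_counts(cm: np.ndarray, c: int) -> tuple[int, int, int, int]:
    tp = cm[c, c]
    fn = cm[c].sum() - tp
    fp = cm[:, c].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return int(tp), int(fn), int(fp), int(tn)


def overall_metrics(
    cm: np.ndarray,
    y_true: np.ndarray | None = None,
    scores: np.ndarray | None = None,
) -> dict[str, float]:
    """Overall record: accuracy, micro F1/sensitivity/specificity, macro AUC.

    ``scores`` (n_slides x C probability vectors, aligned with ``y_true``)
    enables the macro one-vs-rest ROC-AUC; categories absent from the truth
    are excluded from the macro mean with a warning.
    """
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    n_classes = cm.shape[0]
    acc = np.trace(cm) / total
    tp = fn = fp = tn = 0
    for c in range(n_classes):
        tpc, fnc, fpc, tnc = _ovr_counts(cm, c)
        tp, fn, fp, tn = tp + tpc, fn + fnc, fp + fpc, tn + tnc
    out = {
        "accuracy": float(acc),
        "f1_micro": float(2 * tp / (2 * tp + fp + fn)),
        "sensitivity_micro": float(tp / (tp + fn)),
        "specificity_micro": float(tn / (tn + fp)),
    }
    if scores is not None and y_true is not None:
        out["auc_macro"] = float(macro_auc(np.asarray(y_true), np.asarray(scores)))
    return out


def macro_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Macro mean of one-vs-rest ROC-AUC over categories present in truth."""
    n_classes = scores.shape[1]
    aucs = []
    for c in range(1, n_classes + 1):
        mask = y_true == c
        if mask.all() or not mask.any():
            warnings.warn(
                f"category {c} absent from truth (or the only one); "
                "excluded from macro AUC"
            )
            continue
        aucs.append(roc_auc_score(mask.astype(int), scores[:, c - 1]))
    if not aucs:
        raise ValueError("no category with both positives and negatives")
    return float(np.mean(aucs))


def per_class_metrics(cm: np.ndarray) -> list[dict[str, float | None]]:
    """One-vs-rest record per category (1-based ``class_index`` field).

    Categories with no true slides get ``None`` sensitivity/accuracy/F1
    (undefined, not zero).
    """
    records = []
    for c in range(cm.shape[0]):
        tp, fn, fp, tn = _ovr_counts(cm, c)
        support = tp + fn
        sens = tp / support if support else None
        f1 = 2 * tp / (2 * tp + fp + fn) if support or fp else None
        spec = tn / (tn + fp) if (tn + fp) else None
        records.append(
            {
                "class_index": c + 1,
                "support": support,
                "accuracy": sens,  # per-category accuracy == one-vs-rest recall
                "sensitivity": sens,
                "specificity": spec,
                "f1": f1,
            }
        )
    return records
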