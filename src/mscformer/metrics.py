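"""Evaluation metrics: accuracy, Cohen's kappa, Wilcoxon comparison, ROC/AUC.

Accuracy is the confusion-matrix trace over the total, in percent.  Kappa is
``(p_o - p_e) / (1 - p_e)``; the chance term ``p_e`` defaults to the Cohen
marginal-product form, which for balanced sessions coincides with ``1/M``
(the accuracy of a random guess) — selectable via ``chance``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "confusion_from_predictions",
    "accuracy",
    "kappa",
    "wilcoxon_compare",
    "roc_auc",
    "subject_summary_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """M x M counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of correctly classified trials: 100 * trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm.counts) / cm.total


def kappa(cm: ConfusionMatrix, chance: str = "marginal") -> float:
    """Cohen's kappa, ``(p_o - p_e) / (1 - p_e)``.

    ``chance="marginal"`` computes ``p_e`` from the row/column marginal
    products (standard Cohen definition); ``chance="uniform"`` fixes
    ``p_e = 1/M`` (random guessing over balanced classes).
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    if chance == "marginal":
        p_e = float(np.sum(cm.counts.sum(axis=1) * cm.counts.sum(axis=0)) / n**2)
    elif chance == "uniform":
        p_e = 1.0 / cm.n_classes
    else:
        raise ValueError(f"unknown chance model {chance!r}")
    if p_e >= 1.0:
        raise ValueError("degenerate chance agreement p_e = 1")
    return (p_o - p_e) / (1.0 - p_e)


def wilcoxon_compare(per_subject_a, per_subject_b) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired per-subject scores.

    Uses the exact null distribution for n <= 25 pairs; zero differences are
    dropped (Wilcoxon's original policy).  Returns the p-value and a
    significance tier: '**' for p < 0.01, '*' for p < 0.05, 'n.s.' otherwise.
    """
    a = np.asarray(per_subject_a, dtype=float)
    b = np.asarray(per_subject_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired subjects")
    d = a - b
    if np.all(d == 0):
        p = 1.0
        statistic = 0.0
    else:
        n_nonzero = int(np.count_nonzero(d))
        method = "exact" if n_nonzero <= 25 else "approx"
        res = stats.wilcoxon(a, b, zero_method="wilcox",
                             alternative="two-sided", method=method)
        p = float(res.pvalue)
        statistic = float(res.statistic)
    tier = "**" if p < 0.01 else "*" if p < 0.05 else "n.s."
    return {"p_value": p, "statistic": statistic, "tier": tier}


def roc_auc(true_labels, scores) -> dict:
    """Binary ROC curve and AUC from positive-class probabilities.

    AUC equals the Mann-Whitney probability that a random positive scores
    above a random negative (ties count one half).
    """
    y = np.asarray(true_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"ROC requires both classes present, found labels {classes.tolist()}"
        )
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": auc}


def subject_summary_table(
    accuracies: dict[str, float],
    kappas: dict[str, float],
    baseline_accuracies: dict[str, float] | None = None,
):
    """Per-subject comparison table: one column per subject plus the
    Accuracy mean, its S.D., the mean Kappa, and (when a baseline method's
    per-subject accuracies are given) the paired Wilcoxon p-value.

    Returns a one-row :class:`pandas.DataFrame` suitable for CSV export.
    """
    import pandas as pd

    subjects = list(accuracies)
    row = {s: accuracies[s] for s in subjects}
    accs = np.array([accuracies[s] for s in subjects], dtype=float)
    row["Accuracy"] = accs.mean()
    row["S.D."] = accs.std(ddof=1) if len(subjects) > 1 else 0.0
    row["Kappa"] = float(np.mean([kappas[s] for s in subjects]))
    if baseline_accuracies is not None:
        base = [baseline_accuracies[s] for s in subjects]
        row["p-value"] = wilcoxon_compare(accs, base)["p_value"]
    return pd.DataFrame([row])
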