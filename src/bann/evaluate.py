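"""Selection evaluation: power, FDR, ROC and precision-recall curves.

Bayesian scores (PIPs) are selected at the median-probability-model cutoff
(PIP >= 0.5); frequentist P-values at a Bonferroni-corrected level alpha/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = ["EvaluationReport", "evaluate_selection", "bonferroni_threshold"]


@dataclass
class EvaluationReport:
    power: float
    fdr: float
    threshold: float
    n_selected: int
    selected: np.ndarray
    roc_points: np.ndarray  # (fpr, tpr) rows
    pr_points: np.ndarray  # (recall, precision) rows


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test significance cutoff alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return alpha / m


def evaluate_selection(scores, truth, rule: str = "pip_threshold", alpha_or_cutoff: float = 0.5) -> EvaluationReport:
    """Score a selection against causal truth labels.

    rule="pip_threshold": select scores >= cutoff (scores are PIPs, higher is
    stronger evidence).  rule="bonferroni": scores are P-values, select
    scores <= alpha/m.  FDR of an empty selection is defined as 0.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    if rule == "pip_threshold":
        cutoff = float(alpha_or_cutoff)
        selected = scores >= cutoff
        ranking = scores
    elif rule == "bonferroni":
        cutoff = bonferroni_threshold(alpha_or_cutoff, scores.size)
        selected = scores <= cutoff
        ranking = -np.log10(np.maximum(scores, np.finfo(float).tiny))
    else:
        raise ValueError(f"unknown rule {rule!r}")

    n_sel = int(selected.sum())
    tp = int((selected & truth).sum())
    power = tp / truth.sum() if truth.any() else 0.0
    fdr = (n_sel - tp) / n_sel if n_sel else 0.0

    if truth.any() and not truth.all():
        fpr, tpr, _ = roc_curve(truth, ranking)
        prec, rec, _ = precision_recall_curve(truth, ranking)
        roc = np.column_stack([fpr, tpr])
        pr = np.column_stack([rec[::-1], prec[::-1]])
    else:
        roc = np.zeros((0, 2))
        pr = np.zeros((0, 2))
    return EvaluationReport(
        power=float(power),
        fdr=float(fdr),
        threshold=cutoff,
        n_selected=n_sel,
        selected=np.flatnonzero(selected),
        roc_points=roc,
        pr_points=pr,
    )
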