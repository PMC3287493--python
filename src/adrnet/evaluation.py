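"""Performance measures (AUC/ACC/SEN/SPE), CV summaries, and condition
comparisons (Welch t-test, one-way ANOVA)."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MetricError

logger = logging.getLogger(__name__)


def _check_two_classes(labels: np.ndarray) -> None:
    if not ((labels == 1).any() and (labels == 0).any()):
        raise MetricError("metric undefined: labels contain a single class")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg); ties in
    score contribute half. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    n1 = int((labels == 1).sum())
    n0 = labels.size - n1
    ranks = stats.rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def threshold_metrics(scores, labels, tau: float = 0.5) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at decision threshold ``tau``.

    A drug is called positive iff its score is >= tau.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pred = (scores >= tau).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = (tp + tn) / labels.size
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    return acc, sen, spe


def summarize_cv(result) -> dict[str, float]:
    """Elementwise median of the per-repeat pooled AUC/ACC/SEN/SPE."""
    if not result.repeat_metrics:
        result.compute_metrics()
    if not result.repeat_metrics:
        raise MetricError("CV result has no repeats to summarize")
    return {
        key: float(np.median([m[key] for m in result.repeat_metrics]))
        for key in ("auc", "acc", "sen", "spe")
    }


def compare_conditions(aucs_a=None, aucs_b=None, method: str = "welch_t",
                       groups: list | None = None) -> float:
    """Two-sided p-value comparing per-repeat metrics between conditions.

    ``welch_t`` runs an unequal-variance two-sample t-test on aucs_a vs
    aucs_b; ``anova`` runs a one-way ANOVA across ``groups``. Degenerate
    inputs (zero variance everywhere, equal means) yield p = 1.0.
    """
    if method == "welch_t":
        a = np.asarray(aucs_a, dtype=float)
        b = np.asarray(aucs_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least 2 values per sample for the t-test")
        if a.var() == 0 and b.var() == 0:
            if a.mean() == b.mean():
                logger.debug("degenerate t-test (identical constants): p = 1.0")
                return 1.0
            return 0.0
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if method == "anova":
        if groups is None or len(groups) < 2:
            raise ValueError("anova requires >= 2 groups")
        arrs = [np.asarray(g, dtype=float) for g in groups]
        if all(g.var() == 0 for g in arrs):
            means = [g.mean() for g in arrs]
            if len(set(means)) == 1:
                logger.debug("degenerate ANOVA (identical constants): p = 1.0")
                return 1.0
            return 0.0
        return float(stats.f_oneway(*arrs).pvalue)
    raise ValueError(f"unknown method {method!r}")


def comparison_report(rows: list[tuple[str, str, str, float]]) -> pd.DataFrame:
    """CSV-ready condition-comparison report."""
    return pd.DataFrame(rows, columns=["condition_a", "condition_b",
                                       "method", "p_value"])
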