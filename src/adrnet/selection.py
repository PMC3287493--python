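"""Per-feature association tests against a binary ADR class label.

Binary feature columns are tested with a two-sided Fisher exact test on the
2x2 presence/label table; integer-weighted columns (network-expanded or GO
counts) with a two-sided Wilcoxon rank-sum test. Features pass at raw
p < alpha (no multiple-testing correction by default, matching the
p < 0.05 screening rule this pipeline models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, sqrt
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .facts import ADRClassLabels, FactsMatrix

logger = logging.getLogger(__name__)

#: relative slack when comparing hypergeometric point masses in the
#: two-sided tail sum (guards against floating-point near-ties)
_REL_TOL = 1e-7

#: largest pooled sample size handled by the exact rank-sum branch
_EXACT_RANKSUM_N = 12


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Sums hypergeometric point probabilities (same margins) of all tables at
    most as probable as the observed one, with 1e-7 relative slack on the
    comparison. A zero margin makes the table degenerate: p = 1.0 (logged).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 integer matrix")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1, c2 = int(t[:, 0].sum()), int(t[:, 1].sum())
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        logger.debug("degenerate 2x2 table (zero margin): p = 1.0")
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(p, 1.0)


def ranksum_two_sided(xs, ys) -> float:
    """Two-sided Wilcoxon rank-sum p-value with midranks for ties.

    Exact permutation distribution of the rank sum when the pooled size is
    at most 12; otherwise a tie-corrected normal approximation (no
    continuity correction). Two-sided means P(|W - E[W]| >= |w - E[W]|)
    under random assignment of the pooled midranks.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = xs.size, ys.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([xs, ys]))
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    if n <= _EXACT_RANKSUM_N:
        dev = abs(w - mu)
        hits = sum(
            1 for idx in combinations(range(n), n1)
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9
        )
        return hits / comb(n, n1)
    # tie-corrected variance of the rank sum
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / ((n - 1) * n)
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return 1.0
    z = (w - mu) / sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


@dataclass(frozen=True)
class SelectedFeature:
    feature_id: str
    test_used: str  # "fisher" | "ranksum"
    p_value: float


def _is_binary_column(col: np.ndarray) -> bool:
    return bool(np.isin(col, (0, 1)).all())


def feature_pvalue(col: np.ndarray, y: np.ndarray) -> tuple[str, float]:
    """Test one feature column against binary labels (data-type dispatch)."""
    if _is_binary_column(col):
        a = int(((col == 1) & (y == 1)).sum())
        b = int(((col == 1) & (y == 0)).sum())
        c = int(((col == 0) & (y == 1)).sum())
        d = int(((col == 0) & (y == 0)).sum())
        return "fisher", fisher_exact_two_sided([[a, b], [c, d]])
    pos, neg = col[y == 1], col[y == 0]
    if pos.size == 0 or neg.size == 0:
        return "ranksum", 1.0
    return "ranksum", ranksum_two_sided(pos, neg)


def select_features(X: FactsMatrix, y: ADRClassLabels,
                    alpha: float = 0.05) -> list[SelectedFeature]:
    """Keep features with association p < alpha, sorted by ascending p.

    Ties in p are broken lexically by feature id, making the output a
    deterministic function of (X, y, alpha).
    """
    if X.drug_ids != y.drug_ids:
        raise ValueError("rows of X are not aligned with labels")
    labels = y.labels
    out: list[SelectedFeature] = []
    for j, fid in enumerate(X.feature_ids):
        test, p = feature_pvalue(X.values[:, j], labels)
        # alpha >= 1 is the explicit no-op screen (p can be exactly 1.0)
        if p < alpha or alpha >= 1.0:
            out.append(SelectedFeature(fid, test, p))
    out.sort(key=lambda s: (s.p_value, s.feature_id))
    return out


def selection_report(selected: list[SelectedFeature]) -> pd.DataFrame:
    """CSV-ready report of the selected features."""
    return pd.DataFrame(
        [(s.feature_id, s.test_used, s.p_value) for s in selected],
        columns=["feature_id", "test_used", "p_value"])
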