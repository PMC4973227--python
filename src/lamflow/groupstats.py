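"""Nonparametric group-comparison helpers.

The analysis never assumes normality: a D'Agostino-Pearson omnibus screen
is recorded for every cell (it consistently rejects normality on these
statistics), and inference proceeds with Kruskal-Wallis across groups
followed by Dunn's rank-based pairwise comparisons with Bonferroni
adjustment.  Dunn's z statistic is implemented directly (with the standard
tie correction) since no post-hoc package is part of the stack.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
from scipy.stats import kruskal, norm, normaltest, rankdata

__all__ = [
    "normality_p",
    "kruskal_groups",
    "dunn_test",
    "significance_symbol",
]


def normality_p(values: np.ndarray) -> float:
    """D'Agostino-Pearson omnibus normality p-value (NaN when n < 8)."""
    v = np.asarray(values, dtype=float)
    if v.size < 8 or np.ptp(v) == 0:
        return float("nan")
    return float(normaltest(v).pvalue)


def kruskal_groups(samples: Mapping[str, np.ndarray]) -> float:
    """Kruskal-Wallis p-value across named groups (NaN if not testable)."""
    arrays = [np.asarray(v, float) for v in samples.values() if len(v) >= 2]
    if len(arrays) < 2:
        return float("nan")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 1.0  # all values identical: no evidence of any difference
    return float(kruskal(*arrays).pvalue)


def dunn_test(samples: Mapping[str, np.ndarray],
              adjust: str = "bonferroni") -> dict:
    """Dunn's pairwise rank comparisons after a Kruskal-Wallis test.

    For groups i, j with mean pooled ranks R̄_i, R̄_j,

        z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) · (1/n_i + 1/n_j))

    with tie correction ``T = Σ(t³ − t) / (12(N − 1))`` summed over tied
    value multiplicities t.  Two-sided p-values are Bonferroni-multiplied
    by the number of comparisons (clipped at 1).

    Returns ``{(label_i, label_j): adjusted_p}`` for every unordered pair.
    """
    labels = list(samples.keys())
    arrays = [np.asarray(samples[g], float) for g in labels]
    n_per = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in n_per:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr
    pairs = list(combinations(range(len(labels)), 2))
    n_comp = len(pairs)
    out = {}
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / n_per[i] + 1.0 / n_per[j]))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * n_comp)
        out[(labels[i], labels[j])] = float(p)
    return out


def significance_symbol(p: float) -> str:
    """Conventional star coding of a p-value ('' when not significant)."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
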