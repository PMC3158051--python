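"""Two-tailed category statistics used for zone/genotype comparisons.

Thin, contract-checked wrappers over scipy.stats: chi-square contingency
tests on category tables (no continuity correction), exact Fisher tests on
2x2 tables, and two-tailed Mann-Whitney U on count samples (exact null
distribution for small samples without ties, normal approximation with tie
correction otherwise — scipy's ``method="auto"`` policy).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "chi_square_two_tailed",
    "fisher_exact_two_tailed",
    "mann_whitney_two_tailed",
]


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("expected a 2D contingency table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    return t


def chi_square_two_tailed(table) -> float:
    """Pearson chi-square p-value on an r x c table of counts.

    Raises on tables with a zero row/column margin (the statistic is
    undefined there); identical row proportions give statistic 0, p = 1.
    """
    t = _as_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square is undefined for tables with a zero margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.pvalue)


def fisher_exact_two_tailed(table) -> float:
    """Exact two-tailed Fisher p for a 2x2 table (hypergeometric null)."""
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney_two_tailed(sample_a, sample_b) -> float:
    """Two-tailed Mann-Whitney U p-value comparing two count samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)
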