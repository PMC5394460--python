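"""Contingency-table and proportion-interval statistics.

Thin, validated wrappers with the conventions used throughout the package:
Pearson chi-square without continuity correction, two-sided Fisher exact
tests, and Wilson score intervals for proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = ["ChiSquareResult", "pearson_chi_square", "fisher_exact_2x2", "wilson_ci"]


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def pearson_chi_square(table) -> ChiSquareResult:
    """Pearson chi-square of independence, no continuity correction.

    statistic = sum (O-E)^2 / E with E from the product of the margins;
    df = (r-1)(c-1).  A zero row or column margin raises ``ValueError``.
    """
    arr = _as_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    _, p = sps.fisher_exact(arr.astype(int), alternative="two-sided")
    return float(p)


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float, float]:
    """(point estimate, lower, upper) Wilson score interval for a proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - confidence, method="wilson")
    return successes / n, float(lo), float(hi)
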