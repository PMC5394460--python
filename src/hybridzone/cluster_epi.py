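"""Cluster assignment from membership coefficients and epidemiological
summaries: resistance-allele frequencies with confidence intervals, the human
blood index (HBI), and cross-cluster contingency tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import wilson_ci

__all__ = [
    "assign_cluster",
    "assign_all",
    "admixed_proportion",
    "allele_frequency_with_ci",
    "human_blood_index",
    "read_qmatrix",
    "ADMIXED",
]

ADMIXED = "admixed"
_ROW_TOL = 1e-6


def assign_cluster(q_row, t_q: float = 0.5, labels=None) -> str:
    """Assign one individual: the cluster with q_i >= t_q, else 'admixed'.

    A tie of two clusters at exactly ``t_q`` resolves to the lowest-index
    cluster with a warning.  Rows must sum to 1 (tolerance 1e-6).
    """
    q = np.asarray(q_row, dtype=float)
    if abs(q.sum() - 1.0) > _ROW_TOL:
        raise ValueError(f"membership row sums to {q.sum():.6f}, not 1")
    if labels is None:
        labels = [f"cluster{i + 1}" for i in range(len(q))]
    hits = np.nonzero(q >= t_q)[0]
    if len(hits) == 0:
        return ADMIXED
    if len(hits) > 1:
        warnings.warn(
            f"tie at threshold {t_q}: clusters {hits.tolist()}; keeping the lowest index",
            stacklevel=2,
        )
    return labels[hits[0]]


def assign_all(q_matrix: pd.DataFrame, t_q: float = 0.5) -> pd.Series:
    """Assignment for every row of a Q-matrix (columns = clusters)."""
    labels = [
        c if isinstance(c, str) else f"cluster{int(c) + 1}" for c in q_matrix.columns
    ]
    return pd.Series(
        [assign_cluster(row, t_q=t_q, labels=labels) for row in q_matrix.to_numpy()],
        index=q_matrix.index,
        name="cluster",
    )


def admixed_proportion(q_matrix: pd.DataFrame, groups, t_q: float = 0.5) -> pd.Series:
    """Fraction of individuals assigned 'admixed', per group.

    Empty groups yield NaN (flagged via a warning).
    """
    assignments = assign_all(q_matrix, t_q=t_q)
    groups = pd.Series(list(groups), index=q_matrix.index, name="group")
    out = {}
    for g, idx in groups.groupby(groups).groups.items():
        sub = assignments.loc[idx]
        out[g] = float((sub == ADMIXED).mean()) if len(sub) else np.nan
    result = pd.Series(out, name="admixed_proportion")
    if result.isna().any():
        warnings.warn("some groups are empty; their admixed proportion is undefined")
    return result


def read_qmatrix(path) -> pd.DataFrame:
    """Whitespace-delimited membership matrix, one row per individual."""
    q = pd.read_csv(path, sep=r"\s+", header=None)
    q.columns = [f"cluster{i + 1}" for i in range(q.shape[1])]
    return q


def allele_frequency_with_ci(
    alt_count: int, n_alleles: int, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Allele frequency with a Wilson score interval.

    ``n_alleles`` is the number of allele copies (2n for n diploids).
    """
    if n_alleles <= 0:
        raise ValueError("n_alleles must be positive")
    return wilson_ci(alt_count, n_alleles, confidence=confidence)


def human_blood_index(
    table: pd.DataFrame, group_col: str = "group", human_col: str = "human"
) -> tuple[pd.Series, pd.DataFrame]:
    """HBI per group plus the human/non-human x group contingency table.

    ``table`` has one row per scored blood meal with a boolean human-positivity
    flag; mixed meals (human plus another host) count as human-positive, since
    the HBI measures proportionate feeding on humans.
    """
    if table.empty:
        raise ValueError("no scored blood meals")
    human = table[human_col].astype(bool)
    groups = table[group_col]
    hbi = human.groupby(groups).mean().rename("HBI")
    contingency = pd.DataFrame(
        {
            "human": human.groupby(groups).sum(),
            "non_human": (~human).groupby(groups).sum(),
        }
    ).T
    return hbi, contingency
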