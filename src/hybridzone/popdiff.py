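"""Weir-Cockerham per-site FST, 50-kb windowed means, and region enrichment.

The per-site estimator is the 1984 variance-components form for two
populations of diploids: a (among-population), b (among-individual within
population) and c (within-individual) components, with FST = a/(a+b+c).
Sites monomorphic in the pooled sample have a+b+c = 0 and an undefined FST.

Windows tile each arm from coordinate 0 in non-overlapping spans; the window
summary is the arithmetic mean of defined per-site estimates ("mean FST"),
with the weighted ratio-of-sums also reported for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ChiSquareResult, pearson_chi_square

__all__ = [
    "SiteFstComponents",
    "FstWindow",
    "weir_cockerham_site_fst",
    "windowed_mean_fst",
    "top_fraction_threshold",
    "region_enrichment",
    "EnrichmentResult",
]


@dataclass
class SiteFstComponents:
    chrom: str
    pos: int  # 1-based
    a: float
    b: float
    c: float

    @property
    def fst(self) -> float | None:
        denom = self.a + self.b + self.c
        if denom == 0:
            return None
        # the ratio is bounded by 1; guard against floating-point excess
        return min(1.0, self.a / denom)


def _clean(dosages) -> np.ndarray:
    arr = np.asarray(
        [d for d in dosages if d is not None and not (isinstance(d, float) and math.isnan(d))],
        dtype=float,
    )
    return arr


def weir_cockerham_site_fst(
    genotypes_pop1, genotypes_pop2, chrom: str = "", pos: int = 1
) -> SiteFstComponents:
    """Variance components for one biallelic site between two diploid samples.

    Inputs are alt-allele dosage vectors (0/1/2; None/NaN = missing).  Each
    population must contribute at least two called genotypes.
    """
    pops = [_clean(genotypes_pop1), _clean(genotypes_pop2)]
    for k, g in enumerate(pops, start=1):
        if len(g) < 2:
            raise ValueError(f"population {k} has fewer than 2 called genotypes")
    r = 2
    n_i = np.array([len(g) for g in pops], dtype=float)
    p_i = np.array([g.mean() / 2.0 for g in pops])
    h_i = np.array([np.mean(g == 1) for g in pops])  # observed heterozygote proportion
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return SiteFstComponents(chrom=chrom, pos=pos, a=a, b=b, c=c)


@dataclass
class FstWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_sites: int
    mean_fst: float | None
    weighted_fst: float | None  # sum(a) / sum(a+b+c) over defined sites


def windowed_mean_fst(
    site_fsts: list[SiteFstComponents],
    window_size: int = 50_000,
    arm_lengths: dict[str, int] | None = None,
) -> list[FstWindow]:
    """Mean FST in non-overlapping windows tiling each arm from 0.

    Sites must be sorted by (chrom, pos); 1-based positions are assigned to
    windows by their 0-based coordinate (pos - 1).  With ``arm_lengths`` the
    full arm is tiled and empty windows are reported with n_sites = 0;
    otherwise tiling stops at the last observed site.
    """
    order_seen: list[str] = []
    by_chrom: dict[str, list[SiteFstComponents]] = {}
    last: tuple[str, int] | None = None
    for s in site_fsts:
        if s.chrom not in by_chrom:
            order_seen.append(s.chrom)
            by_chrom[s.chrom] = []
        elif order_seen[-1] != s.chrom:
            raise ValueError("sites are not sorted by (chrom, pos)")
        if last is not None and last[0] == s.chrom and s.pos < last[1]:
            raise ValueError("sites are not sorted by (chrom, pos)")
        by_chrom[s.chrom].append(s)
        last = (s.chrom, s.pos)
    chroms = list(arm_lengths) if arm_lengths else order_seen
    windows: list[FstWindow] = []
    for chrom in chroms:
        sites = by_chrom.get(chrom, [])
        if arm_lengths:
            length = arm_lengths[chrom]
        elif sites:
            length = sites[-1].pos  # pos is 1-based; last 0-based coord is pos-1
        else:
            continue
        n_windows = max(1, math.ceil(length / window_size))
        sums = np.zeros(n_windows)
        counts = np.zeros(n_windows, dtype=int)
        num = np.zeros(n_windows)
        den = np.zeros(n_windows)
        for s in sites:
            fst = s.fst
            if fst is None:
                continue
            w = (s.pos - 1) // window_size
            sums[w] += fst
            counts[w] += 1
            num[w] += s.a
            den[w] += s.a + s.b + s.c
        for w in range(n_windows):
            start = w * window_size
            end = min(length, start + window_size)
            windows.append(
                FstWindow(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_sites=int(counts[w]),
                    mean_fst=sums[w] / counts[w] if counts[w] else None,
                    weighted_fst=num[w] / den[w] if counts[w] and den[w] != 0 else None,
                )
            )
    return windows


def top_fraction_threshold(values, q: float = 0.05) -> float:
    """Smallest observed value v with frac(values >= v) <= q.

    When no observed value satisfies the bound (ties at the maximum), the
    maximum is returned and the top set includes all its ties, so the realized
    fraction may exceed q.
    """
    vals = np.asarray([v for v in values if v is not None and not math.isnan(v)], dtype=float)
    if len(vals) == 0:
        raise ValueError("no defined values")
    distinct = np.unique(vals)  # ascending
    n = len(vals)
    vals_sorted = np.sort(vals)
    fracs = (n - np.searchsorted(vals_sorted, distinct, side="left")) / n
    ok = np.nonzero(fracs <= q)[0]
    if len(ok):
        return float(distinct[ok[0]])
    return float(distinct[-1])


@dataclass
class EnrichmentResult:
    proportion_top_inside: float
    chi_square: float
    df: int
    p_value: float
    table: np.ndarray  # [[top_in, top_out], [rest_in, rest_out]]
    threshold: float


def _inside(midpoints: np.ndarray, chroms: np.ndarray, regions: pd.DataFrame, label: str):
    sel = regions[regions["label"] == label]
    inside = np.zeros(len(midpoints), dtype=bool)
    for _, row in sel.iterrows():
        inside |= (chroms == row["chrom"]) & (midpoints >= row["start"]) & (midpoints < row["end"])
    return inside


def region_enrichment(
    windows: list[FstWindow], regions: pd.DataFrame, label: str, q: float = 0.05
) -> EnrichmentResult:
    """Enrichment of top-q FST windows inside the labelled regions.

    ``regions`` is BED-like (columns chrom, start, end, label; 0-based
    half-open).  A window is inside if its midpoint lies in a labelled
    interval.  The chi-square is Pearson's on the 2x2 top/not-top x
    inside/outside table, without continuity correction.
    """
    defined = [w for w in windows if w.mean_fst is not None]
    if not defined:
        raise ValueError("no windows with defined mean FST")
    means = np.array([w.mean_fst for w in defined])
    thr = top_fraction_threshold(means, q=q)
    top = means >= thr
    if top.sum() == 0:
        raise ValueError("zero top windows")
    midpoints = np.array([(w.start + w.end) // 2 for w in defined])
    chroms = np.array([w.chrom for w in defined])
    inside = _inside(midpoints, chroms, regions, label)
    if not inside.any():
        raise ValueError(f"regions labelled {label!r} cover no window")
    table = np.array(
        [
            [int((top & inside).sum()), int((top & ~inside).sum())],
            [int((~top & inside).sum()), int((~top & ~inside).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # degenerate margin (e.g. every window inside the regions): no
        # association is testable; report a zero statistic
        res = ChiSquareResult(statistic=0.0, df=1, p_value=1.0)
    else:
        res = pearson_chi_square(table)
    return EnrichmentResult(
        proportion_top_inside=float(table[0, 0] / top.sum()),
        chi_square=res.statistic,
        df=res.df,
        p_value=res.p_value,
        table=table,
        threshold=thr,
    )
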