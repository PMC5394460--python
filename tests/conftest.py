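"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately separate transcriptions of
the published formulas (brute-force or closed-form), kept independent of the
library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from hybridzone.genome import build_default_genome_map
from hybridzone.variant_filter import SampleCall, VariantSite


@pytest.fixture(scope="session")
def gmap():
    return build_default_genome_map()


def make_site(
    chrom="2R",
    pos=100,
    mq=60.0,
    qd=20.0,
    hrun=0,
    calls=None,
):
    """A VariantSite with clean annotations unless overridden."""
    if calls is None:
        calls = {"s1": (0, 30, 99), "s2": (1, 30, 99)}
    return VariantSite(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="T",
        mq=mq,
        qd=qd,
        hrun=hrun,
        calls={k: SampleCall(gt=g, dp=d, gq=q) for k, (g, d, q) in calls.items()},
    )


# ---------------------------------------------------------------------------
# Independent oracles


def wc_fst_oracle(pop1, pop2):
    """Direct transcription of the 1984 two-level variance components.

    Returns (a, b, c).  Structured as explicit per-population loops rather
    than vectorised moments, so it shares no code with the implementation.
    """
    samples = [[g for g in pop if g is not None and not math.isnan(g)] for pop in (pop1, pop2)]
    r = 2
    n = [len(s) for s in samples]
    p = [sum(s) / (2 * len(s)) for s in samples]
    h = [sum(1 for g in s if g == 1) / len(s) for s in samples]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni * ni for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    ssq = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
    a = (nbar / nc) * (
        ssq - (pbar * (1 - pbar) - (r - 1) / r * ssq - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * ssq - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def brute_force_ld_prune(dosages, r2_max):
    """Keep-first pruning that re-scans all pairs after every removal.

    Valid as an oracle when a single window covers all loci.
    """
    dosages = np.asarray(dosages, dtype=float)
    retained = list(range(dosages.shape[1]))
    changed = True
    while changed:
        changed = False
        for ai in range(len(retained)):
            for bi in range(ai + 1, len(retained)):
                x = dosages[:, retained[ai]]
                y = dosages[:, retained[bi]]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                if r * r > r2_max:
                    del retained[bi]
                    changed = True
                    break
            if changed:
                break
    return retained


def brute_force_tract(scores, positions, max_het, target=1.0):
    """Exhaustive enumeration over all (start, end) AIM pairs.

    Returns (start_index, end_index, span) of the leftmost maximal-span run,
    or (-1, -1, 0) when no qualifying AIM exists.
    """
    n = len(scores)
    best = (-1, -1, -1)
    for i in range(n):
        if scores[i] != target:
            continue
        for j in range(i, n):
            if scores[j] != target:
                continue
            inner = scores[i : j + 1]
            if any(s != target and s != 0.5 for s in inner):
                continue
            if sum(1 for s in inner if s == 0.5) > max_het:
                continue
            span = positions[j] - positions[i]
            if span > best[2]:
                best = (i, j, span)
    return best if best[2] >= 0 else (-1, -1, 0)


def brute_force_top_set(values, q):
    """Enumerate every observed cut point; smallest value whose upper set has
    fraction <= q, falling back to the maximum (ties included)."""
    n = len(values)
    candidates = sorted(set(values))
    for v in candidates:
        if sum(1 for x in values if x >= v) / n <= q:
            return {x for x in values if x >= v}, v
    v = candidates[-1]
    return {x for x in values if x >= v}, v


def pearson_chi2_oracle(table):
    """Sum (O-E)^2/E with margin-product expectations, written longhand."""
    table = [list(map(float, row)) for row in table]
    total = sum(sum(row) for row in table)
    rowsums = [sum(row) for row in table]
    colsums = [sum(row[j] for row in table) for j in range(len(table[0]))]
    stat = 0.0
    for i, row in enumerate(table):
        for j, obs in enumerate(row):
            exp = rowsums[i] * colsums[j] / total
            stat += (obs - exp) ** 2 / exp
    return stat


def fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = hyper(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(hyper(k) for k in range(lo, hi + 1) if hyper(k) <= p_obs * (1 + 1e-9))


def wilson_oracle(x, n, z=1.959963984540054):
    """Closed-form Wilson score interval."""
    p = x / n
    centre = (p + z * z / (2 * n)) / (1 + z * z / n)
    half = (z / (1 + z * z / n)) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return centre - half, centre + half
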