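"""Ancestry-informative markers: selection, tri-state scoring, composition,
and long homozygous-ancestry tracts.

An AIM is a SNP whose allele frequencies differ by strictly more than a
threshold (default 0.9) between the two reference panels.  Each individual is
scored per AIM as 1 (homozygous for the speciesA-diagnostic allele), 0.5
(heterozygous), 0 (homozygous speciesB), or missing when the observed alleles
match neither diagnostic allele.  Composition summarises these classes
separately for the autosomes and chromosome X; tract detection finds the
longest genomic stretch of homozygous target-ancestry AIMs, optionally
tolerating a bounded number of heterozygous AIMs inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dimred import GenotypeMatrix
from .genome import X_ARM

__all__ = [
    "AimDefinition",
    "AncestryTract",
    "select_aims",
    "score_genotypes",
    "score_allele_pair",
    "ancestry_composition",
    "longest_homozygous_tract",
]

CLASSES = ("speciesA_hom", "het", "speciesB_hom")


@dataclass(frozen=True)
class AimDefinition:
    """A diagnostic marker: which allele marks which species, and how cleanly."""

    chrom: str
    pos: int  # 0-based, matching the locus tables
    allele_a: str  # diagnostic of the introgressing species (panel A)
    allele_b: str
    delta: float

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"


def select_aims(freq_a: pd.DataFrame, freq_b: pd.DataFrame, min_diff: float = 0.9) -> list[AimDefinition]:
    """Loci with panel frequency difference strictly above ``min_diff``.

    Tables need columns (chrom, pos, ref, alt, freq) with identical loci;
    ``freq`` is the alt-allele frequency.  ``allele_a`` is whichever allele is
    more frequent in panel A.
    """
    if not freq_a[["chrom", "pos"]].equals(freq_b[["chrom", "pos"]]):
        raise ValueError("panel tables must share loci in the same order")
    fa = freq_a["freq"].to_numpy()
    fb = freq_b["freq"].to_numpy()
    delta = np.abs(fa - fb)
    aims = []
    for i in np.nonzero(delta > min_diff)[0]:
        row = freq_a.iloc[i]
        a_has_alt = fa[i] > fb[i]
        aims.append(
            AimDefinition(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                allele_a=str(row["alt"] if a_has_alt else row["ref"]),
                allele_b=str(row["ref"] if a_has_alt else row["alt"]),
                delta=float(delta[i]),
            )
        )
    aims.sort(key=lambda m: (m.chrom, m.pos))
    return aims


def score_allele_pair(allele1: str, allele2: str, aim: AimDefinition) -> float | None:
    """Tri-state score of one genotype; None when an allele is non-diagnostic."""
    diagnostic = {aim.allele_a, aim.allele_b}
    if allele1 not in diagnostic or allele2 not in diagnostic:
        return None
    return ((allele1 == aim.allele_a) + (allele2 == aim.allele_a)) / 2.0


def score_genotypes(gm: GenotypeMatrix, aims: list[AimDefinition]) -> pd.DataFrame:
    """Individuals x AIMs score matrix with values in {0, 0.5, 1} (NaN = missing).

    Dosages are alt-allele counts; the score is the fraction of the
    individual's two alleles that are speciesA-diagnostic.
    """
    locus_index = {
        (c, p): i for i, (c, p) in enumerate(zip(gm.loci["chrom"], gm.loci["pos"]))
    }
    cols = []
    data = np.full((gm.n_samples, len(aims)), np.nan)
    for j, aim in enumerate(aims):
        key = (aim.chrom, aim.pos)
        if key not in locus_index:
            raise KeyError(f"genotypes do not cover AIM {aim.key}")
        i = locus_index[key]
        d = gm.dosages[:, i].astype(float)
        d = np.where(d < 0, np.nan, d)
        # dosage counts alt alleles; flip when the diagnostic allele is ref
        score = (1.0 - d / 2.0) if _aim_uses_ref(gm, aim) else d / 2.0
        cols.append(aim.key)
        data[:, j] = score
    return pd.DataFrame(data, index=pd.Index(gm.samples, name="individual"), columns=cols)


def _aim_uses_ref(gm: GenotypeMatrix, aim: AimDefinition) -> bool:
    if "ref" in gm.loci.columns:
        row = gm.loci[(gm.loci["chrom"] == aim.chrom) & (gm.loci["pos"] == aim.pos)].iloc[0]
        return aim.allele_a == str(row["ref"])
    # simulator convention: ref="A", alt="T"
    return aim.allele_a == "A"


def default_grouping(aims: list[AimDefinition]) -> dict[str, str]:
    """AIM key -> 'X' or 'autosomal'."""
    return {m.key: ("X" if m.chrom == X_ARM else "autosomal") for m in aims}


def ancestry_composition(
    scores: pd.DataFrame, grouping: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual and per-group class proportions over non-missing scores.

    Returns (per-individual frame with MultiIndex columns (group, class) plus
    (group, 'n_scored'), per-group aggregate pooling all scored AIMs).
    Groups with zero non-missing AIMs get NaN proportions.
    """
    missing = set(scores.columns) - set(grouping)
    if missing:
        raise ValueError(f"AIMs without a group assignment: {sorted(missing)[:3]}...")
    groups = sorted(set(grouping[c] for c in scores.columns))
    per_ind = {}
    pooled = {g: np.zeros(3) for g in groups}
    for g in groups:
        cols = [c for c in scores.columns if grouping[c] == g]
        sub = scores[cols]
        n_scored = sub.notna().sum(axis=1)
        counts = {
            "speciesA_hom": (sub == 1.0).sum(axis=1),
            "het": (sub == 0.5).sum(axis=1),
            "speciesB_hom": (sub == 0.0).sum(axis=1),
        }
        for k, cls in enumerate(CLASSES):
            pooled[g][k] = counts[cls].sum()
            per_ind[(g, cls)] = counts[cls] / n_scored.replace(0, np.nan)
        per_ind[(g, "n_scored")] = n_scored.astype(float)
    frame = pd.DataFrame(per_ind)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["group", "class"])
    agg = pd.DataFrame(
        {g: pooled[g] / pooled[g].sum() if pooled[g].sum() else [np.nan] * 3 for g in groups},
        index=list(CLASSES),
    ).T
    agg["n_scored"] = [pooled[g].sum() for g in groups]
    return frame, agg


@dataclass
class AncestryTract:
    """A maximal run of homozygous target-ancestry AIMs."""

    chrom: str
    start_index: int  # AIM indices, inclusive; -1/-1 for an empty tract
    end_index: int
    start_pos: int
    end_pos: int
    span_bp: int
    n_aims: int
    n_het_inside: int


_EMPTY = dict(start_index=-1, end_index=-1, start_pos=0, end_pos=0, span_bp=0, n_aims=0, n_het_inside=0)


def longest_homozygous_tract(
    scores,
    positions,
    max_het: int = 0,
    target_score: float = 1.0,
    chrom: str = "",
) -> AncestryTract:
    """Longest genomic span of AIMs at ``target_score`` with <= ``max_het``
    heterozygous AIMs inside and no opposite-homozygote or missing AIM.

    Runs begin and end on a target-homozygous AIM; the span is the distance
    between the first and last AIM positions.  Ties break to the leftmost
    start.  Returns a zero-length tract when no qualifying AIM exists.
    """
    scores = np.asarray(scores, dtype=float)
    positions = np.asarray(positions)
    if len(scores) != len(positions):
        raise ValueError("scores and positions differ in length")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    best = AncestryTract(chrom=chrom, **_EMPTY)
    n = len(scores)
    is_target = scores == target_score
    is_het = scores == 0.5
    blocking = ~(is_target | is_het)  # opposite homozygote or missing
    i = 0
    while i < n:
        if not is_target[i]:
            i += 1
            continue
        hets = 0
        last_target = i
        hets_at_last = 0
        j = i
        while j < n and not blocking[j] and hets + is_het[j] <= max_het:
            hets += is_het[j]
            if is_target[j]:
                last_target = j
                hets_at_last = hets
            j += 1
        span = int(positions[last_target] - positions[i])
        n_aims = last_target - i + 1
        if span > best.span_bp or (span == best.span_bp and best.start_index == -1):
            best = AncestryTract(
                chrom=chrom,
                start_index=i,
                end_index=last_target,
                start_pos=int(positions[i]),
                end_pos=int(positions[last_target]),
                span_bp=span,
                n_aims=n_aims,
                n_het_inside=int(hets_at_last),
            )
        i += 1
    return best
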