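"""Synthetic two-species cohorts with asymmetric autosomal introgression.

The generator emulates the statistical structure the downstream analyses
assume: two parental panels (speciesA, the introgressing donor; speciesB, the
resident species) with near-fixed allele-frequency differences concentrated
in pericentromeric islands of divergence, admixed diploid individuals whose
haplotypes are mosaics of ancestry blocks with separately specified autosomal
and X ancestry proportions, per-site/per-call annotations for filter testing,
and Hardy-Weinberg karyotype samples for the inversion statistics.

Everything is a pure function of the configuration, whose ``seed`` fully
determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .dimred import GenotypeMatrix
from .genome import GenomeMap, X_ARM, build_default_genome_map
from .variant_filter import SampleCall, VariantSite

__all__ = [
    "SPECIES_A",
    "SPECIES_B",
    "SimulationConfig",
    "TruthRecord",
    "build_default_genome_map",
    "simulate_parental_frequencies",
    "simulate_cohort",
    "simulate_karyotype_sample",
    "default_annotation_model",
]

SPECIES_A = "speciesA"
SPECIES_B = "speciesB"

REF_ALLELE = "A"
ALT_ALLELE = "T"


def default_annotation_model() -> dict[str, tuple]:
    """Plausible annotation distributions; every entry is (dist, *params).

    Supported dists: constant(v), poisson(mean), normal(mean, sd),
    normal_clipped(mean, sd, lo, hi), gamma(shape, scale), geometric(p)
    (geometric counts failures, so values start at 0).
    """
    return {
        "dp": ("poisson", 30),
        "gq": ("normal_clipped", 60, 15, 0, 99),
        "mq": ("normal", 50, 5),
        "qd": ("gamma", 4.0, 5.0),
        "hrun": ("geometric", 0.7),
    }


def clean_annotation_model() -> dict[str, tuple]:
    """Degenerate model with every annotation safely above all filter thresholds."""
    return {
        "dp": ("constant", 30),
        "gq": ("constant", 99),
        "mq": ("constant", 60),
        "qd": ("constant", 20),
        "hrun": ("constant", 0),
    }


def _draw(model: tuple, size, rng: np.random.Generator) -> np.ndarray:
    dist, *params = model
    if dist == "constant":
        return np.full(size, params[0], dtype=float)
    if dist == "poisson":
        return rng.poisson(params[0], size).astype(float)
    if dist == "normal":
        return rng.normal(params[0], params[1], size)
    if dist == "normal_clipped":
        mean, sd, lo, hi = params
        return np.clip(np.round(rng.normal(mean, sd, size)), lo, hi)
    if dist == "gamma":
        return rng.gamma(params[0], params[1], size)
    if dist == "geometric":
        return (rng.geometric(params[0], size) - 1).astype(float)
    raise ValueError(f"unknown annotation distribution {dist!r}")


@dataclass
class SimulationConfig:
    """Generator parameters.

    ``island_divergence`` are Beta shapes (a, b) for the speciesA panel at
    island loci; the speciesB panel uses the reflected Beta(b, a), so island
    frequency differences concentrate near fixation.  ``background_divergence``
    are Beta shapes for a single frequency shared exactly by both panels.
    ``alpha_autosome``/``alpha_x`` are the true speciesA (introgressed)
    ancestry fractions; ``block_length_bp`` is the mean ancestry block length
    of the alternating-exponential block process.
    """

    n_per_population: int = 25
    n_loci_per_arm: int = 200
    island_locus_fraction: float = 0.25
    # a bare float v means point masses fA = v, fB = 1 - v (fully fixed
    # interspecific differences when v = 1)
    island_divergence: tuple[float, float] | float = (50.0, 1.0)
    background_divergence: tuple[float, float] | float = (2.0, 2.0)
    alpha_autosome: float = 0.7
    alpha_x: float = 0.1
    block_length_bp: float = 5_000_000.0
    forced_island_ancestry: dict[str, str] | None = None
    annotation_model: dict[str, tuple] = field(default_factory=default_annotation_model)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_autosome", "alpha_x"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.block_length_bp <= 0:
            raise ValueError("block_length_bp must be positive")
        if not 0.0 <= self.island_locus_fraction <= 1.0:
            raise ValueError("island_locus_fraction must lie in [0, 1]")
        if self.n_per_population < 1 or self.n_loci_per_arm < 1:
            raise ValueError("cohort and locus counts must be positive")


@dataclass
class TruthRecord:
    """True ancestry mosaic for one individual.

    ``intervals[arm]`` is a pair (haplotype 0, haplotype 1) of lists of
    (start, end, species) tiling the arm without overlap.
    """

    individual: str
    intervals: dict[str, tuple[list[tuple[int, int, str]], list[tuple[int, int, str]]]]

    def dosage_at(self, chrom: str, pos: int) -> int:
        """Number of speciesA haplotypes at a 0-based position."""
        d = 0
        for hap in self.intervals[chrom]:
            for start, end, species in hap:
                if start <= pos < end:
                    d += species == SPECIES_A
                    break
        return d


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def simulate_parental_frequencies(
    gmap: GenomeMap, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus alt-allele frequencies for the two parental panels.

    Returns two frames with identical (chrom, pos, ref, alt) and an ``island``
    flag; ``freq`` is the panel frequency of the alt allele.  Island loci are
    drawn from the reflected Beta pair, background loci share one draw.
    """
    rng = _rng(config, 1)
    rows_a, rows_b = [], []
    for arm, length in gmap.arms:
        if length <= 0:
            raise ValueError(f"empty arm {arm}")
        islands = gmap.islands_on(arm)
        n = config.n_loci_per_arm
        n_isl = int(round(n * config.island_locus_fraction)) if islands else 0
        pos = set()
        if n_isl:
            span = islands[0]
            pos.update(rng.integers(span.start, span.end, n_isl).tolist())
        while len(pos) < n:
            p = int(rng.integers(0, length))
            if any(s.start <= p < s.end for s in islands) and len(pos) >= n_isl:
                continue
            pos.add(p)
        positions = np.array(sorted(pos))
        in_island = np.zeros(len(positions), dtype=bool)
        for s in islands:
            in_island |= (positions >= s.start) & (positions < s.end)
        fa = np.empty(len(positions))
        fb = np.empty(len(positions))
        k = int(in_island.sum())
        isl = config.island_divergence
        if isinstance(isl, (int, float)):
            fa[in_island] = float(isl)
            fb[in_island] = 1.0 - float(isl)
        else:
            fa[in_island] = rng.beta(isl[0], isl[1], k)
            fb[in_island] = rng.beta(isl[1], isl[0], k)
        bg = config.background_divergence
        if isinstance(bg, (int, float)):  # point mass: both panels share exactly this value
            shared = np.full(len(positions) - k, float(bg))
        else:
            shared = rng.beta(*bg, len(positions) - k)
        fa[~in_island] = shared
        fb[~in_island] = shared
        for f, rows in ((fa, rows_a), (fb, rows_b)):
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": arm,
                        "pos": positions,
                        "ref": REF_ALLELE,
                        "alt": ALT_ALLELE,
                        "island": in_island,
                        "freq": f,
                    }
                )
            )
    freq_a = pd.concat(rows_a, ignore_index=True)
    freq_b = pd.concat(rows_b, ignore_index=True)
    return freq_a, freq_b


def _sample_haplotype_blocks(
    length: int, alpha: float, mean_block: float, rng: np.random.Generator
) -> list[tuple[int, int, str]]:
    """Alternating-exponential ancestry mosaic with stationary speciesA fraction alpha."""
    if alpha <= 0.0:
        return [(0, length, SPECIES_B)]
    if alpha >= 1.0:
        return [(0, length, SPECIES_A)]
    means = {SPECIES_A: 2 * mean_block * alpha, SPECIES_B: 2 * mean_block * (1 - alpha)}
    state = SPECIES_A if rng.random() < alpha else SPECIES_B
    blocks: list[tuple[int, int, str]] = []
    pos = 0
    while pos < length:
        size = max(1, int(rng.exponential(means[state])))
        end = min(length, pos + size)
        blocks.append((pos, end, state))
        pos = end
        state = SPECIES_B if state == SPECIES_A else SPECIES_A
    return blocks


def _force_interval(
    blocks: list[tuple[int, int, str]], start: int, end: int, species: str
) -> list[tuple[int, int, str]]:
    """Overwrite [start, end) with the given ancestry, keeping an exact tiling."""
    out: list[tuple[int, int, str]] = []
    for b_start, b_end, b_sp in blocks:
        if b_end <= start or b_start >= end:
            out.append((b_start, b_end, b_sp))
            continue
        if b_start < start:
            out.append((b_start, start, b_sp))
        if b_end > end:
            out.append((end, b_end, b_sp))
    out.append((start, end, species))
    out.sort()
    merged: list[tuple[int, int, str]] = []
    for blk in out:
        if merged and merged[-1][2] == blk[2] and merged[-1][1] == blk[0]:
            merged[-1] = (merged[-1][0], blk[1], blk[2])
        else:
            merged.append(blk)
    return merged


def simulate_cohort(
    config: SimulationConfig,
    freq_a: pd.DataFrame,
    freq_b: pd.DataFrame,
    gmap: GenomeMap,
    sample_prefix: str = "ind",
) -> tuple[GenotypeMatrix, list[TruthRecord], list[VariantSite]]:
    """Diploid cohort of ``n_per_population`` individuals.

    Each haplotype is an ancestry-block mosaic (speciesA fraction
    ``alpha_autosome`` on autosomes, ``alpha_x`` on X); alleles are drawn from
    the ancestry-matched panel frequency at each locus; per-site and per-call
    annotations come from ``annotation_model``.  Returns the dosage matrix,
    per-individual truth, and annotated variant records.
    """
    if not freq_a[["chrom", "pos"]].equals(freq_b[["chrom", "pos"]]):
        raise ValueError("panel frequency tables must share loci")
    map_arms = set(gmap.arm_lengths)
    if not set(freq_a["chrom"]).issubset(map_arms):
        raise ValueError("frequency tables reference arms missing from the map")
    rng = _rng(config, 2)
    n = config.n_per_population
    samples = [f"{sample_prefix}{i:03d}" for i in range(n)]
    loci = freq_a[["chrom", "pos"]].reset_index(drop=True)
    fa = freq_a["freq"].to_numpy()
    fb = freq_b["freq"].to_numpy()
    arm_positions = {
        arm: loci.loc[loci["chrom"] == arm, "pos"].to_numpy() for arm in gmap.arm_lengths
    }
    arm_index = {
        arm: np.nonzero((loci["chrom"] == arm).to_numpy())[0] for arm in gmap.arm_lengths
    }
    forced = config.forced_island_ancestry or {}

    dosage = np.zeros((n, len(loci)), dtype=np.int64)
    truths: list[TruthRecord] = []
    for i, sample in enumerate(samples):
        intervals: dict[str, tuple[list, list]] = {}
        for arm, length in gmap.arms:
            alpha = config.alpha_x if arm == X_ARM else config.alpha_autosome
            haps = []
            for _ in range(2):
                blocks = _sample_haplotype_blocks(length, alpha, config.block_length_bp, rng)
                if arm in forced:
                    for span in gmap.islands_on(arm):
                        blocks = _force_interval(blocks, span.start, span.end, forced[arm])
                haps.append(blocks)
            intervals[arm] = (haps[0], haps[1])
            positions = arm_positions[arm]
            idx = arm_index[arm]
            if len(positions) == 0:
                continue
            for blocks in haps:
                anc = np.empty(len(positions), dtype=bool)  # True = speciesA
                for start, end, species in blocks:
                    mask = (positions >= start) & (positions < end)
                    anc[mask] = species == SPECIES_A
                p = np.where(anc, fa[idx], fb[idx])
                dosage[i, idx] += rng.random(len(p)) < p
        truths.append(TruthRecord(individual=sample, intervals=intervals))

    model = config.annotation_model
    m = len(loci)
    mq = _draw(model["mq"], m, rng)
    qd = np.maximum(_draw(model["qd"], m, rng), 0.0)
    hrun = np.maximum(_draw(model["hrun"], m, rng), 0).astype(int)
    dp = np.maximum(_draw(model["dp"], (m, n), rng), 0).astype(int)
    gq = np.maximum(_draw(model["gq"], (m, n), rng), 0).astype(int)
    sites: list[VariantSite] = []
    for j in range(m):
        calls = {
            samples[i]: SampleCall(gt=int(dosage[i, j]), dp=int(dp[j, i]), gq=int(gq[j, i]))
            for i in range(n)
        }
        sites.append(
            VariantSite(
                chrom=str(loci.at[j, "chrom"]),
                pos=int(loci.at[j, "pos"]) + 1,  # VCF is 1-based
                ref=REF_ALLELE,
                alt=ALT_ALLELE,
                mq=float(mq[j]),
                qd=float(qd[j]),
                hrun=int(hrun[j]),
                calls=calls,
            )
        )
    gm = GenotypeMatrix(dosages=dosage, samples=samples, loci=loci)
    return gm, truths, sites


# ---------------------------------------------------------------------------
# Karyotypes

_2R_LETTERS = ("j", "b", "d")
_2L_LETTERS = ("a",)


def _compose_label(letters: Iterable[str], genotypes: dict[str, int], rng) -> str:
    haps: tuple[list[str], list[str]] = ([], [])
    for letter in letters:
        g = genotypes.get(letter, 0)
        if g == 2:
            haps[0].append(letter)
            haps[1].append(letter)
        elif g == 1:
            haps[rng.integers(0, 2)].append(letter)
    return "/".join("".join(h) if h else "+" for h in haps)


def simulate_karyotype_sample(
    inversion_freqs: dict[str, float], n: int, seed: int
) -> list[tuple[str, str]]:
    """Draw ``n`` (2R label, 2L label) karyotypes under Hardy-Weinberg.

    ``inversion_freqs`` maps inversion letters (j, b, d on 2R; a on 2L) to
    inverted-arrangement frequencies; missing letters default to 0.  Each
    inversion segregates independently; labels use '+' for the all-standard
    arrangement and round-trip through the karyotype parser.
    """
    for letter, f in inversion_freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency for {letter!r} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    labels = []
    for _ in range(n):
        genotypes = {
            letter: int(rng.binomial(2, inversion_freqs.get(letter, 0.0)))
            for letter in (*_2R_LETTERS, *_2L_LETTERS)
        }
        label_2r = _compose_label(_2R_LETTERS, genotypes, rng)
        label_2l = _compose_label(_2L_LETTERS, genotypes, rng)
        labels.append((label_2r, label_2l))
    return labels
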