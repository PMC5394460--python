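"""Hard filtering of called variants.

The filter mirrors a conservative genotype-aware scheme: site-level
annotation rules (mapping quality, quality-by-depth, homopolymer run) reject
whole variants, while genotype-level rules (genotype quality, absolute depth,
and depth relative to each sample's own median) mask individual genotypes.
A final "missingless" reduction keeps only sites called in every sample.

All comparisons are strict: a call with GQ exactly at the minimum passes, a
site with HRun exactly at the maximum passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SampleCall",
    "VariantSite",
    "FilterThresholds",
    "sample_depth_medians",
    "apply_hard_filter",
    "drop_incomplete_sites",
]


@dataclass(frozen=True)
class SampleCall:
    """One sample's genotype at one site: alt-allele dosage, depth, quality.

    ``gt`` is 0/1/2 or ``None`` for missing.
    """

    gt: int | None
    dp: int
    gq: int

    def __post_init__(self) -> None:
        if self.dp < 0 or self.gq < 0:
            raise ValueError("DP and GQ must be non-negative")
        if self.gt is not None and self.gt not in (0, 1, 2):
            raise ValueError(f"invalid dosage {self.gt}")


@dataclass
class VariantSite:
    """A biallelic variant with site annotations and per-sample calls."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    mq: float
    qd: float
    hrun: int
    calls: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")


@dataclass(frozen=True)
class FilterThresholds:
    """Rejection thresholds; defaults are the study-grade values."""

    gq_min: int = 40
    dp_min: int = 14
    dp_median_factor: float = 2.0
    mq_min: float = 40.0
    qd_min: float = 5.0
    hrun_max: int = 3

    def __post_init__(self) -> None:
        for name in ("gq_min", "dp_min", "dp_median_factor", "mq_min", "qd_min", "hrun_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# Fixed evaluation order so rejection counts are reproducible.
SITE_RULES = ("MQ", "QD", "HRun")
GENOTYPE_RULES = ("GQ", "DP_min", "DP_median")


def sample_depth_medians(sites: list[VariantSite]) -> dict[str, float]:
    """Median read depth per sample over all its calls.

    Even counts use the midpoint of the two central values.  A sample with no
    calls anywhere raises ``ValueError`` naming it.
    """
    depths: dict[str, list[int]] = {}
    for site in sites:
        for sample, call in site.calls.items():
            depths.setdefault(sample, []).append(call.dp)
    medians = {}
    for sample, dps in depths.items():
        if not dps:
            raise ValueError(f"sample {sample!r} has no calls")
        medians[sample] = float(np.median(dps))
    if not medians:
        raise ValueError("no calls in input")
    return medians


def _failing_site_rule(site: VariantSite, t: FilterThresholds) -> str | None:
    if site.mq < t.mq_min:
        return "MQ"
    if site.qd < t.qd_min:
        return "QD"
    if site.hrun > t.hrun_max:
        return "HRun"
    return None


def _failing_genotype_rule(call: SampleCall, median: float, t: FilterThresholds) -> str | None:
    if call.gq < t.gq_min:
        return "GQ"
    if call.dp < t.dp_min:
        return "DP_min"
    if call.dp < median / t.dp_median_factor or call.dp > median * t.dp_median_factor:
        return "DP_median"
    return None


def apply_hard_filter(
    sites: list[VariantSite],
    medians: dict[str, float],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[VariantSite], dict[str, int]]:
    """Apply the six-rule hard filter; returns (retained sites, rejection counts).

    Site-level rules remove the whole variant (each removed site counted once,
    under the first failing rule in the order MQ, QD, HRun).  Genotype-level
    rules set single genotypes to missing (each masked call counted once under
    GQ, DP_min or DP_median).  Input records are not mutated.
    """
    counts = {rule: 0 for rule in (*GENOTYPE_RULES, *SITE_RULES)}
    retained: list[VariantSite] = []
    for site in sites:
        rule = _failing_site_rule(site, thresholds)
        if rule is not None:
            counts[rule] += 1
            continue
        new_calls = {}
        for sample, call in site.calls.items():
            if sample not in medians:
                raise KeyError(f"no median depth for sample {sample!r}")
            if call.gt is not None:
                g_rule = _failing_genotype_rule(call, medians[sample], thresholds)
                if g_rule is not None:
                    counts[g_rule] += 1
                    call = replace(call, gt=None)
            new_calls[sample] = call
        retained.append(replace_site_calls(site, new_calls))
    return retained, counts


def replace_site_calls(site: VariantSite, calls: dict[str, SampleCall]) -> VariantSite:
    return VariantSite(
        chrom=site.chrom, pos=site.pos, ref=site.ref, alt=site.alt,
        mq=site.mq, qd=site.qd, hrun=site.hrun, calls=calls,
    )


def drop_incomplete_sites(sites: list[VariantSite]) -> list[VariantSite]:
    """Keep only sites with a called genotype in every sample (order preserved)."""
    return [s for s in sites if all(c.gt is not None for c in s.calls.values())]
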