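"""Genome coordinate model for the *Anopheles gambiae* s.l. chromosome arms.

Coordinates are 0-based half-open throughout the library; VCF input/output
converts to 1-based positions at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple


class Span(NamedTuple):
    """A labelled interval on one chromosome arm (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    label: str


@dataclass(frozen=True)
class GenomeMap:
    """Arm lengths plus labelled pericentromeric-island and inversion spans.

    Invariants enforced at construction: positive arm lengths, unique arm
    names, every span inside its arm.
    """

    arms: tuple[tuple[str, int], ...]
    island_spans: tuple[Span, ...] = ()
    inversion_spans: tuple[Span, ...] = ()

    def __post_init__(self) -> None:
        names = [a for a, _ in self.arms]
        if len(set(names)) != len(names):
            raise ValueError("arm names must be unique")
        lengths = dict(self.arms)
        for name, length in self.arms:
            if length <= 0:
                raise ValueError(f"arm {name} has non-positive length")
        for span in (*self.island_spans, *self.inversion_spans):
            if span.chrom not in lengths:
                raise ValueError(f"span {span} references unknown arm")
            if not (0 <= span.start < span.end <= lengths[span.chrom]):
                raise ValueError(f"span {span} lies outside arm {span.chrom}")

    @property
    def arm_lengths(self) -> dict[str, int]:
        return dict(self.arms)

    def islands_on(self, chrom: str) -> list[Span]:
        return [s for s in self.island_spans if s.chrom == chrom]

    def inversion(self, name: str) -> Span:
        for s in self.inversion_spans:
            if s.label == name:
                return s
        raise KeyError(name)


#: Arms are autosomal except the sex chromosome.
X_ARM = "X"

# Arm lengths approximating the AgamP4 reference assembly (rounded to Mb);
# fixed constants so window censuses are realistic without external files.
_ARM_LENGTHS = (
    ("X", 24_000_000),
    ("2R", 61_000_000),
    ("2L", 49_000_000),
    ("3R", 53_000_000),
    ("3L", 42_000_000),
)

# One pericentromeric island of divergence per chromosome.  The centromere of
# the X lies at its distal end; for chromosomes 2 and 3 it sits between the R
# arm end and the L arm start.
_ISLANDS = (
    Span("X", 20_000_000, 24_000_000, "pericentromeric"),
    Span("2R", 59_000_000, 61_000_000, "pericentromeric"),
    Span("2L", 0, 2_000_000, "pericentromeric"),
    Span("3R", 51_000_000, 53_000_000, "pericentromeric"),
    Span("3L", 0, 2_000_000, "pericentromeric"),
)

# The four polymorphic paracentric inversions scored cytologically.
_INVERSIONS = (
    Span("2R", 3_300_000, 15_700_000, "2Rj"),
    Span("2R", 19_000_000, 26_800_000, "2Rb"),
    Span("2R", 31_800_000, 42_300_000, "2Rd"),
    Span("2L", 20_500_000, 42_200_000, "2La"),
)


def build_default_genome_map() -> GenomeMap:
    """Return the fixed five-arm genome map (X, 2R, 2L, 3R, 3L).

    Deterministic: every call returns an identical map.
    """
    return GenomeMap(arms=_ARM_LENGTHS, island_spans=_ISLANDS, inversion_spans=_INVERSIONS)
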