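"""Paracentric-inversion karyotypes as biallelic loci.

Cytological karyotype labels treat each inversion (j, b, d on arm 2R; a on
arm 2L) as a biallelic locus whose alleles are the standard ('+') and
inverted arrangements.  A label like ``"jbd/+, j/bd, jb/d"`` lists
phase-alternative readings of the same genotype: every alternative must
decompose to identical per-inversion genotypes.  The undocumented
arrangement letter 'u' is treated as unscored: loci whose letters appear
nowhere in such a label are counted as unscored for that individual, while
letters that do appear are scored with 'u' acting as standard.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KaryotypeClass",
    "InversionGenotypeCounts",
    "parse_karyotype",
    "decompose_counts",
    "counts_from_percentages",
    "count_karyotype_classes",
]

ARM_LETTERS = {"2R": ("j", "b", "d"), "2L": ("a",)}
UNSCORED = "u"

_ARRANGEMENT_RE = re.compile(r"^(\+|[a-z]+)$")


@dataclass(frozen=True)
class KaryotypeClass:
    """One parsed karyotype: per-inversion genotypes on one arm.

    ``genotypes`` maps each inversion letter of the arm to the inverted-copy
    count 0/1/2, or ``None`` when that locus is unscored for this class.
    """

    arm: str
    label: str
    # excluded from the generated hash (dicts are unhashable); equality still
    # compares the decomposition
    genotypes: dict[str, int | None] = field(hash=False)


def _parse_alternative(alt: str, arm: str, label: str) -> dict[str, int | None]:
    try:
        left, right = alt.split("/")
    except ValueError:
        raise ValueError(f"malformed karyotype label {label!r}: alternative {alt!r}") from None
    letters = ARM_LETTERS[arm]
    haps = []
    for hap in (left.strip(), right.strip()):
        if not _ARRANGEMENT_RE.match(hap):
            raise ValueError(f"malformed karyotype label {label!r}: arrangement {hap!r}")
        if hap != "+" and len(set(hap)) != len(hap):
            raise ValueError(f"label {label!r}: repeated letter within arrangement {hap!r}")
        bad = set(hap) - set(letters) - {"+", UNSCORED}
        if bad:
            raise ValueError(f"label {label!r}: letters {sorted(bad)} not valid on arm {arm}")
        haps.append(hap)
    unscored = any(UNSCORED in h for h in haps)
    present = set("".join(haps)) - {"+", UNSCORED}
    genotypes: dict[str, int | None] = {}
    for letter in letters:
        if unscored and letter not in present:
            genotypes[letter] = None
        else:
            genotypes[letter] = sum(letter in h for h in haps)
    return genotypes


def parse_karyotype(label: str, arm: str) -> KaryotypeClass:
    """Parse a (possibly multi-alternative) karyotype label on the given arm.

    Raises ``ValueError`` for malformed labels or alternatives that disagree
    in their per-inversion decomposition.
    """
    if arm not in ARM_LETTERS:
        raise ValueError(f"unknown arm {arm!r} (expected one of {sorted(ARM_LETTERS)})")
    alternatives = [a.strip() for a in label.split(",") if a.strip()]
    if not alternatives:
        raise ValueError(f"empty karyotype label {label!r}")
    decomposed = [_parse_alternative(a, arm, label) for a in alternatives]
    first = decomposed[0]
    for alt, d in zip(alternatives[1:], decomposed[1:]):
        if d != first:
            raise ValueError(
                f"label {label!r}: alternative {alt!r} decomposes differently ({d} vs {first})"
            )
    return KaryotypeClass(arm=arm, label=label, genotypes=first)


@dataclass
class InversionGenotypeCounts:
    """std/std, std/inv, inv/inv and unscored tallies for one inversion locus."""

    std_std: int = 0
    het: int = 0
    inv_inv: int = 0
    unscored: int = 0

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.std_std, self.het, self.inv_inv)

    @property
    def total_scored(self) -> int:
        return self.std_std + self.het + self.inv_inv


def decompose_counts(
    rows: list[tuple[KaryotypeClass, int]]
) -> dict[str, InversionGenotypeCounts]:
    """Per-inversion genotype tallies from (karyotype class, count) rows.

    All rows must sit on one arm.  Classes with an unscored locus contribute
    to that locus's ``unscored`` tally only.
    """
    if not rows:
        return {}
    arms = {kc.arm for kc, _ in rows}
    if len(arms) != 1:
        raise ValueError(f"rows mix arms {sorted(arms)}")
    arm = arms.pop()
    out = {letter: InversionGenotypeCounts() for letter in ARM_LETTERS[arm]}
    for kc, count in rows:
        for letter, g in kc.genotypes.items():
            tally = out[letter]
            if g is None:
                tally.unscored += count
            elif g == 0:
                tally.std_std += count
            elif g == 1:
                tally.het += count
            else:
                tally.inv_inv += count
    return out


def counts_from_percentages(percentages, total: int) -> np.ndarray:
    """Integer counts from printed percentages of a known total.

    Nearest-integer rounding; if the rounded counts do not sum to ``total``, a
    largest-remainder correction is applied and a warning emitted.
    """
    pct = np.asarray(percentages, dtype=float)
    if (pct < 0).any():
        raise ValueError("percentages must be non-negative")
    if total <= 0:
        raise ValueError("total must be positive")
    exact = pct * total / 100.0
    counts = np.rint(exact).astype(int)
    diff = total - counts.sum()
    if diff != 0:
        warnings.warn(
            f"rounded counts sum to {counts.sum()} != {total}; applying largest-remainder correction",
            stacklevel=2,
        )
        remainders = exact - np.floor(exact)
        order = np.argsort(-remainders if diff > 0 else remainders)
        for i in range(abs(diff)):
            counts[order[i % len(counts)]] += 1 if diff > 0 else -1
    return counts


def count_karyotype_classes(frequencies) -> int:
    """Number of distinct karyotype classes with non-zero frequency."""
    return int(sum(1 for f in frequencies if f > 0))


def column_genotype_counts(
    labels, percentages, total: int, arm: str
) -> dict[str, InversionGenotypeCounts]:
    """Convenience: percentages-of-total for labelled rows -> per-inversion counts."""
    counts = counts_from_percentages(percentages, total)
    rows = [
        (parse_karyotype(label, arm), int(c)) for label, c in zip(labels, counts) if c > 0
    ]
    return decompose_counts(rows)
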