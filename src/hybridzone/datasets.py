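"""Published field-survey summary tables from the Guinea-Bissau hybrid zone.

These are printed summaries (karyotype frequency percentages from the
coastal Safim and inland Leibala samples; human-blood-index and
insecticide-resistance allele summaries per microsatellite-defined genetic
cluster) used as inputs to the contingency statistics.  Integer counts are
reconstructed from the printed percentages and sample sizes via
nearest-integer rounding with a largest-remainder fallback.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .karyotype import InversionGenotypeCounts, column_genotype_counts

__all__ = [
    "load_karyotype_frequency_table",
    "KARYOTYPE_TOTALS",
    "published_genotype_counts",
    "HBI_SUMMARY",
    "KDR_SUMMARY",
    "reconstruct_binary_counts",
]

#: karyotyped sample sizes per column of the frequency table
KARYOTYPE_TOTALS = {
    "safim_coluzzii": 12,
    "safim_admixed": 76,
    "safim_gambiae": 114,
    "leibala_gambiae": 58,
}

#: human blood index and number of scored meals per genetic cluster
HBI_SUMMARY = {
    "coluzzii": (0.385, 13),
    "gambiae_inland": (0.824, 34),
    "gambiae_coast": (0.308, 65),
    "admixed": (0.391, 23),
}

#: kdr (Vgsc-1014F) allele frequency and number of genotyped individuals
KDR_SUMMARY = {
    "coluzzii": (0.019, 211),
    "gambiae_inland": (0.767, 176),
    "gambiae_coast": (0.045, 231),
    "admixed": (0.179, 67),
}


def load_karyotype_frequency_table() -> pd.DataFrame:
    """Karyotype frequency percentages by arm/label and sample column."""
    with resources.files("hybridzone.data").joinpath("karyotype_frequencies.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def published_genotype_counts(column: str, arm: str) -> dict[str, InversionGenotypeCounts]:
    """Per-inversion genotype tallies for one sample column of the survey table."""
    table = load_karyotype_frequency_table()
    sub = table[table["arm"] == arm]
    return column_genotype_counts(
        sub["label"].tolist(), sub[column].to_numpy(), KARYOTYPE_TOTALS[column], arm
    )


def reconstruct_binary_counts(proportion: float, n: int) -> tuple[int, int]:
    """(successes, failures) implied by a printed proportion of a known n."""
    successes = int(round(proportion * n))
    return successes, n - successes
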