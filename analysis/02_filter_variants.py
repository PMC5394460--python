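"""Hard-filter the simulated call set and reduce to the missingless set.

Applies the six-rule filter (GQ < 40, DP < 14, DP outside [median/2,
median x 2] per sample, MQ < 40, QD < 5, HRun > 3) with genotype-level
masking for the quality/depth rules and site-level removal for the
annotation rules, then drops every site missing a genotype in any sample.

Run after 01:  python analysis/02_filter_variants.py
"""

from pathlib import Path

import pandas as pd

from hybridzone import io
from hybridzone.variant_filter import (
    apply_hard_filter,
    drop_incomplete_sites,
    sample_depth_medians,
)

OUT = Path("results/analysis")

if __name__ == "__main__":
    sites, samples = io.read_vcf(OUT / "simulated.vcf")
    medians = sample_depth_medians(sites)
    filtered, counts = apply_hard_filter(sites, medians)
    complete = drop_incomplete_sites(filtered)
    io.write_vcf(complete, samples, OUT / "filtered.vcf")
    pd.DataFrame(sorted(counts.items()), columns=["rule", "count"]).to_csv(
        OUT / "filter_log.tsv", sep="\t", index=False
    )
    print(
        f"{len(sites)} sites in; {len(complete)} missingless sites out "
        f"({len(sites) - len(filtered)} removed at site level, "
        f"{sum(counts[r] for r in ('GQ', 'DP_min', 'DP_median'))} genotypes masked)"
    )
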