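"""Inversion-karyotype contrasts.

Part 1 rebuilds integer genotype counts from the published coastal (Safim)
and inland (Leibala) karyotype-frequency percentages, decomposes each
karyotype into per-inversion biallelic genotypes, and reproduces the
coast-vs-inland chi-square statistics for 2La and 2Rb plus the
coluzzii-vs-gambiae Fisher tests at the coast.  Part 2 round-trips a
Hardy-Weinberg simulated karyotype sample through the parser.

Run from the repository root:  python analysis/06_inversion_karyotypes.py
"""

from pathlib import Path

import pandas as pd

from hybridzone import datasets
from hybridzone.karyotype import count_karyotype_classes, decompose_counts, parse_karyotype
from hybridzone.simulate import simulate_karyotype_sample
from hybridzone.stats import fisher_exact_2x2, pearson_chi_square

OUT = Path("results/analysis")

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for letter, arm in (("a", "2L"), ("b", "2R"), ("d", "2R")):
        coast = datasets.published_genotype_counts("safim_gambiae", arm)[letter]
        inland = datasets.published_genotype_counts("leibala_gambiae", arm)[letter]
        res = pearson_chi_square([coast.as_tuple(), inland.as_tuple()])
        rows.append((f"2{arm[1]}{letter}" if arm == "2R" else "2La",
                     *coast.as_tuple(), *inland.as_tuple(), res.statistic, res.df, res.p_value))
    report = pd.DataFrame(
        rows,
        columns=["inversion", "coast_ss", "coast_het", "coast_ii",
                 "inland_ss", "inland_het", "inland_ii", "chi_square", "df", "p"],
    )
    report.to_csv(OUT / "published_karyotype_tests.tsv", sep="\t", index=False)

    # coluzzii vs gambiae at the coast: allele-count Fisher tests for 2Rd, 2La
    fisher = {}
    for letter, arm in (("d", "2R"), ("a", "2L")):
        col = datasets.published_genotype_counts("safim_coluzzii", arm)[letter]
        gam = datasets.published_genotype_counts("safim_gambiae", arm)[letter]
        table = [
            [2 * col.std_std + col.het, 2 * col.inv_inv + col.het],
            [2 * gam.std_std + gam.het, 2 * gam.inv_inv + gam.het],
        ]
        fisher[letter] = fisher_exact_2x2(table)

    table = datasets.load_karyotype_frequency_table()
    sub = table[table["arm"] == "2R"]
    census = (count_karyotype_classes(sub["safim_gambiae"]),
              count_karyotype_classes(sub["leibala_gambiae"]))

    sim = simulate_karyotype_sample({"j": 0.15, "b": 0.55, "d": 0.16, "a": 0.78}, 300, seed=42)
    counts = decompose_counts([(parse_karyotype(l2r, "2R"), 1) for l2r, _ in sim])
    print(
        "published tests:\n" + report.round(2).to_string(index=False)
        + f"\ncoastal coluzzii-vs-gambiae Fisher p: 2Rd={fisher['d']:.2f}, 2La={fisher['a']:.2f}"
        + f"\n2R karyotype classes: coast {census[0]}, inland {census[1]}"
        + f"\nsimulated round-trip (n=300) 2Rb genotypes: {counts['b'].as_tuple()}"
    )
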