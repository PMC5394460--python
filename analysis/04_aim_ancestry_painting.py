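"""Ancestry-informative-marker analysis: select AIMs (panel frequency
difference > 0.9), score every individual 0 / 0.5 / 1, summarise ancestry
composition separately for autosomes and X, and find each coastal
individual's longest homozygous resident-species tract on X.

Run after 02:  python analysis/04_aim_ancestry_painting.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hybridzone import ancestry, io
from hybridzone.plots import ancestry_painting

OUT = Path("results/analysis")

if __name__ == "__main__":
    freq_a = pd.read_csv(OUT / "panel_speciesA_freqs.tsv", sep="\t")
    freq_b = pd.read_csv(OUT / "panel_speciesB_freqs.tsv", sep="\t")
    sites, samples = io.read_vcf(OUT / "filtered.vcf")
    gm = io.genotype_matrix_from_sites(sites, samples)
    aims = ancestry.select_aims(freq_a, freq_b)
    retained = set(zip(gm.loci["chrom"], gm.loci["pos"]))
    aims = [m for m in aims if (m.chrom, m.pos) in retained]
    scores = ancestry.score_genotypes(gm, aims)
    scores.to_csv(OUT / "aim_scores.tsv", sep="\t")
    grouping = ancestry.default_grouping(aims)
    per_ind, per_group = ancestry.ancestry_composition(scores, grouping)
    per_ind.to_csv(OUT / "ancestry_composition.tsv", sep="\t")
    x_aims = [m for m in aims if m.chrom == "X"]
    pos = np.array([m.pos for m in x_aims])
    rows = []
    for ind in scores.index:
        vals = scores.loc[ind, [m.key for m in x_aims]].to_numpy(dtype=float)
        for h in (0, 1):
            t = ancestry.longest_homozygous_tract(vals, pos, max_het=h, target_score=0.0)
            rows.append((ind, h, t.start_pos, t.end_pos, t.span_bp))
    tracts = pd.DataFrame(rows, columns=["individual", "max_het", "start", "end", "span_bp"])
    tracts.to_csv(OUT / "x_tracts.tsv", sep="\t", index=False)
    ancestry_painting(
        scores[[m.key for m in x_aims]], {m.key: m.pos for m in x_aims},
        OUT / "x_painting.png",
    )
    coast = scores.index.str.startswith("coast")
    auto_cols = [k for k, g in grouping.items() if g == "autosomal"]
    x_cols = [k for k, g in grouping.items() if g == "X"]
    coastal_tracts = tracts[(tracts["max_het"] == 0) & tracts["individual"].str.startswith("coast")]
    print(
        f"{len(aims)} AIMs ({len(x_aims)} on X); coastal mean donor ancestry "
        f"{scores.loc[coast, auto_cols].mean().mean():.2f} autosomal vs "
        f"{scores.loc[coast, x_cols].mean().mean():.2f} on X; "
        f"median coastal X tract {coastal_tracts['span_bp'].median() / 1e6:.1f} Mb"
    )
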