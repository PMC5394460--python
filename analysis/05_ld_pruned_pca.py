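"""PCA of chromosome-3 genotypes after singleton removal and LD pruning
(500-SNP windows, 100-SNP step, r^2 <= 0.1), mirroring the preparation used
for between-cohort ordination.

Run after 02:  python analysis/05_ld_pruned_pca.py
"""

from pathlib import Path

import pandas as pd

from hybridzone import dimred, io
from hybridzone.plots import pca_scatter

OUT = Path("results/analysis")

if __name__ == "__main__":
    sites, samples = io.read_vcf(OUT / "filtered.vcf")
    gm = io.genotype_matrix_from_sites(sites, samples)
    gm3 = gm.restrict_to_arms(["3R", "3L"])
    n0 = gm3.n_loci
    gm3 = dimred.remove_singletons(gm3)
    n1 = gm3.n_loci
    gm3 = dimred.ld_prune_matrix(gm3)
    result = dimred.pca(gm3, k=10)
    result.coordinates.to_csv(OUT / "pca_coordinates.tsv", sep="\t")
    pd.Series(result.eigenvalues, name="eigenvalue").to_csv(
        OUT / "pca_eigenvalues.tsv", sep="\t", index_label="component"
    )
    groups = pd.Series(
        ["coast" if s.startswith("coast") else "inland" for s in result.coordinates.index],
        index=result.coordinates.index,
    )
    pca_scatter(result.coordinates, groups, OUT / "pca.png")
    pc1 = result.coordinates["PC1"]
    sep = pc1[groups == "coast"].mean() - pc1[groups == "inland"].mean()
    print(
        f"chromosome 3: {n0} loci -> {n1} after singleton removal -> "
        f"{gm3.n_loci} after LD pruning; PC1 separates cohorts by {abs(sep):.2f} "
        f"(eigenvalue share {result.eigenvalues[0] / result.eigenvalues.sum():.0%})"
    )
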