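"""Simulate the two-species hybrid-zone study.

Generates two parental allele-frequency panels with pericentromeric islands
of divergence, an introgressed "coastal" cohort (70% donor ancestry on the
autosomes, 10% on X, with a resistant X island) and a pure "inland" cohort,
and writes the annotated VCF, the per-haplotype ancestry truth, the panels
and the region annotations under results/analysis/.

Run from the repository root:  python analysis/01_simulate_hybrid_zone.py
"""

import dataclasses
from pathlib import Path

from hybridzone import io
from hybridzone.genome import build_default_genome_map
from hybridzone.pipeline import _merge_cohort_sites
from hybridzone.simulate import (
    SPECIES_B,
    SimulationConfig,
    simulate_cohort,
    simulate_parental_frequencies,
)

OUT = Path("results/analysis")
SEED = 42

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    gmap = build_default_genome_map()
    coast_cfg = SimulationConfig(
        n_per_population=12, n_loci_per_arm=600, alpha_autosome=0.7, alpha_x=0.1,
        forced_island_ancestry={"X": SPECIES_B}, seed=SEED,
    )
    inland_cfg = dataclasses.replace(
        coast_cfg, alpha_autosome=0.0, alpha_x=0.0, forced_island_ancestry=None,
        seed=SEED + 1,
    )
    freq_a, freq_b = simulate_parental_frequencies(gmap, coast_cfg)
    gm_c, truths_c, sites_c = simulate_cohort(coast_cfg, freq_a, freq_b, gmap, "coast")
    gm_i, truths_i, sites_i = simulate_cohort(inland_cfg, freq_a, freq_b, gmap, "inland")
    samples = gm_c.samples + gm_i.samples
    sites = _merge_cohort_sites(sites_c, sites_i)
    io.write_vcf(sites, samples, OUT / "simulated.vcf")
    io.write_truth_tsv(truths_c + truths_i, OUT / "truth.tsv")
    freq_a.to_csv(OUT / "panel_speciesA_freqs.tsv", sep="\t", index=False)
    freq_b.to_csv(OUT / "panel_speciesB_freqs.tsv", sep="\t", index=False)
    io.regions_to_frame(gmap.island_spans).to_csv(
        OUT / "islands.bed", sep="\t", index=False, header=False
    )
    (OUT / "samples_coast.txt").write_text("\n".join(gm_c.samples) + "\n")
    (OUT / "samples_inland.txt").write_text("\n".join(gm_i.samples) + "\n")
    n_island = int(freq_a["island"].sum())
    print(
        f"simulated {len(sites)} variants for {len(samples)} individuals "
        f"({n_island} island loci of {len(freq_a)}); outputs in {OUT}"
    )
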