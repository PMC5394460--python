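"""End-to-end reproducible workflow: simulate -> filter -> (FST | AIMs | PCA)
-> karyotype and epidemiological reports, with a manifest recording
parameters, seeds and output checksums.

The simulated study contrasts a "coastal" cohort carrying heavy autosomal
introgression (with an introgression-resistant X pericentromeric island) with
a pure "inland" reference cohort, mirroring the structure of the hybrid-zone
analyses the library implements.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import ancestry, datasets, dimred, io, karyotype, popdiff, stats
from .genome import X_ARM, build_default_genome_map
from .simulate import (
    SPECIES_B,
    SimulationConfig,
    simulate_cohort,
    simulate_karyotype_sample,
    simulate_parental_frequencies,
)
from .variant_filter import (
    FilterThresholds,
    apply_hard_filter,
    drop_incomplete_sites,
    replace_site_calls,
    sample_depth_medians,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

# inverted-arrangement frequencies observed cytologically at the two focal sites
COASTAL_INVERSION_FREQS = {"j": 0.0, "b": 0.01, "d": 0.50, "a": 0.20}
INLAND_INVERSION_FREQS = {"j": 0.15, "b": 0.55, "d": 0.16, "a": 0.78}


@dataclass
class RunConfig:
    """All stage parameters with their study-grade defaults."""

    seed: int = 0
    n_per_population: int = 12
    n_loci_per_arm: int = 300
    alpha_autosome: float = 0.7
    alpha_x: float = 0.1
    block_length_bp: float = 5_000_000.0
    window_size: int = 50_000
    top_q: float = 0.05
    aim_min_diff: float = 0.9
    ld_window: int = 500
    ld_step: int = 100
    r2_max: float = 0.1
    n_components: int = 10
    max_het: int = 1
    t_q: float = 0.5
    karyotype_n: int = 200
    make_plots: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge_cohort_sites(sites_a, sites_b):
    """Union of calls per locus; site annotations taken from the first cohort."""
    merged = []
    for sa, sb in zip(sites_a, sites_b):
        assert (sa.chrom, sa.pos) == (sb.chrom, sb.pos)
        merged.append(replace_site_calls(sa, {**sa.calls, **sb.calls}))
    return merged


def run_pipeline(config: RunConfig, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}
    gmap = build_default_genome_map()

    # --- simulate ---------------------------------------------------------
    sim_coast = SimulationConfig(
        n_per_population=config.n_per_population,
        n_loci_per_arm=config.n_loci_per_arm,
        alpha_autosome=config.alpha_autosome,
        alpha_x=config.alpha_x,
        block_length_bp=config.block_length_bp,
        forced_island_ancestry={X_ARM: SPECIES_B},
        seed=config.seed,
    )
    sim_inland = dataclasses.replace(
        sim_coast, alpha_autosome=0.0, alpha_x=0.0, forced_island_ancestry=None,
        seed=config.seed + 1,
    )
    freq_a, freq_b = simulate_parental_frequencies(gmap, sim_coast)
    gm_coast, truths, sites_coast = simulate_cohort(sim_coast, freq_a, freq_b, gmap, "coast")
    gm_inland, truths_inland, sites_inland = simulate_cohort(
        sim_inland, freq_a, freq_b, gmap, "inland"
    )
    samples = gm_coast.samples + gm_inland.samples
    sites = _merge_cohort_sites(sites_coast, sites_inland)
    io.write_vcf(sites, samples, out / "simulated.vcf")
    io.write_truth_tsv(truths + truths_inland, out / "truth.tsv")
    freq_a.to_csv(out / "panel_speciesA_freqs.tsv", sep="\t", index=False)
    freq_b.to_csv(out / "panel_speciesB_freqs.tsv", sep="\t", index=False)
    io.regions_to_frame(gmap.island_spans).to_csv(
        out / "islands.bed", sep="\t", index=False, header=False
    )
    io.regions_to_frame(gmap.inversion_spans).to_csv(
        out / "inversions.bed", sep="\t", index=False, header=False
    )
    logger.info("simulate: %d individuals, %d sites", len(samples), len(sites))
    manifest["stages"]["simulate"] = {"individuals": len(samples), "sites": len(sites)}

    # --- filter -----------------------------------------------------------
    medians = sample_depth_medians(sites)
    filtered, counts = apply_hard_filter(sites, medians, FilterThresholds())
    complete = drop_incomplete_sites(filtered)
    io.write_vcf(complete, samples, out / "filtered.vcf")
    pd.DataFrame(sorted(counts.items()), columns=["rule", "count"]).to_csv(
        out / "filter_log.tsv", sep="\t", index=False
    )
    logger.info(
        "filter: %d -> %d sites (missingless), rejections %s", len(sites), len(complete), counts
    )
    manifest["stages"]["filter"] = {"sites_in": len(sites), "sites_out": len(complete),
                                    "rejections": counts}

    # --- FST --------------------------------------------------------------
    gm_all = io.genotype_matrix_from_sites(complete, samples)
    coast_rows = [i for i, s in enumerate(samples) if s.startswith("coast")]
    inland_rows = [i for i, s in enumerate(samples) if s.startswith("inland")]
    comps = []
    for j in range(gm_all.n_loci):
        comps.append(
            popdiff.weir_cockerham_site_fst(
                gm_all.dosages[coast_rows, j],
                gm_all.dosages[inland_rows, j],
                chrom=str(gm_all.loci.at[j, "chrom"]),
                pos=int(gm_all.loci.at[j, "pos"]) + 1,
            )
        )
    windows = popdiff.windowed_mean_fst(
        comps, window_size=config.window_size, arm_lengths=gmap.arm_lengths
    )
    win_frame = pd.DataFrame(
        [(w.chrom, w.start, w.end, w.n_sites, w.mean_fst, w.weighted_fst) for w in windows],
        columns=["chrom", "start", "end", "n_sites", "mean_fst", "weighted_fst"],
    )
    win_frame.to_csv(out / "fst_windows.tsv", sep="\t", index=False)
    regions = io.regions_to_frame(gmap.island_spans)
    enrich = popdiff.region_enrichment(windows, regions, "pericentromeric", q=config.top_q)
    logger.info(
        "fst: %d windows, top-%.0f%% island proportion %.2f (chi2=%.1f)",
        len(windows), 100 * config.top_q, enrich.proportion_top_inside, enrich.chi_square,
    )
    manifest["stages"]["fst"] = {
        "windows": len(windows),
        "proportion_top_inside_islands": enrich.proportion_top_inside,
        "chi_square": enrich.chi_square,
        "p_value": enrich.p_value,
    }
    if config.make_plots:
        from . import plots

        plots.manhattan(windows, regions, out / "fst_manhattan.png", config.window_size)

    # --- AIMs -------------------------------------------------------------
    aims = ancestry.select_aims(freq_a, freq_b, min_diff=config.aim_min_diff)
    retained = set(zip(gm_all.loci["chrom"], gm_all.loci["pos"]))
    aims = [m for m in aims if (m.chrom, m.pos) in retained]
    pd.DataFrame(
        [(m.chrom, m.pos, m.allele_a, m.allele_b, m.delta) for m in aims],
        columns=["chrom", "pos", "alleleA", "alleleB", "delta"],
    ).to_csv(out / "aims.tsv", sep="\t", index=False)
    scores = ancestry.score_genotypes(gm_all, aims)
    scores.to_csv(out / "aim_scores.tsv", sep="\t")
    grouping = ancestry.default_grouping(aims)
    per_ind, per_group = ancestry.ancestry_composition(scores, grouping)
    per_ind.to_csv(out / "ancestry_composition.tsv", sep="\t")
    x_aims = [m for m in aims if m.chrom == X_ARM]
    tract_rows = []
    for ind in scores.index:
        vals = scores.loc[ind, [m.key for m in x_aims]].to_numpy(dtype=float)
        pos = np.array([m.pos for m in x_aims])
        for h in (0, config.max_het):
            tract = ancestry.longest_homozygous_tract(
                vals, pos, max_het=h, target_score=0.0, chrom=X_ARM
            )
            tract_rows.append((ind, h, tract.start_pos, tract.end_pos, tract.span_bp, tract.n_aims))
    pd.DataFrame(
        tract_rows,
        columns=["individual", "max_het", "start", "end", "span_bp", "n_aims"],
    ).to_csv(out / "x_tracts.tsv", sep="\t", index=False)
    logger.info("aims: %d markers (%d on X)", len(aims), len(x_aims))
    manifest["stages"]["aims"] = {"n_aims": len(aims), "n_x_aims": len(x_aims)}
    if config.make_plots and x_aims:
        from . import plots

        plots.ancestry_painting(
            scores[[m.key for m in x_aims]], {m.key: m.pos for m in x_aims},
            out / "x_painting.png",
        )

    # --- PCA --------------------------------------------------------------
    gm3 = gm_all.restrict_to_arms(["3R", "3L"])
    gm3 = dimred.remove_singletons(gm3)
    gm3 = dimred.ld_prune_matrix(
        gm3, window=config.ld_window, step=config.ld_step, r2_max=config.r2_max
    )
    pca_res = dimred.pca(gm3, k=config.n_components)
    pca_res.coordinates.to_csv(out / "pca_coordinates.tsv", sep="\t")
    pd.Series(pca_res.eigenvalues, name="eigenvalue").to_csv(
        out / "pca_eigenvalues.tsv", sep="\t", index_label="component"
    )
    logger.info("pca: %d loci after pruning", gm3.n_loci)
    manifest["stages"]["pca"] = {"loci_after_pruning": gm3.n_loci}
    if config.make_plots:
        from . import plots

        groups = pd.Series(
            ["coast" if s.startswith("coast") else "inland" for s in pca_res.coordinates.index],
            index=pca_res.coordinates.index,
        )
        plots.pca_scatter(pca_res.coordinates, groups, out / "pca.png")

    # --- karyotypes -------------------------------------------------------
    karyo_rows = []
    for name, freqs, seed in (
        ("coastal", COASTAL_INVERSION_FREQS, config.seed + 2),
        ("inland", INLAND_INVERSION_FREQS, config.seed + 3),
    ):
        labels = simulate_karyotype_sample(freqs, config.karyotype_n, seed)
        io.write_karyotype_tsv(labels, out / f"karyotypes_{name}.tsv")
        counts_2r = karyotype.decompose_counts(
            [(karyotype.parse_karyotype(l2r, "2R"), 1) for l2r, _ in labels]
        )
        counts_2l = karyotype.decompose_counts(
            [(karyotype.parse_karyotype(l2l, "2L"), 1) for _, l2l in labels]
        )
        for letter, tally in {**counts_2r, **counts_2l}.items():
            karyo_rows.append((name, letter, *tally.as_tuple(), tally.unscored))
    karyo_frame = pd.DataFrame(
        karyo_rows, columns=["cohort", "inversion", "std_std", "het", "inv_inv", "unscored"]
    )
    karyo_frame.to_csv(out / "karyotype_genotype_counts.tsv", sep="\t", index=False)
    chi_rows = []
    for letter in ("a", "b", "d"):
        sub = karyo_frame[karyo_frame["inversion"] == letter]
        table = sub[["std_std", "het", "inv_inv"]].to_numpy()
        res = stats.pearson_chi_square(table)
        chi_rows.append((letter, res.statistic, res.df, res.p_value))
    pd.DataFrame(chi_rows, columns=["inversion", "chi_square", "df", "p"]).to_csv(
        out / "karyotype_tests.tsv", sep="\t", index=False
    )
    manifest["stages"]["karyotype"] = {"n_per_cohort": config.karyotype_n}

    # --- published-survey report -----------------------------------------
    epi_rows = []
    for group, (hbi, n) in datasets.HBI_SUMMARY.items():
        human, _ = datasets.reconstruct_binary_counts(hbi, n)
        point, lo, hi = stats.wilson_ci(human, n)
        epi_rows.append((group, "HBI", point, lo, hi, n))
    for group, (f, n) in datasets.KDR_SUMMARY.items():
        count, _ = datasets.reconstruct_binary_counts(f, 2 * n)
        point, lo, hi = stats.wilson_ci(count, 2 * n)
        epi_rows.append((group, "kdr_1014F", point, lo, hi, 2 * n))
    pd.DataFrame(
        epi_rows, columns=["group", "quantity", "estimate", "ci_low", "ci_high", "n"]
    ).to_csv(out / "epi_report.tsv", sep="\t", index=False)

    # --- manifest ---------------------------------------------------------
    checksums = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix in (".tsv", ".vcf", ".bed")
    }
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
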