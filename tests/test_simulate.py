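"""The synthetic two-species generator: determinism, island divergence,
ancestry-block structure, karyotype sampling, and its contract with the
variant filter."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hybridzone.genome import GenomeMap, Span, build_default_genome_map
from hybridzone.karyotype import parse_karyotype
from hybridzone.simulate import (
    SPECIES_A,
    SPECIES_B,
    SimulationConfig,
    clean_annotation_model,
    simulate_cohort,
    simulate_karyotype_sample,
    simulate_parental_frequencies,
)
from hybridzone.variant_filter import (
    apply_hard_filter,
    drop_incomplete_sites,
    sample_depth_medians,
)


class TestGenomeMap:
    def test_default_map_has_x_island_and_all_inversions(self, gmap):
        assert any(s.chrom == "X" and s.label == "pericentromeric" for s in gmap.island_spans)
        lengths = gmap.arm_lengths
        for name in ("2La", "2Rj", "2Rb", "2Rd"):
            span = gmap.inversion(name)
            assert 0 <= span.start < span.end <= lengths[span.chrom]
        assert set(lengths) == {"X", "2R", "2L", "3R", "3L"}

    def test_default_map_is_deterministic(self):
        assert build_default_genome_map() == build_default_genome_map()

    def test_span_outside_arm_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            GenomeMap(arms=(("X", 100),), island_spans=(Span("X", 50, 200, "pericentromeric"),))

    def test_duplicate_arm_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            GenomeMap(arms=(("X", 100), ("X", 200)))


class TestParentalFrequencies:
    def test_island_loci_are_nearly_fixed_differences(self, gmap):
        # Beta(50,1) vs Beta(1,50) puts ~96-97% of island loci above the 0.9
        # frequency-difference threshold (Monte-Carlo tail probability)
        cfg = SimulationConfig(n_loci_per_arm=400, seed=7)
        fa, fb = simulate_parental_frequencies(gmap, cfg)
        isl = fa["island"].to_numpy()
        delta = np.abs(fa["freq"].to_numpy() - fb["freq"].to_numpy())
        assert np.mean(delta[isl] > 0.9) >= 0.8

    def test_point_mass_background_gives_zero_divergence(self, gmap):
        cfg = SimulationConfig(n_loci_per_arm=100, background_divergence=0.3, seed=7)
        fa, fb = simulate_parental_frequencies(gmap, cfg)
        bg = ~fa["island"].to_numpy()
        assert np.all(fa["freq"].to_numpy()[bg] == fb["freq"].to_numpy()[bg])
        assert np.all(fa["freq"].to_numpy()[bg] == 0.3)

    def test_same_seed_reproduces_tables_exactly(self, gmap):
        cfg = SimulationConfig(n_loci_per_arm=50, seed=3)
        a1, b1 = simulate_parental_frequencies(gmap, cfg)
        a2, b2 = simulate_parental_frequencies(gmap, cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            GenomeMap(arms=(("X", 0),))


@pytest.fixture(scope="module")
def small_freqs(gmap):
    cfg = SimulationConfig(n_loci_per_arm=80, seed=11)
    return cfg, simulate_parental_frequencies(gmap, cfg)


class TestCohort:
    def test_alpha_zero_yields_pure_resident_truth(self, gmap, small_freqs):
        cfg, (fa, fb) = small_freqs
        cfg = dataclasses.replace(cfg, alpha_autosome=0.0, alpha_x=0.0, n_per_population=3)
        _, truths, _ = simulate_cohort(cfg, fa, fb, gmap)
        for t in truths:
            for haps in t.intervals.values():
                for blocks in haps:
                    assert all(sp == SPECIES_B for _, _, sp in blocks)

    def test_alpha_one_yields_pure_donor_autosomes(self, gmap, small_freqs):
        cfg, (fa, fb) = small_freqs
        cfg = dataclasses.replace(cfg, alpha_autosome=1.0, n_per_population=3)
        _, truths, _ = simulate_cohort(cfg, fa, fb, gmap)
        for t in truths:
            for arm, haps in t.intervals.items():
                if arm == "X":
                    continue
                for blocks in haps:
                    assert all(sp == SPECIES_A for _, _, sp in blocks)

    def test_truth_intervals_tile_each_arm_exactly(self, gmap, small_freqs):
        cfg, (fa, fb) = small_freqs
        cfg = dataclasses.replace(cfg, n_per_population=4, seed=13)
        _, truths, _ = simulate_cohort(cfg, fa, fb, gmap)
        lengths = gmap.arm_lengths
        for t in truths:
            for arm, haps in t.intervals.items():
                for blocks in haps:
                    assert blocks[0][0] == 0
                    assert blocks[-1][1] == lengths[arm]
                    for (s0, e0, _), (s1, e1, _) in zip(blocks, blocks[1:]):
                        assert e0 == s1  # contiguous, no overlap

    def test_realized_autosomal_ancestry_matches_alpha(self, gmap):
        # mean truth-derived speciesA dosage across a 50-individual cohort
        # should sit within +/-0.05 of alpha (block-process standard error)
        cfg = SimulationConfig(
            n_per_population=50, n_loci_per_arm=60, alpha_autosome=0.7, seed=5
        )
        fa, fb = simulate_parental_frequencies(gmap, cfg)
        _, truths, _ = simulate_cohort(cfg, fa, fb, gmap)
        lengths = gmap.arm_lengths
        fractions = []
        for t in truths:
            bp_a = bp_total = 0
            for arm, haps in t.intervals.items():
                if arm == "X":
                    continue
                for blocks in haps:
                    bp_a += sum(e - s for s, e, sp in blocks if sp == SPECIES_A)
                    bp_total += lengths[arm]
            fractions.append(bp_a / bp_total)
        assert abs(np.mean(fractions) - 0.7) < 0.05

    def test_forced_island_ancestry_overrides_blocks(self, gmap, small_freqs):
        cfg, (fa, fb) = small_freqs
        cfg = dataclasses.replace(
            cfg, alpha_x=0.9, forced_island_ancestry={"X": SPECIES_B}, n_per_population=5
        )
        _, truths, _ = simulate_cohort(cfg, fa, fb, gmap)
        island = gmap.islands_on("X")[0]
        for t in truths:
            for blocks in t.intervals["X"]:
                for s, e, sp in blocks:
                    if s < island.end and e > island.start:
                        overlap_only_b = sp == SPECIES_B or e <= island.start or s >= island.end
                        assert overlap_only_b

    def test_same_seed_reproduces_cohort_bitwise(self, gmap, small_freqs):
        cfg, (fa, fb) = small_freqs
        gm1, _, _ = simulate_cohort(cfg, fa, fb, gmap)
        gm2, _, _ = simulate_cohort(cfg, fa, fb, gmap)
        assert np.array_equal(gm1.dosages, gm2.dosages)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(alpha_autosome=1.2)

    def test_clean_annotations_pass_hard_filter_unchanged(self, gmap, small_freqs):
        cfg, (fa, fb) = small_freqs
        cfg = dataclasses.replace(
            cfg, annotation_model=clean_annotation_model(), n_per_population=4
        )
        _, _, sites = simulate_cohort(cfg, fa, fb, gmap)
        medians = sample_depth_medians(sites)
        kept, counts = apply_hard_filter(sites, medians)
        assert len(drop_incomplete_sites(kept)) == len(sites)
        assert all(c == 0 for c in counts.values())


class TestKaryotypeSample:
    def test_zero_frequencies_give_all_standard(self):
        labels = simulate_karyotype_sample({"j": 0, "b": 0, "d": 0, "a": 0}, 20, seed=1)
        assert all(l2r == "+/+" and l2l == "+/+" for l2r, l2l in labels)

    def test_fixed_inversion_gives_homozygote_labels(self):
        labels = simulate_karyotype_sample({"d": 1.0}, 20, seed=1)
        assert all(l2r == "d/d" for l2r, _ in labels)

    def test_hardy_weinberg_homozygote_fraction(self):
        labels = simulate_karyotype_sample({"b": 0.5}, 1000, seed=2)
        bb = sum(1 for l2r, _ in labels if l2r == "b/b")
        assert abs(bb / 1000 - 0.25) < 0.05

    def test_labels_round_trip_through_parser(self):
        labels = simulate_karyotype_sample({"j": 0.2, "b": 0.5, "d": 0.3, "a": 0.6}, 50, seed=3)
        for l2r, l2l in labels:
            kc_r = parse_karyotype(l2r, "2R")
            kc_l = parse_karyotype(l2l, "2L")
            assert set(kc_r.genotypes) == {"j", "b", "d"}
            assert set(kc_l.genotypes) == {"a"}

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            simulate_karyotype_sample({"b": 1.5}, 10, seed=0)
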