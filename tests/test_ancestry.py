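"""AIM selection, tri-state scoring, composition, and homozygous-tract
detection (against exhaustive enumeration)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_tract
from hybridzone.ancestry import (
    AimDefinition,
    ancestry_composition,
    default_grouping,
    longest_homozygous_tract,
    score_allele_pair,
    score_genotypes,
    select_aims,
)
from hybridzone.dimred import GenotypeMatrix


def _freq_tables(rows):
    """rows: list of (chrom, pos, fA, fB)."""
    base = pd.DataFrame(
        [(c, p, "A", "T") for c, p, _, _ in rows], columns=["chrom", "pos", "ref", "alt"]
    )
    fa = base.assign(freq=[r[2] for r in rows])
    fb = base.assign(freq=[r[3] for r in rows])
    return fa, fb


class TestSelectAims:
    def test_large_difference_selected_with_delta(self):
        fa, fb = _freq_tables([("X", 10, 0.98, 0.01)])
        (aim,) = select_aims(fa, fb)
        assert aim.delta == pytest.approx(0.97)
        assert aim.allele_a == "T"  # alt more frequent in panel A
        assert aim.allele_b == "A"

    def test_difference_exactly_at_threshold_not_selected(self):
        fa, fb = _freq_tables([("X", 10, 0.95, 0.05)])  # |delta| = 0.9 exactly
        assert select_aims(fa, fb) == []

    def test_equal_frequencies_not_selected(self):
        fa, fb = _freq_tables([("X", 10, 0.5, 0.5)])
        assert select_aims(fa, fb) == []

    def test_reference_allele_can_be_diagnostic(self):
        fa, fb = _freq_tables([("2L", 5, 0.02, 0.99)])  # alt frequent in panel B
        (aim,) = select_aims(fa, fb)
        assert aim.allele_a == "A" and aim.allele_b == "T"

    def test_mismatched_loci_rejected(self):
        fa, _ = _freq_tables([("X", 10, 0.9, 0.1)])
        _, fb = _freq_tables([("X", 11, 0.9, 0.1)])
        with pytest.raises(ValueError, match="share loci"):
            select_aims(fa, fb)


AIM = AimDefinition(chrom="X", pos=10, allele_a="G", allele_b="C", delta=0.95)


class TestScoring:
    @pytest.mark.parametrize(
        "pair, expected",
        [(("G", "G"), 1.0), (("G", "C"), 0.5), (("C", "G"), 0.5), (("C", "C"), 0.0)],
    )
    def test_tri_state_coding(self, pair, expected):
        assert score_allele_pair(*pair, AIM) == expected

    def test_third_allele_scores_missing(self):
        assert score_allele_pair("G", "A", AIM) is None

    def test_dosage_scoring_flips_when_ref_is_diagnostic(self):
        loci = pd.DataFrame({"chrom": ["X", "X"], "pos": [10, 20]})
        gm = GenotypeMatrix(np.array([[2, 2], [0, 1]]), ["i1", "i2"], loci)
        aims = [
            AimDefinition("X", 10, "T", "A", 0.95),  # alt diagnostic
            AimDefinition("X", 20, "A", "T", 0.95),  # ref diagnostic
        ]
        scores = score_genotypes(gm, aims)
        assert scores.loc["i1"].tolist() == [1.0, 0.0]
        assert scores.loc["i2"].tolist() == [0.0, 0.5]

    def test_label_symmetry_swapping_panels_maps_scores_to_complement(self):
        rng = np.random.default_rng(0)
        rows = [("2R", int(p), 0.98, 0.01) for p in np.sort(rng.choice(10_000, 20, False))]
        fa, fb = _freq_tables(rows)
        loci = fa[["chrom", "pos"]]
        gm = GenotypeMatrix(rng.integers(0, 3, (6, 20)), [f"i{k}" for k in range(6)], loci)
        s_fwd = score_genotypes(gm, select_aims(fa, fb))
        s_rev = score_genotypes(gm, select_aims(fb, fa))
        np.testing.assert_allclose(s_fwd.to_numpy(), 1.0 - s_rev.to_numpy())


class TestComposition:
    def test_all_target_homozygous(self):
        scores = pd.DataFrame({"X:1": [1.0], "X:2": [1.0]}, index=["i1"])
        per_ind, agg = ancestry_composition(scores, {"X:1": "X", "X:2": "X"})
        assert per_ind.loc["i1", ("X", "speciesA_hom")] == 1.0
        assert agg.loc["X", "speciesA_hom"] == 1.0

    def test_counting_example(self):
        scores = pd.DataFrame(
            {"2L:1": [1.0], "2L:2": [1.0], "2L:3": [0.5], "2L:4": [0.0]}, index=["i1"]
        )
        grouping = {c: "autosomal" for c in scores.columns}
        per_ind, _ = ancestry_composition(scores, grouping)
        row = per_ind.loc["i1", "autosomal"]
        assert (row["speciesA_hom"], row["het"], row["speciesB_hom"]) == (0.5, 0.25, 0.25)

    def test_missing_scores_excluded_from_denominator(self):
        scores = pd.DataFrame({"X:1": [1.0], "X:2": [np.nan]}, index=["i1"])
        per_ind, _ = ancestry_composition(scores, {"X:1": "X", "X:2": "X"})
        assert per_ind.loc["i1", ("X", "speciesA_hom")] == 1.0
        assert per_ind.loc["i1", ("X", "n_scored")] == 1.0

    def test_group_with_no_scored_aims_flagged_nan(self):
        scores = pd.DataFrame({"X:1": [np.nan], "2L:1": [1.0]}, index=["i1"])
        per_ind, _ = ancestry_composition(scores, {"X:1": "X", "2L:1": "autosomal"})
        assert np.isnan(per_ind.loc["i1", ("X", "speciesA_hom")])

    def test_grouping_must_cover_all_aims(self):
        scores = pd.DataFrame({"X:1": [1.0]}, index=["i1"])
        with pytest.raises(ValueError, match="without a group"):
            ancestry_composition(scores, {})

    def test_default_grouping_splits_x_from_autosomes(self):
        aims = [AimDefinition("X", 1, "A", "T", 0.95), AimDefinition("3L", 1, "A", "T", 0.95)]
        assert default_grouping(aims) == {"X:1": "X", "3L:1": "autosomal"}


MB = 1_000_000


class TestTracts:
    def test_het_tolerance_extends_run(self):
        scores = [1, 1, 1, 0.5, 1, 1]
        positions = [1 * MB, 2 * MB, 3 * MB, 4 * MB, 5 * MB, 6 * MB]
        strict = longest_homozygous_tract(scores, positions, max_het=0)
        assert (strict.n_aims, strict.span_bp) == (3, 2 * MB)
        relaxed = longest_homozygous_tract(scores, positions, max_het=1)
        assert (relaxed.n_aims, relaxed.span_bp) == (6, 5 * MB)
        assert relaxed.n_het_inside == 1

    def test_all_opposite_homozygous_gives_empty_tract(self):
        tract = longest_homozygous_tract([0, 0, 0], [1, 2, 3])
        assert tract.span_bp == 0 and tract.start_index == -1

    def test_tie_breaks_to_leftmost(self):
        scores = [1, 1, 0, 1, 1]
        positions = [0, 5, 10, 20, 25]
        tract = longest_homozygous_tract(scores, positions)
        assert (tract.start_index, tract.end_index) == (0, 1)

    def test_missing_scores_break_runs(self):
        scores = [1, np.nan, 1, 1]
        tract = longest_homozygous_tract(scores, [0, 10, 20, 40], max_het=1)
        assert (tract.start_index, tract.end_index) == (2, 3)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            longest_homozygous_tract([1, 1], [5, 1])

    @settings(derandomize=True, max_examples=150)
    @given(
        st.lists(st.sampled_from([0.0, 0.5, 1.0]), min_size=1, max_size=40),
        st.integers(min_value=0, max_value=2),
        st.randoms(use_true_random=False),
    )
    def test_matches_exhaustive_enumeration(self, scores, max_het, rnd):
        positions = sorted(rnd.sample(range(10_000), len(scores)))
        tract = longest_homozygous_tract(scores, positions, max_het=max_het)
        i, j, span = brute_force_tract(scores, positions, max_het)
        assert (tract.start_index, tract.end_index, tract.span_bp) == (i, j, span)

    def test_span_monotone_in_het_tolerance(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            scores = rng.choice([0.0, 0.5, 1.0], 50, p=[0.2, 0.3, 0.5])
            positions = np.sort(rng.choice(100_000, 50, replace=False))
            s0 = longest_homozygous_tract(scores, positions, max_het=0).span_bp
            s1 = longest_homozygous_tract(scores, positions, max_het=1).span_bp
            assert s1 >= s0
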