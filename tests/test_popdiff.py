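"""Weir-Cockerham per-site FST, windowed means, top-quantile thresholds and
region enrichment, each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_top_set, pearson_chi2_oracle, wc_fst_oracle
from hybridzone.popdiff import (
    FstWindow,
    SiteFstComponents,
    region_enrichment,
    top_fraction_threshold,
    weir_cockerham_site_fst,
    windowed_mean_fst,
)


class TestSiteFst:
    def test_fixed_difference_gives_exactly_one(self):
        comp = weir_cockerham_site_fst([0] * 10, [2] * 10)
        assert comp.fst == 1.0

    def test_identical_samples_give_non_positive_or_undefined(self):
        sample = [0, 1, 1, 2, 0, 1]
        comp = weir_cockerham_site_fst(sample, sample)
        assert comp.fst is None or comp.fst <= 0

    def test_monomorphic_in_both_is_undefined(self):
        comp = weir_cockerham_site_fst([0, 0, 0], [0, 0, 0])
        assert comp.fst is None

    def test_spec_example_matches_independent_transcription(self):
        comp = weir_cockerham_site_fst([0, 1, 1, 2], [0, 0, 1, 0])
        a, b, c = wc_fst_oracle([0, 1, 1, 2], [0, 0, 1, 0])
        assert comp.a == pytest.approx(a)
        assert comp.b == pytest.approx(b)
        assert comp.c == pytest.approx(c)

    def test_random_cases_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(2, 12, 2)
            g1 = rng.integers(0, 3, n1).tolist()
            g2 = rng.integers(0, 3, n2).tolist()
            comp = weir_cockerham_site_fst(g1, g2)
            a, b, c = wc_fst_oracle(g1, g2)
            np.testing.assert_allclose([comp.a, comp.b, comp.c], [a, b, c], atol=1e-12)
            fst = comp.fst
            if fst is not None:
                assert fst <= 1.0

    def test_single_genotype_population_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            weir_cockerham_site_fst([1], [0, 1, 2])

    def test_missing_genotypes_are_ignored(self):
        comp = weir_cockerham_site_fst([0, 1, None, 2], [0, 0, 1, 0])
        ref = weir_cockerham_site_fst([0, 1, 2], [0, 0, 1, 0])
        assert comp.a == ref.a


def _comp(chrom, pos, fst_value):
    # a site whose fst equals fst_value with unit denominator
    return SiteFstComponents(chrom=chrom, pos=pos, a=fst_value, b=0.0, c=1.0 - fst_value)


class TestWindows:
    def test_single_site_window(self):
        wins = windowed_mean_fst([_comp("2L", 10_000, 0.4)])
        w = [w for w in wins if w.n_sites][0]
        assert (w.start, w.end) == (0, 10_000) or (w.start, w.end) == (0, 50_000)
        assert w.mean_fst == pytest.approx(0.4)
        assert w.n_sites == 1

    def test_arithmetic_mean_of_sites_in_window(self):
        comps = [_comp("2L", p, f) for p, f in [(10_000, 0.1), (20_000, 0.2), (30_000, 0.6)]]
        wins = windowed_mean_fst(comps)
        assert wins[0].mean_fst == pytest.approx(0.3)

    def test_boundary_position_50000_falls_in_first_window(self):
        # 1-based position 50000 has 0-based coordinate 49999 -> window [0, 50000)
        wins = windowed_mean_fst(
            [_comp("2L", 50_000, 0.5)], arm_lengths={"2L": 100_000}
        )
        assert wins[0].start == 0 and wins[0].n_sites == 1
        assert wins[1].n_sites == 0

    def test_position_50001_starts_second_window(self):
        wins = windowed_mean_fst(
            [_comp("2L", 50_001, 0.5)], arm_lengths={"2L": 100_000}
        )
        assert wins[0].n_sites == 0 and wins[1].n_sites == 1

    def test_unsorted_input_rejected(self):
        comps = [_comp("2L", 30_000, 0.1), _comp("2L", 10_000, 0.2)]
        with pytest.raises(ValueError, match="sorted"):
            windowed_mean_fst(comps)

    def test_every_defined_site_lands_in_exactly_one_window(self):
        rng = np.random.default_rng(3)
        positions = np.sort(rng.choice(np.arange(1, 400_000), 200, replace=False))
        comps = [_comp("3R", int(p), float(rng.uniform(0, 1))) for p in positions]
        wins = windowed_mean_fst(comps, arm_lengths={"3R": 400_000})
        assert sum(w.n_sites for w in wins) == len(comps)
        assert all(w.end - w.start == 50_000 for w in wins[:-1])

    def test_undefined_sites_do_not_count(self):
        comps = [
            SiteFstComponents("2L", 100, 0.0, 0.0, 0.0),  # undefined
            _comp("2L", 200, 0.5),
        ]
        wins = windowed_mean_fst(comps)
        assert wins[0].n_sites == 1 and wins[0].mean_fst == pytest.approx(0.5)


class TestTopFraction:
    def test_top_five_percent_of_1_to_100(self):
        values = list(range(1, 101))
        thr = top_fraction_threshold(values, q=0.05)
        assert thr == 96
        assert {v for v in values if v >= thr} == {96, 97, 98, 99, 100}

    def test_all_equal_values_all_in_top_set(self):
        thr = top_fraction_threshold([7.0] * 20, q=0.05)
        assert thr == 7.0

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(min_value=0, max_value=10), min_size=1, max_size=60),
        st.floats(min_value=0.01, max_value=0.5),
    )
    def test_matches_exhaustive_cut_point_enumeration(self, values, q):
        thr = top_fraction_threshold(values, q=q)
        expected_set, expected_thr = brute_force_top_set(values, q)
        assert thr == expected_thr
        assert {v for v in values if v >= thr} == expected_set

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            top_fraction_threshold([None, float("nan")])


def _windows_with_means(means, inside_flags, width=1000):
    wins, regions = [], []
    for i, m in enumerate(means):
        wins.append(FstWindow("2L", i * width, (i + 1) * width, 1, m, m))
        if inside_flags[i]:
            regions.append(("2L", i * width, (i + 1) * width, "focal"))
    return wins, pd.DataFrame(regions, columns=["chrom", "start", "end", "label"])


class TestEnrichment:
    def test_all_windows_inside_gives_proportion_one(self):
        wins, regions = _windows_with_means([0.1, 0.2, 0.9, 0.8], [1, 1, 1, 1])
        res = region_enrichment(wins, regions, "focal", q=0.5)
        assert res.proportion_top_inside == 1.0

    def test_region_absent_from_top_gives_zero(self):
        means = [0.9, 0.8, 0.1, 0.05, 0.02, 0.01]
        wins, regions = _windows_with_means(means, [0, 0, 1, 1, 0, 0])
        res = region_enrichment(wins, regions, "focal", q=0.34)
        assert res.proportion_top_inside == 0.0

    def test_hand_built_two_by_two_table(self):
        # 100 windows, 20 inside, top-5 set has 3 inside -> [[3,2],[17,78]]
        means = np.linspace(0.0, 0.99, 100)
        inside = np.zeros(100, dtype=bool)
        inside[[99, 98, 97]] = True  # 3 of the top five
        inside[:17] = True  # 17 low windows
        wins, regions = _windows_with_means(means.tolist(), inside.tolist())
        res = region_enrichment(wins, regions, "focal", q=0.05)
        assert res.proportion_top_inside == pytest.approx(0.6)
        np.testing.assert_array_equal(res.table, [[3, 2], [17, 78]])
        assert res.chi_square == pytest.approx(pearson_chi2_oracle([[3, 2], [17, 78]]))
        assert res.df == 1

    def test_no_defined_windows_rejected(self):
        wins = [FstWindow("2L", 0, 1000, 0, None, None)]
        with pytest.raises(ValueError):
            region_enrichment(wins, pd.DataFrame(columns=["chrom", "start", "end", "label"]), "x")
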