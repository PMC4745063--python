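"""Hotspot calling, intersections, gene content, rate test, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import colocmap as cm
from colocmap import (
    call_hotspots,
    genes_in_windows,
    ora_enrichment,
    overlap_hotspots,
    rate_test,
)
from colocmap.hotspots import HotspotSet
from colocmap.quantify import FeatureWindowMatrix
from colocmap.windows import make_windows
from conftest import make_track


def matrix_from_levels(levels: pd.DataFrame) -> FeatureWindowMatrix:
    layout = cm.GenomeLayout((("chrT", len(levels) * 100),))
    grid = make_windows(layout, 100)
    return FeatureWindowMatrix(grid, grid.windows[["chrom", "start", "end"]], levels)


class TestCallHotspots:
    def test_top_5_of_100_distinct_levels(self, rng):
        v = rng.permutation(np.arange(100, dtype=float))
        m = matrix_from_levels(pd.DataFrame({"A": v}))
        hs = call_hotspots(m, "A", q=0.05)
        assert len(hs) == 5
        assert hs.window_ids == frozenset(np.argsort(v)[-5:].tolist())
        assert hs.threshold == sorted(v)[-5]

    def test_ceiling_rule_small_n(self, rng):
        v = rng.normal(size=20)
        m = matrix_from_levels(pd.DataFrame({"A": v}))
        assert len(call_hotspots(m, "A", q=0.05)) == 1  # ceil(1.0)

    def test_every_member_level_geq_every_nonmember(self, rng):
        v = rng.poisson(50, size=200).astype(float)
        m = matrix_from_levels(pd.DataFrame({"A": v}))
        hs = call_hotspots(m, "A", q=0.05)
        members = sorted(hs.window_ids)
        others = [i for i in range(200) if i not in hs.window_ids]
        assert v[members].min() >= v[others].max()

    def test_boundary_ties_resolved_by_genomic_order(self):
        v = np.array([5.0, 9.0, 5.0, 5.0, 1.0, 2.0, 9.0, 5.0, 0.0, 3.0])
        m = matrix_from_levels(pd.DataFrame({"A": v}))
        hs = call_hotspots(m, "A", q=0.3)  # ceil(3) = 3: two 9s then first 5
        assert hs.window_ids == frozenset({1, 6, 0})

    def test_constant_feature_rejected(self):
        m = matrix_from_levels(pd.DataFrame({"A": np.ones(10)}))
        with pytest.raises(ValueError, match="constant"):
            call_hotspots(m, "A")

    def test_invariant_under_positive_affine_rescaling(self, rng):
        v = rng.gamma(3.0, 2.0, size=100)
        m0 = matrix_from_levels(pd.DataFrame({"A": v}))
        m1 = matrix_from_levels(pd.DataFrame({"A": 7.5 * v + 3.0}))
        assert (
            call_hotspots(m0, "A").window_ids == call_hotspots(m1, "A").window_ids
        )

    def test_planted_tenfold_windows_recovered_exactly(self, rng):
        counts = rng.poisson(100, size=200).astype(float)
        planted = rng.choice(200, size=10, replace=False)
        counts[planted] *= 10
        m = matrix_from_levels(pd.DataFrame({"A": counts}))
        hs = call_hotspots(m, "A", q=0.05)
        assert hs.window_ids == frozenset(int(i) for i in planted)


def hs(name, ids, q=0.05):
    return HotspotSet(name, q, 0.0, frozenset(ids))


class TestOverlapHotspots:
    def test_pairwise_double(self):
        ov = overlap_hotspots([hs("a", {1, 2, 3}), hs("b", {3, 4})])
        assert ov.double == {3}

    def test_three_identical_sets_triple_equals_set(self):
        ids = {2, 5, 9}
        ov = overlap_hotspots([hs("a", ids), hs("b", ids), hs("c", ids)])
        assert ov.triple == ids

    def test_double_bounded_by_smallest_set_and_triple_by_double(self, rng):
        sets = [hs(n, set(rng.choice(50, size=k, replace=False)))
                for n, k in (("a", 10), ("b", 7), ("c", 12))]
        ov = overlap_hotspots(sets)
        assert len(ov.triple) <= len(ov.double)
        for a, b in itertools.combinations("abc", 2):
            assert len(ov.pair_intersection(a, b)) <= min(len(s) for s in sets)

    def test_venn_segments_match_enumeration_and_sum_to_zone_union(self, rng):
        """Venn decomposition on a 50-window toy vs brute-force membership counts."""
        levels = pd.DataFrame({f: rng.gamma(2, 1, size=50) for f in ("g1", "p1", "d1")})
        model = cm.ZoneModel((("Genic", ("g1",)), ("Proximal", ("p1",)), ("Distal", ("d1",))))
        matrix = matrix_from_levels(levels)
        assign = cm.classify_windows(matrix, model)
        sets = [hs(n, set(rng.choice(50, size=8, replace=False))) for n in ("a", "b", "c")]
        ov = overlap_hotspots(sets, assign)
        membership = {w: frozenset(n for n in "abc" if w in ov.sets[n])
                      for w in set().union(*ov.sets.values())}
        for zone in ("Genic", "Proximal", "Distal"):
            for pat in ["a", "b", "c", "a&b", "a&c", "b&c", "a&b&c"]:
                expected = sum(
                    1
                    for w, ms in membership.items()
                    if ms == frozenset(pat.split("&")) and assign.labels[w] == zone
                )
                assert ov.venn.loc[zone, pat] == expected
            union_in_zone = sum(1 for w in membership if assign.labels[w] == zone)
            assert ov.venn.loc[zone].sum() == union_in_zone


class TestGenesInWindows:
    def test_gene_inside_window_included(self):
        genes = make_track("genes", [("chrT", 100, 200)])
        genes.intervals["name"] = ["geneA"]
        windows = pd.DataFrame([("chrT", 0, 500_000)], columns=["chrom", "start", "end"])
        assert genes_in_windows(genes, windows) == ["geneA"]

    def test_boundary_spanning_gene_counted_once(self):
        genes = make_track("genes", [("chrT", 499_999, 500_050)])
        genes.intervals["name"] = ["geneA"]
        windows = pd.DataFrame(
            [("chrT", 0, 500_000), ("chrT", 500_000, 1_000_000)],
            columns=["chrom", "start", "end"],
        )
        assert genes_in_windows(genes, windows) == ["geneA"]

    def test_unnamed_gene_rejected(self):
        genes = make_track("genes", [("chrT", 0, 10)])
        windows = pd.DataFrame([("chrT", 0, 100)], columns=["chrom", "start", "end"])
        with pytest.raises(ValueError, match="unnamed"):
            genes_in_windows(genes, windows)

    def test_matches_per_gene_brute_force_scan(self, rng):
        n = 300
        starts = rng.integers(0, 990_000, size=n)
        ends = starts + rng.integers(1, 40_000, size=n)
        ends = np.minimum(ends, 1_000_000)
        genes = make_track("genes", list(zip(["chrT"] * n, starts, ends)))
        genes.intervals["name"] = [f"g{i}" for i in range(n)]
        win_ids = rng.choice(20, size=7, replace=False)
        windows = pd.DataFrame(
            [("chrT", int(i) * 50_000, (int(i) + 1) * 50_000) for i in win_ids],
            columns=["chrom", "start", "end"],
        )
        expected = set()
        for _, g in genes.intervals.iterrows():
            for _, w in windows.iterrows():
                if max(g["start"], w["start"]) < min(g["end"], w["end"]):
                    expected.add(g["name"])
        assert genes_in_windows(genes, windows) == sorted(expected)


class TestRateTest:
    def test_identical_groups_give_t0_p1(self):
        v = np.array([1.0, 2.0, 3.0, 2.5])
        rt = rate_test(v, v.copy())
        assert rt.t == pytest.approx(0.0)
        assert rt.p == pytest.approx(1.0)

    def test_printed_summaries_reproduce_reported_p(self):
        """Welch from (2.444±1.430, n=54) vs (1.237±0.984, n=5414) gives
        p ~ 8.8e-8, matching the reported value to summary rounding."""
        rt = rate_test((1.237, 0.984, 5414), (2.444, 1.430, 54))
        assert rt.p == pytest.approx(8.84e-8, rel=0.05)

    def test_agrees_with_scipy_welch_from_stats(self):
        ref = stats.ttest_ind_from_stats(
            2.444, 1.430, 54, 1.237, 0.984, 5414, equal_var=False
        )
        rt = rate_test((1.237, 0.984, 5414), (2.444, 1.430, 54))
        assert rt.t == pytest.approx(ref.statistic)
        assert rt.p == pytest.approx(ref.pvalue)

    def test_raw_vectors_match_permutation_oracle(self, rng):
        group = np.array([3.1, 2.7, 3.9, 4.2, 2.9, 3.3, 3.8, 3.5])
        background = np.array([2.1, 2.4, 1.9, 2.6, 2.2, 2.0])
        rt = rate_test(background, group)
        pooled = np.concatenate([group, background])
        B = 100_000
        g = np.random.default_rng(0)
        stats_perm = np.empty(B)
        for i in range(B):
            perm = g.permutation(pooled)
            a, b = perm[: len(group)], perm[len(group):]
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            stats_perm[i] = abs((a.mean() - b.mean()) / np.sqrt(va + vb))
        p_perm = np.mean(stats_perm >= abs(rt.t) - 1e-12)
        assert rt.p == pytest.approx(p_perm, abs=0.01)

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            rate_test(np.arange(5.0), (2.0, 1.0, 1))


class TestOraEnrichment:
    def test_exact_combinatorial_case(self):
        """Universe 10, list 5, set 5, full overlap: p = 1/C(10,5) = 1/252."""
        universe = [f"g{i}" for i in range(10)]
        res = ora_enrichment(universe[:5], universe, {"s": universe[:5]})
        assert res.loc[0, "p"] == pytest.approx(1 / math.comb(10, 5))

    def test_disjoint_set_has_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = ora_enrichment(universe[:5], universe, {"s": universe[5:]})
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_null_calibration_of_uncorrected_p(self, rng):
        """Random sets under the null: ~5% reach uncorrected p < 0.05."""
        universe = [f"g{i}" for i in range(400)]
        gene_list = list(rng.choice(universe, size=60, replace=False))
        hits = 0
        total = 0
        for rep in range(50):
            sets = {
                f"s{rep}_{i}": list(rng.choice(universe, size=25, replace=False))
                for i in range(20)
            }
            res = ora_enrichment(gene_list, universe, sets)
            hits += int((res["p"] < 0.05).sum())
            total += len(res)
        assert hits / total < 0.08

    def test_significance_needs_all_three_corrections(self, rng):
        universe = [f"g{i}" for i in range(100)]
        gene_list = universe[:20]
        sets = {"hot": universe[:15], "cold": universe[60:80]}
        res = ora_enrichment(gene_list, universe, sets).set_index("gene_set")
        row = res.loc["hot"]
        assert bool(row["significant"]) == (
            row["p_bonferroni"] < 0.05
            and row["p_benjamini"] < 0.05
            and row["q_fdr"] < 0.05
        )

    def test_ordered_by_ascending_bonferroni(self, rng):
        universe = [f"g{i}" for i in range(200)]
        gene_list = universe[:30]
        sets = {f"s{i}": list(rng.choice(universe, size=20, replace=False)) for i in range(10)}
        sets["loaded"] = universe[:18]
        res = ora_enrichment(gene_list, universe, sets)
        assert res["p_bonferroni"].is_monotonic_increasing

    def test_bh_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        universe = [f"g{i}" for i in range(300)]
        gene_list = list(rng.choice(universe, size=40, replace=False))
        sets = {f"s{i}": list(rng.choice(universe, size=15, replace=False)) for i in range(12)}
        res = ora_enrichment(gene_list, universe, sets)
        np.testing.assert_allclose(
            res["p_benjamini"], multipletests(res["p"], method="fdr_bh")[1]
        )

    def test_stray_query_gene_rejected(self):
        with pytest.raises(ValueError, match="not in universe"):
            ora_enrichment(["zz"], ["g1"], {"s": ["g1"]})
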