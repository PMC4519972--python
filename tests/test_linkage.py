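"""Linkage mapping: two-point statistics, grouping, ordering, Kosambi."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svmap.genotypes import GenotypeMatrix
from svmap.linkage import (build_map, group_markers, haldane, haldane_inv,
                           kosambi, kosambi_inv, order_group,
                           summarize_map_table, two_point, two_point_table)
from svmap.simulate import random_true_map, simulate_meiosis

LOG10_2 = math.log10(2.0)


class TestMapFunctions:
    def test_kosambi_closed_forms(self):
        assert kosambi(0.0) == 0.0
        assert kosambi(0.25) == pytest.approx(25 * math.log(3), abs=1e-9)   # 27.465
        assert kosambi(0.1) == pytest.approx(25 * math.log(1.5), abs=1e-9)  # 10.137
        assert kosambi(0.5) == math.inf

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.4999))
    def test_kosambi_roundtrip(self, r):
        assert kosambi_inv(kosambi(r)) == pytest.approx(r, abs=1e-12)

    def test_kosambi_below_haldane(self):
        r = np.linspace(0.01, 0.49, 25)
        assert (kosambi(r) <= haldane(r) + 1e-12).all()

    def test_small_r_limit(self):
        for r in (1e-4, 1e-5):
            assert kosambi(r) / (100 * r) == pytest.approx(1.0, rel=1e-4)
            assert haldane(r) / (100 * r) == pytest.approx(1.0, rel=1e-3)

    def test_domain_errors(self):
        for f in (kosambi, haldane):
            with pytest.raises(ValueError):
                f(-0.01)
            with pytest.raises(ValueError):
                f(0.51)


class TestTwoPoint:
    def test_identical_columns(self):
        col = ["a", "b"] * 50
        t = two_point(col, col)
        assert t.recombinants == 0 and t.rf == 0.0
        assert t.lod == pytest.approx(100 * LOG10_2)  # ~30.103

    def test_half_recombinant(self):
        ci = ["a", "a", "b", "b"] * 25
        cj = ["a", "b", "a", "b"] * 25
        t = two_point(ci, cj)
        assert t.rf == 0.5 and t.lod == 0.0

    def test_six_strain_toy(self):
        """n=6, R=2: LOD = 2*log10(2/3) + 4*log10(4/3), by hand."""
        t = two_point(list("aabbab"), list("abbbaa"))
        assert (t.n, t.recombinants) == (6, 2)
        assert t.rf == pytest.approx(1 / 3)
        assert t.lod == pytest.approx(2 * math.log10(2 / 3) + 4 * math.log10(4 / 3))

    def test_missing_and_h_excluded(self):
        t = two_point(list("ab-hab"), list("ababab"))
        assert t.n == 4

    def test_no_informative_rows(self):
        with pytest.raises(ValueError):
            two_point(list("--"), list("ab"))

    def test_swap_symmetry(self):
        ci, cj = list("aabbabab"), list("abbbaaba")
        a, b = two_point(ci, cj), two_point(cj, ci)
        assert (a.n, a.recombinants, a.rf, a.lod) == (b.n, b.recombinants, b.rf, b.lod)

    def test_lod_decreasing_in_recombinants(self):
        n = 100
        lods = []
        for R in range(0, 50):
            ci = ["a"] * n
            cj = ["b"] * R + ["a"] * (n - R)
            lods.append(two_point(ci, cj).lod)
        assert all(x > y for x, y in zip(lods, lods[1:]))

    def test_table_matches_scalar(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.choice(list("ab-"), size=(40, 5), p=[.45, .45, .1]),
                            columns=[f"M{i}" for i in range(5)],
                            index=pd.Index([f"S{i}" for i in range(40)], name="strain"))
        gm = GenotypeMatrix(data)
        t = two_point_table(gm)
        for i, j in itertools.combinations(gm.markers, 2):
            s = two_point(gm.column(i), gm.column(j))
            assert t["recombinants"].loc[i, j] == s.recombinants
            assert t["lod"].loc[i, j] == pytest.approx(s.lod)


class TestGrouping:
    def _tables(self, seed=20, n=192):
        tm = random_true_map(n_groups=4, markers_per_group=6,
                             spacing_cm=(5, 15), seed=seed)
        gm, _ = simulate_meiosis(tm, n, seed=seed + 1)
        return tm, two_point_table(gm)

    def test_no_linkage_all_unlinked(self):
        lod = pd.DataFrame(np.zeros((3, 3)), index=list("xyz"), columns=list("xyz"))
        groups, unlinked = group_markers(lod, 3.0)
        assert groups == [] and unlinked == ["x", "y", "z"]

    def test_infinite_threshold_unlinks_everything(self):
        _, t = self._tables()
        groups, unlinked = group_markers(t["lod"], math.inf)
        assert groups == [] and len(unlinked) == 24

    def test_partition_recovers_chromosomes(self):
        tm, t = self._tables()
        groups, unlinked = group_markers(t["lod"], 3.0, max_rf=0.3, rf=t["rf"])
        assert not unlinked
        assert {frozenset(g) for g in groups} == \
            {frozenset(g.markers) for g in tm.groups}

    def test_raising_threshold_only_refines(self):
        _, t = self._tables(seed=21)
        lo_groups, lo_un = group_markers(t["lod"], 3.0)
        hi_groups, hi_un = group_markers(t["lod"], 10.0)
        lo_parts = [set(g) for g in lo_groups] + [{m} for m in lo_un]
        hi_parts = [set(g) for g in hi_groups] + [{m} for m in hi_un]
        for h in hi_parts:
            assert any(h <= l for l in lo_parts)


class TestOrdering:
    def _sim_group(self, n_markers, seed, n=100):
        rng = np.random.default_rng(seed)
        gaps = rng.uniform(3, 20, n_markers - 1)
        pos = np.concatenate([[0.0], np.cumsum(gaps)])
        ids = [f"M{i:02d}" for i in range(n_markers)]
        from svmap.linkage import GeneticMap, LinkageGroup
        shuffled = list(rng.permutation(ids))
        tm = GeneticMap(groups=[LinkageGroup("g", shuffled, np.sort(pos))])
        gm, _ = simulate_meiosis(tm, n, seed=seed + 1)
        t = two_point_table(gm)
        return ids, shuffled, t

    def test_two_markers_canonical(self):
        rf = pd.DataFrame([[0, .1], [.1, 0]], index=["b", "a"], columns=["b", "a"])
        assert order_group(["b", "a"], rf, rf * 100) == ["a", "b"]

    def test_single_marker_rejected(self):
        rf = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            order_group(["a"], rf, rf)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        """Heuristic ordering attains the brute-force optimum (<= 8 markers)."""
        n_markers = 4 + seed % 5
        ids, _, t = self._sim_group(n_markers, 100 + seed)
        order = order_group(ids, t["rf"], t["lod"])
        v = t["rf"].to_numpy()
        loc = {m: k for k, m in enumerate(t["rf"].index)}
        obj = sum(v[loc[x], loc[y]] for x, y in zip(order, order[1:]))
        best = min(sum(v[loc[x], loc[y]] for x, y in zip(p, p[1:]))
                   for p in itertools.permutations(ids))
        assert obj == pytest.approx(best, abs=1e-12)

    def test_framework_fixes_orientation(self):
        ids, truth_order, t = self._sim_group(6, 200)
        # seed with the first three markers of the true (shuffled) order
        fw = truth_order[:3]
        order = order_group(ids, t["rf"], t["lod"], framework=fw)
        assert order.index(fw[0]) < order.index(fw[1]) < order.index(fw[2])

    def test_reversal_preserves_length(self):
        ids, _, t = self._sim_group(7, 300)
        order = order_group(ids, t["rf"], t["lod"])
        rev = order[::-1]
        fwd_len = sum(kosambi(min(t["rf"].loc[x, y], 0.499))
                      for x, y in zip(order, order[1:]))
        rev_len = sum(kosambi(min(t["rf"].loc[x, y], 0.499))
                      for x, y in zip(rev, rev[1:]))
        assert fwd_len == pytest.approx(rev_len)


class TestBuildMap:
    def test_recovers_truth_at_mapping_population_scale(self):
        tm = random_true_map(n_groups=5, markers_per_group=8,
                             spacing_cm=(5, 15), seed=30)
        gm, _ = simulate_meiosis(tm, 192, seed=31)
        m = build_map(gm, lod_threshold=3.0, max_rf=0.3)
        assert len(m.groups) == 5 and not m.unlinked
        orders = {frozenset(g.markers): g.markers for g in tm.groups}
        for g in m.groups:
            truth = orders[frozenset(g.markers)]
            assert g.markers in (truth, truth[::-1])
            assert (np.diff(g.positions) >= 0).all()

    def test_adjacent_rf_within_binomial_error(self):
        tm = random_true_map(n_groups=1, markers_per_group=6,
                             spacing_cm=(8, 20), seed=32)
        n = 192
        gm, _ = simulate_meiosis(tm, n, seed=33)
        t = two_point_table(gm)
        g = tm.groups[0]
        for (m1, p1), (m2, p2) in zip(zip(g.markers, g.positions),
                                      zip(g.markers[1:], g.positions[1:])):
            r_true = haldane_inv(p2 - p1)
            se = np.sqrt(r_true * (1 - r_true) / n)
            assert abs(t["rf"].loc[m1, m2] - r_true) <= 3 * se

    def test_group_numbering_by_size(self):
        tm = random_true_map(n_groups=3, markers_per_group=4, seed=34)
        # drop one marker from one chromosome to break the tie
        tm.groups[1].markers = tm.groups[1].markers[:3]
        tm.groups[1].positions = tm.groups[1].positions[:3]
        gm, _ = simulate_meiosis(tm, 192, seed=35)
        m = build_map(gm, max_rf=0.3)
        sizes = [g.n_markers for g in m.groups]
        assert sizes == sorted(sizes, reverse=True)
        assert [g.name for g in m.groups] == ["Group 1", "Group 2", "Group 3"]


class TestSummaryRollup:
    def test_published_style_per_group_table(self):
        """Roll-up of a ten-group summary: total length, markers, spacing."""
        per_group = pd.DataFrame({
            "gd_cm": [118.211, 70.185, 38.397, 108.488, 34.148,
                      17.118, 2.681, 19.473, 1.605, 1.295],
            "n_markers": [28, 13, 8, 18, 10, 6, 5, 5, 5, 4],
            "n_scaffolds": [10, 4, 6, 7, 2, 5, 1, 3, 1, 4],
            "scaffold_kb": [4543, 2742, 661, 3136, 2395, 391, 391, 3460, 880, 1048],
        })
        out = summarize_map_table(per_group)
        assert out["total_cm"] == pytest.approx(411.601)
        assert out["n_markers"] == 102
        assert out["mean_spacing_cm"] == pytest.approx(4.035)
        assert out["n_scaffolds"] == 43
        assert out["scaffold_kb"] == pytest.approx(19_647)
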