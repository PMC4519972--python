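"""Scaffold anchoring, genome statistics, conflicts, recombination scan."""

import numpy as np
import pandas as pd
import pytest

from svmap.anchor import (anchor_scaffolds, detect_conflicts, gene_content,
                          genome_stats, recombination_scan)
from svmap.linkage import GeneticMap, LinkageGroup
from svmap.simulate import simulate_annotation


def _map_one_group(markers, positions, name="Group 1"):
    return GeneticMap(groups=[LinkageGroup(name, list(markers),
                                           np.asarray(positions, float))])


def _coords(rows):
    return pd.DataFrame(rows, columns=["marker", "scaffold", "bp"])


class TestAnchoring:
    def test_majority_assignment_and_sizes(self):
        gmap = GeneticMap(groups=[
            LinkageGroup("Group 1", ["m1", "m2", "m3"], np.array([0., 5., 9.])),
            LinkageGroup("Group 2", ["m4", "m5"], np.array([0., 3.]))])
        coords = _coords([("m1", "s1", 1000), ("m2", "s1", 9000),
                          ("m3", "s2", 500), ("m4", "s3", 100),
                          ("m5", "s3", 4000)])
        anchors, per_group = anchor_scaffolds(
            gmap, coords, {"s1": 20_000, "s2": 5_000, "s3": 8_000})
        assign = {a.scaffold: a.group for a in anchors}
        assert assign == {"s1": "Group 1", "s2": "Group 1", "s3": "Group 2"}
        sizes = per_group.set_index("group")["scaffold_kb"]
        assert sizes["Group 1"] == 25.0 and sizes["Group 2"] == 8.0
        # anchored size per group is the exact sum of member scaffold lengths
        assert sizes.sum() * 1000 == 33_000

    def test_orientation_from_rank_correlation(self):
        gmap = _map_one_group(["m1", "m2", "m3", "m4"], [0, 2, 5, 9])
        coords = _coords([("m1", "s1", 100), ("m2", "s1", 2000),
                          ("m3", "s2", 9000), ("m4", "s2", 300)])
        anchors, _ = anchor_scaffolds(gmap, coords, {"s1": 3000, "s2": 10_000})
        orient = {a.scaffold: a.orientation for a in anchors}
        assert orient == {"s1": "+", "s2": "-"}

    def test_single_marker_scaffold_undetermined(self):
        gmap = _map_one_group(["m1", "m2"], [0, 4])
        coords = _coords([("m1", "s1", 100), ("m2", "s2", 100)])
        anchors, _ = anchor_scaffolds(gmap, coords, {"s1": 1000, "s2": 1000})
        assert all(a.orientation == "undetermined" for a in anchors)

    def test_missing_coordinates_error(self):
        gmap = _map_one_group(["m1", "m2"], [0, 4])
        with pytest.raises(KeyError):
            anchor_scaffolds(gmap, _coords([("m1", "s1", 1)]), {"s1": 100})

    def test_recovers_simulated_chromosomes(self, mini_run):
        """Every scaffold with >= 1 mapped marker lands in the group holding
        its true chromosome."""
        scaffolds = mini_run["genomes"].scaffolds.set_index("scaffold")
        group_to_chrom = {}
        for a in mini_run["anchors"]:
            chrom = scaffolds.loc[a.scaffold, "chromosome"]
            group_to_chrom.setdefault(a.group, set()).add(chrom)
        assert all(len(chroms) == 1 for chroms in group_to_chrom.values())
        assert len(group_to_chrom) == mini_run["config"].simulate.n_chromosomes


class TestConflicts:
    def test_interleaved_marker(self):
        gmap = _map_one_group(["y1", "x1", "y2"], [0, 0.4, 0.7])
        coords = _coords([("y1", "s30", 10), ("x1", "s97", 20), ("y2", "s30", 90)])
        rep = detect_conflicts(gmap, coords)
        assert len(rep) == 1
        row = rep.iloc[0]
        assert row["scaffold"] == "s30" and row["interlopers"] == "s97"
        assert row["cm_gap"] == pytest.approx(0.7)

    def test_contiguous_scaffolds_no_conflict(self):
        gmap = _map_one_group(["a1", "a2", "b1", "b2"], [0, 1, 2, 3])
        coords = _coords([("a1", "sA", 1), ("a2", "sA", 2),
                          ("b1", "sB", 1), ("b2", "sB", 2)])
        assert len(detect_conflicts(gmap, coords)) == 0

    def test_matches_quadratic_oracle_on_shuffles(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            labels = list(rng.choice(["sA", "sB", "sC", "sD"], size=20))
            markers = [f"m{i}" for i in range(20)]
            gmap = _map_one_group(markers, np.arange(20.0))
            coords = _coords([(m, s, i * 100)
                              for i, (m, s) in enumerate(zip(markers, labels))])
            got = len(detect_conflicts(gmap, coords))
            # oracle: scan every scaffold's consecutive-occurrence gaps
            expected = 0
            for y in set(labels):
                idx = [i for i, l in enumerate(labels) if l == y]
                expected += sum(
                    1 for i1, i2 in zip(idx, idx[1:])
                    if any(labels[j] != y for j in range(i1 + 1, i2)))
            assert got == expected


class TestGenomeStats:
    def _anchors(self, n, group="Group 1", kb=100):
        from svmap.anchor import ScaffoldAnchor
        return [ScaffoldAnchor(f"s{i}", kb * 1000, group,
                               pd.DataFrame(columns=["marker", "cm", "bp"]),
                               "undetermined") for i in range(n)]

    def test_scaffold_reduction_published_case(self):
        """43 scaffolds anchored on 10 groups out of 302 -> 269 left."""
        groups = [LinkageGroup(f"Group {i+1}", ["a", "b"], np.array([0., 1.]))
                  for i in range(10)]
        gmap = GeneticMap(groups=groups)
        anchors = []
        from svmap.anchor import ScaffoldAnchor
        per_group = [10, 4, 6, 7, 2, 5, 1, 3, 1, 4]
        kb = [4543, 2742, 661, 3136, 2395, 391, 391, 3460, 880, 1048]
        k = 0
        for gi, (n, size) in enumerate(zip(per_group, kb)):
            for j in range(n):
                share = size * 1000 // n + (size * 1000 % n if j == 0 else 0)
                anchors.append(ScaffoldAnchor(
                    f"s{k}", share, f"Group {gi+1}",
                    pd.DataFrame(columns=["marker", "cm", "bp"]), "+"))
                k += 1
        # give the map the published total length
        gmap.groups[0].positions = np.array([0.0, 411.601])
        for g in gmap.groups[1:]:
            g.positions = np.array([0.0, 0.0])
        s = genome_stats(gmap, anchors, genome_size=37_200_000,
                         original_scaffold_count=302)
        assert s.anchored_scaffolds == 43
        assert s.anchored_kb == pytest.approx(19_647)
        assert s.reduced_scaffolds == 269
        assert s.kb_per_cm == pytest.approx(47.7)
        assert s.coverage_pct == pytest.approx(52.8)

    def test_zero_anchored_keeps_original_count(self):
        gmap = _map_one_group(["m1", "m2"], [0, 10])
        s = genome_stats(gmap, [], genome_size=1_000_000,
                         original_scaffold_count=50)
        assert s.reduced_scaffolds == 50 and s.anchored_scaffolds == 0

    def test_more_anchored_than_original_rejected(self):
        gmap = _map_one_group(["m1", "m2"], [0, 10])
        with pytest.raises(ValueError):
            genome_stats(gmap, self._anchors(5), 1_000_000, 3)


class TestRecombinationScan:
    def test_published_hot_and_cold_examples(self):
        """28.9 cM over 242.6 kb is ~5.7x the genome mean (hot); 5.6 cM over
        666 kb is ~0.40x -- normal at the 1/3 default, cold at 0.45."""
        markers = ["m1", "m2", "m3", "m4"]
        pos = [0.0, 28.9, 28.9 + 377.101, 411.601]
        gmap = _map_one_group(markers, pos)
        coords = _coords([("m1", "s1", 0), ("m2", "s1", 242_600),
                          ("m3", "s1", 242_600 + 18_738_400),
                          ("m4", "s1", 19_647_000)])
        scan = recombination_scan(gmap, coords).set_index("left_marker")
        assert scan.loc["m1", "label"] == "hot"
        assert scan.loc["m1", "ratio_to_mean"] == pytest.approx(5.69, abs=0.01)
        assert scan.loc["m3", "label"] == "normal"
        assert scan.loc["m3", "ratio_to_mean"] == pytest.approx(0.40, abs=0.01)
        relaxed = recombination_scan(gmap, coords, cold_factor=0.45)
        assert relaxed.set_index("left_marker").loc["m3", "label"] == "cold"

    def test_uniform_map_all_normal(self):
        markers = [f"m{i}" for i in range(6)]
        gmap = _map_one_group(markers, np.arange(6) * 5.0)
        coords = _coords([(m, "s1", i * 100_000) for i, m in enumerate(markers)])
        scan = recombination_scan(gmap, coords)
        assert (scan["label"] == "normal").all()

    def test_cross_scaffold_intervals_skipped(self):
        gmap = _map_one_group(["m1", "m2"], [0, 5])
        coords = _coords([("m1", "s1", 0), ("m2", "s2", 100)])
        assert len(recombination_scan(gmap, coords)) == 0


class TestGeneContent:
    def _anchor(self, scaffold):
        from svmap.anchor import ScaffoldAnchor
        return ScaffoldAnchor(scaffold, 1000, "Group 1",
                              pd.DataFrame(columns=["marker", "cm", "bp"]), "+")

    def test_counts_and_fraction(self):
        ann = pd.DataFrame({"gene_id": [f"g{i}" for i in range(100)],
                            "scaffold": ["s1"] * 40 + ["s2"] * 60,
                            "start": 0, "end": 10, "strand": "+"})
        n, frac, per = gene_content([self._anchor("s1")], ann)
        assert n == 40 and frac == pytest.approx(0.4)

    def test_empty_annotation(self):
        n, frac, _ = gene_content([self._anchor("s1")], pd.DataFrame())
        assert n == 0 and frac == 0.0

    def test_order_and_strand_invariance(self):
        rng = np.random.default_rng(5)
        ann = pd.DataFrame({"gene_id": [f"g{i}" for i in range(50)],
                            "scaffold": rng.choice(["s1", "s2", "s3"], 50),
                            "start": 0, "end": 10,
                            "strand": rng.choice(["+", "-"], 50)})
        anchors = [self._anchor("s1"), self._anchor("s3")]
        n1, _, _ = gene_content(anchors, ann)
        shuffled = ann.sample(frac=1, random_state=1).assign(strand="-")
        n2, _, _ = gene_content(anchors, shuffled)
        assert n1 == n2

    def test_unknown_scaffold_rejected(self):
        ann = pd.DataFrame({"gene_id": ["g1"], "scaffold": ["weird"],
                            "start": [0], "end": [10], "strand": ["+"]})
        with pytest.raises(KeyError):
            gene_content([self._anchor("s1")], ann, known_scaffolds={"s1"})

    def test_simulated_annotation_is_deterministic(self, tiny):
        a1 = simulate_annotation(tiny.genomes.scaffolds, n_genes=60, seed=8)
        a2 = simulate_annotation(tiny.genomes.scaffolds, n_genes=60, seed=8)
        pd.testing.assert_frame_equal(a1, a2)
        assert len(a1) == 60
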