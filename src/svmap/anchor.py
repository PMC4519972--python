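"""Scaffold anchoring: tie assembly scaffolds to linkage groups.

Every mapped marker has both a map position (cM) and a physical position
(scaffold, bp), so scaffolds can be assigned to the linkage group holding the
majority of their markers, oriented by the rank correlation between genetic
and physical positions, and rolled up into genome-scale statistics: map
coverage, physical-per-genetic distance (kb/cM), the scaffold-count reduction
achieved by merging each group's scaffolds into a super-scaffold, interleaving
conflicts, and recombination hot/cold intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import GeneticMap

__all__ = ["ScaffoldAnchor", "GenomeMapStats", "anchor_scaffolds",
           "detect_conflicts", "genome_stats", "recombination_scan",
           "gene_content"]


@dataclass
class ScaffoldAnchor:
    scaffold: str
    length: int
    group: str
    markers: pd.DataFrame        # marker, cm, bp
    orientation: str             # '+', '-' or 'undetermined'

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class GenomeMapStats:
    total_cm: float
    anchored_scaffolds: int
    anchored_kb: float
    genome_size_bp: int
    coverage_pct: float          # 100 * anchored size / genome size
    kb_per_cm: float
    original_scaffolds: int
    reduced_scaffolds: int


def _marker_positions(gmap: GeneticMap) -> pd.DataFrame:
    return gmap.to_frame().set_index("marker")


def anchor_scaffolds(gmap: GeneticMap, marker_coords: pd.DataFrame,
                     scaffold_lengths: dict[str, int],
                     ) -> tuple[list[ScaffoldAnchor], pd.DataFrame]:
    """Assign scaffolds to linkage groups via their mapped markers.

    ``marker_coords`` needs columns ``marker``, ``scaffold``, ``bp``.  A
    scaffold joins the group containing the majority of its markers (ties to
    the lower-numbered group); orientation is the sign of the Spearman rank
    correlation between cM and bp, determined only with >= 2 markers.
    Returns the anchors and a per-group summary (scaffold count, total kb).
    """
    coords = marker_coords.set_index("marker")
    mp = _marker_positions(gmap)
    mapped = mp.join(coords, how="left")
    if mapped["scaffold"].isna().any():
        missing = mapped.index[mapped["scaffold"].isna()].tolist()
        raise KeyError(f"markers lacking scaffold coordinates: {missing}")

    anchors = []
    group_order = [g.name for g in gmap.groups]
    for scaffold, sub in mapped.groupby("scaffold", sort=True):
        counts = sub["group"].value_counts()
        best = max(counts.items(),
                   key=lambda kv: (kv[1], -group_order.index(kv[0])))[0]
        members = sub[sub["group"] == best]
        tbl = (members.reset_index()[["marker", "position_cm", "bp"]]
               .rename(columns={"position_cm": "cm"})
               .sort_values("cm").reset_index(drop=True))
        if len(tbl) >= 2 and tbl["bp"].nunique() > 1 and tbl["cm"].nunique() > 1:
            rho = stats.spearmanr(tbl["cm"], tbl["bp"]).statistic
            orient = "+" if rho > 0 else "-" if rho < 0 else "undetermined"
        else:
            orient = "undetermined"
        if scaffold not in scaffold_lengths:
            raise KeyError(f"no length for scaffold {scaffold}")
        anchors.append(ScaffoldAnchor(scaffold, int(scaffold_lengths[scaffold]),
                                      best, tbl, orient))

    rows = []
    for gname in group_order:
        mine = [a for a in anchors if a.group == gname]
        rows.append({"group": gname, "n_scaffolds": len(mine),
                     "scaffold_kb": round(sum(a.length for a in mine) / 1000.0, 3)})
    return anchors, pd.DataFrame(rows)


def detect_conflicts(gmap: GeneticMap, marker_coords: pd.DataFrame,
                     ) -> pd.DataFrame:
    """Report scaffold interleaving on the map.

    A conflict is a maximal run of markers from other scaffolds separating
    two consecutive markers of one scaffold within a group.  Columns:
    group, scaffold, left_marker, right_marker, interlopers, cm_gap.
    """
    scaf = marker_coords.set_index("marker")["scaffold"]
    rows = []
    for g in gmap.groups:
        labels = [scaf.get(m) for m in g.markers]
        for y in sorted(set(labels)):
            idx = [i for i, l in enumerate(labels) if l == y]
            for i1, i2 in zip(idx, idx[1:]):
                between = {labels[j] for j in range(i1 + 1, i2)} - {y}
                if between:
                    rows.append({
                        "group": g.name, "scaffold": y,
                        "left_marker": g.markers[i1],
                        "right_marker": g.markers[i2],
                        "interlopers": ",".join(sorted(between)),
                        "cm_gap": round(float(g.positions[i2] - g.positions[i1]), 3),
                    })
    return pd.DataFrame(rows, columns=["group", "scaffold", "left_marker",
                                       "right_marker", "interlopers", "cm_gap"])


def genome_stats(gmap: GeneticMap, anchors: list[ScaffoldAnchor],
                 genome_size: int, original_scaffold_count: int,
                 ) -> GenomeMapStats:
    """Genome-scale roll-up of the anchored map.

    The reduced scaffold count merges each group's anchored scaffolds into
    one super-scaffold: original - anchored + groups with >= 1 anchor.
    """
    if len(anchors) > original_scaffold_count:
        raise ValueError("more anchored scaffolds than the assembly has")
    total_cm = gmap.total_length_cm
    anchored_kb = sum(a.length for a in anchors) / 1000.0
    groups_hit = len({a.group for a in anchors})
    return GenomeMapStats(
        total_cm=round(total_cm, 3),
        anchored_scaffolds=len(anchors),
        anchored_kb=round(anchored_kb, 3),
        genome_size_bp=int(genome_size),
        coverage_pct=round(100.0 * anchored_kb * 1000.0 / genome_size, 1),
        kb_per_cm=round(anchored_kb / total_cm, 1) if total_cm else float("nan"),
        original_scaffolds=int(original_scaffold_count),
        reduced_scaffolds=int(original_scaffold_count - len(anchors) + groups_hit),
    )


def recombination_scan(gmap: GeneticMap, marker_coords: pd.DataFrame,
                       hot_factor: float = 3.0, cold_factor: float = 1 / 3,
                       ) -> pd.DataFrame:
    """Label intervals between adjacent same-scaffold markers hot or cold.

    The rate of an interval is its cM span per kb of scaffold; an interval is
    ``hot`` at >= hot_factor times the mean rate over all scanned intervals,
    ``cold`` at <= cold_factor times, else ``normal``.
    """
    coords = marker_coords.set_index("marker")
    rows = []
    for g in gmap.groups:
        for (m1, p1), (m2, p2) in zip(zip(g.markers, g.positions),
                                      zip(g.markers[1:], g.positions[1:])):
            s1, s2 = coords.loc[m1, "scaffold"], coords.loc[m2, "scaffold"]
            if s1 != s2:
                continue
            kb = abs(int(coords.loc[m2, "bp"]) - int(coords.loc[m1, "bp"])) / 1000.0
            if kb == 0:
                continue
            rows.append({"group": g.name, "left_marker": m1, "right_marker": m2,
                         "scaffold": s1, "cm": round(float(p2 - p1), 3),
                         "kb": round(kb, 3)})
    df = pd.DataFrame(rows, columns=["group", "left_marker", "right_marker",
                                     "scaffold", "cm", "kb"])
    if not len(df):
        df["cm_per_mb"] = df["ratio_to_mean"] = df["label"] = []
        return df
    mean_rate = df["cm"].sum() / df["kb"].sum()  # genome-average cM per kb
    rate = df["cm"] / df["kb"]
    df["cm_per_mb"] = (rate * 1000).round(2)
    df["ratio_to_mean"] = (rate / mean_rate).round(3)
    df["label"] = np.select([df["ratio_to_mean"] >= hot_factor,
                             df["ratio_to_mean"] <= cold_factor],
                            ["hot", "cold"], default="normal")
    return df


def gene_content(anchors: list[ScaffoldAnchor], annotation: pd.DataFrame,
                 known_scaffolds: set[str] | None = None,
                 ) -> tuple[int, float, pd.DataFrame]:
    """Genes landing on anchored scaffolds.

    ``annotation`` needs columns ``gene_id`` and ``scaffold`` (e.g. from
    :func:`svmap.io.read_gff3_genes`).  Returns (count, fraction of all
    genes, per-scaffold counts).  Gene order and strand are irrelevant.
    """
    if not len(annotation):
        return 0, 0.0, pd.DataFrame(columns=["scaffold", "n_genes"])
    if known_scaffolds is not None:
        bad = set(annotation["scaffold"]) - set(known_scaffolds)
        if bad:
            raise KeyError(f"annotation references unknown scaffolds: {sorted(bad)}")
    anchored = {a.scaffold for a in anchors}
    on = annotation[annotation["scaffold"].isin(anchored)]
    per = (on.groupby("scaffold", sort=True)["gene_id"].count()
           .rename("n_genes").reset_index())
    frac = len(on) / len(annotation)
    return int(len(on)), float(frac), per
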