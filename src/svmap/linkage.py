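"""Genetic-map construction for haploid co-dominant marker data.

Two-point linkage statistics, LOD-threshold grouping, marker ordering and
Kosambi map distances.  The data model is the classic haploid mapping cross:
every progeny is a single meiotic product scored ``a`` (reference parent) or
``b`` (donor parent) at each marker, so the recombination fraction between two
markers is estimated directly as the proportion of progeny whose alleles
differ, and the two-point LOD is

    LOD = R*log10(2*r) + (n-R)*log10(2*(1-r)),   r = R/n (capped at 0.5),

with LOD = n*log10(2) when R = 0.  Grouping places markers in the same linkage
group when they are connected by pairwise LOD >= threshold (single linkage);
an optional maximum-rf co-requirement guards against spurious large-n links.
Map distances use Kosambi's function d = 25*ln((1+2r)/(1-2r)) centimorgans.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TwoPointResult",
    "LinkageGroup",
    "GeneticMap",
    "two_point",
    "two_point_table",
    "group_markers",
    "order_group",
    "kosambi",
    "kosambi_inv",
    "haldane",
    "haldane_inv",
    "build_map",
    "summarize_map_table",
]

LOG10_2 = np.log10(2.0)


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi(r):
    """Kosambi map distance in cM for recombination fraction ``r``.

    d = 25 * ln((1 + 2r) / (1 - 2r)).  Returns +inf for r >= 0.5.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    with np.errstate(divide="ignore"):
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inv(d):
    """Inverse Kosambi: cM -> recombination fraction, r = tanh(d/50)/2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def haldane(r):
    """Haldane map distance in cM (no interference), d = -50*ln(1-2r)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    with np.errstate(divide="ignore"):
        d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


def haldane_inv(d):
    """Inverse Haldane: r = (1 - exp(-d/50)) / 2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# two-point statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPointResult:
    marker_i: str
    marker_j: str
    n: int          # progeny scored a/b at both markers
    recombinants: int
    rf: float       # R/n capped at 0.5
    lod: float


def _lod_from_counts(R, n):
    """Vectorised two-point LOD for haploid data; rf capped at 0.5."""
    R = np.asarray(R, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.minimum(np.where(n > 0, R / n, np.nan), 0.5)
        term_r = np.where(R > 0, R * np.log10(2.0 * r), 0.0)
        term_nr = np.where(n - R > 0, (n - R) * np.log10(2.0 * (1.0 - r)), 0.0)
        lod = term_r + term_nr
    return r, np.maximum(lod, 0.0)


def two_point(col_i, col_j, name_i: str = "i", name_j: str = "j") -> TwoPointResult:
    """Two-point linkage between two genotype columns (codes a/b/h/-).

    Only rows scored ``a`` or ``b`` at both markers are informative.
    """
    gi = np.asarray(col_i, dtype=object)
    gj = np.asarray(col_j, dtype=object)
    if gi.shape != gj.shape:
        raise ValueError("genotype columns must have equal length")
    ok = np.isin(gi, ("a", "b")) & np.isin(gj, ("a", "b"))
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no progeny informative for both markers")
    R = int(np.sum(gi[ok] != gj[ok]))
    r, lod = _lod_from_counts(R, n)
    return TwoPointResult(name_i, name_j, n, R, float(r), float(lod))


def two_point_table(matrix) -> dict[str, pd.DataFrame]:
    """All-pairs two-point statistics for a genotype matrix.

    ``matrix`` is a :class:`svmap.genotypes.GenotypeMatrix` or a DataFrame of
    codes (rows = strains, columns = markers).  Returns square DataFrames
    ``n``, ``recombinants``, ``rf`` and ``lod`` indexed by marker id.
    """
    df = matrix.data if hasattr(matrix, "data") else matrix
    markers = list(df.columns)
    arr = df.to_numpy(dtype="U1")
    is_a = (arr == "a").astype(float)
    valid = ((arr == "a") | (arr == "b")).astype(float)
    is_b = valid - is_a
    n = valid.T @ valid
    R = is_a.T @ is_b + is_b.T @ is_a
    rf, lod = _lod_from_counts(R, n)
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, 0.0)
    wrap = lambda m: pd.DataFrame(m, index=markers, columns=markers)
    return {"n": wrap(n.astype(int)), "recombinants": wrap(R.astype(int)),
            "rf": wrap(rf), "lod": wrap(lod)}


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def group_markers(lod: pd.DataFrame, lod_threshold: float = 3.0,
                  max_rf: float | None = None, rf: pd.DataFrame | None = None,
                  ) -> tuple[list[list[str]], list[str]]:
    """Partition markers into linkage groups by pairwise LOD.

    Groups are the connected components of the graph with an edge wherever
    LOD >= ``lod_threshold`` (and, when ``max_rf`` is given, rf <= max_rf).
    Components of size one are returned separately as unlinked markers.
    """
    markers = list(lod.index)
    g = nx.Graph()
    g.add_nodes_from(markers)
    lodv = lod.to_numpy()
    edge = lodv >= lod_threshold
    if max_rf is not None:
        if rf is None:
            raise ValueError("max_rf requires the rf table")
        edge &= rf.to_numpy() <= max_rf
    ii, jj = np.nonzero(np.triu(edge, k=1))
    g.add_edges_from((markers[i], markers[j]) for i, j in zip(ii, jj))
    groups, unlinked = [], []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            groups.append(sorted(comp))
        else:
            unlinked.extend(comp)
    groups.sort(key=lambda ms: (-len(ms), ms[0]))
    return groups, sorted(unlinked)


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def _order_objective(order: list[int], v: np.ndarray) -> float:
    idx = np.asarray(order)
    return float(v[idx[:-1], idx[1:]].sum())


def _best_insertion(order: list[int], marker: int, v: np.ndarray) -> list[int]:
    best, best_obj = None, np.inf
    for pos in range(len(order) + 1):
        cand = order[:pos] + [marker] + order[pos:]
        obj = _order_objective(cand, v)
        # ties broken toward the telomeric (left) end deterministically
        if obj < best_obj - 1e-12:
            best, best_obj = cand, obj
    return best


def _ripple(order: list[int], v: np.ndarray, max_window: int = 5,
            max_rounds: int = 50) -> list[int]:
    """Sliding-window permutation polish until no improvement.

    The window starts at 3 and widens (to ``max_window``) only when the
    narrower pass has converged, so the classic window-3 ripple is always
    subsumed; the wider windows escape its rare local optima.
    """
    order = list(order)
    window = 3
    for _ in range(max_rounds):
        improved = False
        w = min(window, len(order))
        for i in range(max(1, len(order) - w + 1)):
            head, seg, tail = order[:i], order[i:i + w], order[i + w:]
            best_seg, best_obj = seg, _order_objective(order, v)
            for perm in itertools.permutations(seg):
                obj = _order_objective(head + list(perm) + tail, v)
                if obj < best_obj - 1e-12:
                    best_seg, best_obj = list(perm), obj
            if best_seg != seg:
                order = head + best_seg + tail
                improved = True
        if improved:
            window = 3
        elif window < max_window:
            window += 1
        else:
            return order
    return order


def _seed_triple(idx: list[int], v: np.ndarray, lv: np.ndarray) -> list[int]:
    """Highest-total-LOD triple, ordered exhaustively by the rf objective."""
    if len(idx) == 3:
        triple = tuple(idx)
    elif len(idx) <= 25:
        triple = max(itertools.combinations(idx, 3),
                     key=lambda t: lv[t[0], t[1]] + lv[t[0], t[2]] + lv[t[1], t[2]])
    else:  # greedy for very large groups: best pair, then best third
        sub = lv[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, -np.inf)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        rest = [k for k in range(len(idx)) if k not in (i, j)]
        k = max(rest, key=lambda k: sub[i, k] + sub[j, k])
        triple = (idx[i], idx[j], idx[k])
    return min((list(p) for p in itertools.permutations(triple)),
               key=lambda p: (_order_objective(p, v), p))


def order_group(markers: list[str], rf: pd.DataFrame, lod: pd.DataFrame,
                framework: list[str] | None = None) -> list[str]:
    """Order the markers of one linkage group.

    A framework (markers of known relative order, e.g. from physical
    positions) seeds the order; otherwise the highest-LOD triple does.
    Remaining markers are inserted one at a time, most-informative first, at
    the position minimising the sum of adjacent recombination fractions, and
    a widening-window permutation pass polishes the result until no
    improvement.  The final order is canonicalised (first id < last id)
    unless a framework fixed the orientation.
    """
    markers = list(markers)
    if len(markers) < 2:
        raise ValueError("a linkage group needs at least 2 markers")
    if len(markers) == 2:
        return sorted(markers)

    all_ids = list(rf.index)
    loc = {m: all_ids.index(m) for m in markers}
    v = rf.to_numpy()
    lv = lod.to_numpy()

    oriented = False
    if framework:
        seed = [m for m in framework if m in markers]
        if len(seed) >= 2:
            oriented = True
        else:
            seed = None
    else:
        seed = None
    if seed is None:
        seed_idx = _seed_triple([loc[m] for m in markers], v, lv)
    else:
        seed_idx = [loc[m] for m in seed]

    remaining = [loc[m] for m in markers if loc[m] not in seed_idx]
    order = list(seed_idx)
    while remaining:
        # most informative next: highest LOD to any placed marker, ties by id
        remaining.sort(key=lambda i: (-float(lv[i, order].max()), all_ids[i]))
        order = _best_insertion(order, remaining.pop(0), v)
    order = _ripple(order, v)
    named = [all_ids[i] for i in order]
    if not oriented and named[0] > named[-1]:
        named.reverse()
    return named


# ---------------------------------------------------------------------------
# the map
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroup:
    name: str
    markers: list[str]
    positions: np.ndarray  # cumulative Kosambi cM, non-decreasing

    @property
    def length_cm(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    unlinked: list[str] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    @property
    def total_length_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))

    def to_frame(self) -> pd.DataFrame:
        rows = [(g.name, rank + 1, m, round(float(p), 3))
                for g in self.groups
                for rank, (m, p) in enumerate(zip(g.markers, g.positions))]
        return pd.DataFrame(rows, columns=["group", "rank", "marker", "position_cm"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unlinked: list[str] | None = None,
                   ) -> "GeneticMap":
        groups = []
        for name, sub in df.groupby("group", sort=False):
            sub = sub.sort_values("rank")
            groups.append(LinkageGroup(str(name), list(sub["marker"]),
                                       sub["position_cm"].to_numpy(float)))
        return cls(groups=groups, unlinked=list(unlinked or []))

    def summary(self) -> pd.DataFrame:
        """Per-group roll-up: length, marker count, mean spacing (GD / n)."""
        rows = [{"group": g.name, "gd_cm": round(g.length_cm, 3),
                 "n_markers": g.n_markers,
                 "avg_spacing_cm": round(g.length_cm / g.n_markers, 2)}
                for g in self.groups]
        return pd.DataFrame(rows)


def summarize_map_table(per_group: pd.DataFrame) -> dict[str, float]:
    """Totals over a per-group summary table (columns ``gd_cm``, ``n_markers``,
    optionally ``n_scaffolds`` / ``scaffold_kb``).

    Mean spacing is total length / total markers, reported to 3 decimals.
    """
    out = {
        "total_cm": round(float(per_group["gd_cm"].sum()), 3),
        "n_markers": int(per_group["n_markers"].sum()),
    }
    out["mean_spacing_cm"] = round(out["total_cm"] / out["n_markers"], 3)
    if "n_scaffolds" in per_group:
        out["n_scaffolds"] = int(per_group["n_scaffolds"].sum())
    if "scaffold_kb" in per_group:
        out["scaffold_kb"] = round(float(per_group["scaffold_kb"].sum()), 3)
    return out


def build_map(matrix, lod_threshold: float = 3.0, max_rf: float | None = None,
              framework: dict[str, list[str]] | list[str] | None = None,
              ) -> GeneticMap:
    """Construct a genetic map from a filtered homokaryon genotype matrix.

    Composes two-point statistics -> LOD grouping -> per-group ordering ->
    adjacent Kosambi distances -> cumulative positions.  ``framework`` may be
    a single ordered marker list (applied to whichever group contains its
    markers) or ``None``.  Groups are numbered by descending marker count,
    then descending length.
    """
    tables = two_point_table(matrix)
    rf, lod = tables["rf"], tables["lod"]
    raw_groups, unlinked = group_markers(lod, lod_threshold, max_rf=max_rf, rf=rf)
    built = []
    for members in raw_groups:
        fw = list(framework) if framework else None
        order = order_group(members, rf, lod, framework=fw)
        adj = np.array([rf.loc[a, b] for a, b in zip(order, order[1:])])
        adj = np.minimum(adj, 0.4999999)  # adjacent pairs are linked by construction
        pos = np.concatenate([[0.0], np.cumsum(kosambi(adj))])
        built.append((order, pos))
    built.sort(key=lambda op: (-len(op[0]), -float(op[1][-1]), op[0][0]))
    groups = [LinkageGroup(f"Group {i + 1}", order, pos)
              for i, (order, pos) in enumerate(built)]
    return GeneticMap(groups=groups, unlinked=unlinked)
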