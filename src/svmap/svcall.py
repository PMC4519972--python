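"""Structural-variant detection from discordant read-pair signatures.

A paired-end library with a known insert-size distribution constrains every
properly mapped pair: forward/reverse (FR) orientation with a reference-frame
outer span close to the library mean.  Pairs violating the expectation signal
a structural difference between the sequenced strain and the reference:

* FR with the span stretched beyond mean + k*sd  -> deletion in the donor
* FR with the span shrunk below mean - k*sd      -> insertion in the donor
* both mates on the same strand                  -> inversion breakpoint
* everted (reverse/forward) orientation          -> tandem duplication
* one mate unmapped                              -> novel (donor-only) sequence

Discordant pairs of one signature whose breakpoint intervals overlap are
clustered; clusters meeting the support threshold become SV loci, and
overlapping clusters of conflicting signatures merge into a single
``complex`` locus.  Breakpoints and lengths are estimated from the cluster's
pair geometry (median implied size change for deletion/insertion, strand-
specific boundary statistics for inversion/duplication).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AlignedPair", "InsertModel", "SVLocus", "SVCallSet",
           "classify_pair", "classify_pairs", "fit_insert_model",
           "call_svs", "summarize_calls", "class_table", "SV_CLASSES"]

SV_CLASSES = ("insertion", "deletion", "duplication", "inversion", "complex")
SIGNATURES = ("concordant", "del_like", "ins_like", "inv_like", "dup_like",
              "one_end_unmapped")


@dataclass(frozen=True)
class AlignedPair:
    """One aligned read pair in reference coordinates (0-based, half-open)."""
    scaffold: str
    pos1: int
    end1: int
    strand1: str
    mapped1: bool
    pos2: int
    end2: int
    strand2: str
    mapped2: bool
    insert: int  # reference-frame outer span; -1 unless both mates mapped


@dataclass(frozen=True)
class InsertModel:
    """Concordance window for the library: FR pairs with
    |insert - mean| <= k*sd are concordant."""
    mean: float
    sd: float
    k: float = 3.0

    def __post_init__(self):
        if self.sd <= 0 or self.k <= 0:
            raise ValueError("sd and k must be positive")


@dataclass(frozen=True)
class SVLocus:
    scaffold: str
    start: int
    end: int
    kind: str
    length: int
    support: int
    length_is_lower_bound: bool = False

    def __post_init__(self):
        if self.end < self.start or self.length <= 0 or self.support <= 0:
            raise ValueError("invalid SV locus")


@dataclass
class SVCallSet:
    loci: list[SVLocus] = field(default_factory=list)

    def __len__(self):
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def n_scaffolds(self) -> int:
        return len({l.scaffold for l in self.loci})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"scaffold": l.scaffold, "start": l.start, "end": l.end,
              "type": l.kind, "length": l.length, "support": l.support,
              "length_is_lower_bound": l.length_is_lower_bound}
             for l in self.loci],
            columns=["scaffold", "start", "end", "type", "length", "support",
                     "length_is_lower_bound"])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pairs(pairs: pd.DataFrame, model: InsertModel) -> pd.Series:
    """Vectorised signature assignment; see :func:`classify_pair`."""
    m1 = pairs["mapped1"].to_numpy(bool)
    m2 = pairs["mapped2"].to_numpy(bool)
    s1 = pairs["strand1"].to_numpy()
    s2 = pairs["strand2"].to_numpy()
    p1 = pairs["pos1"].to_numpy()
    p2 = pairs["pos2"].to_numpy()
    ins = pairs["insert"].to_numpy(float)

    left_strand = np.where(p1 <= p2, s1, s2)
    right_strand = np.where(p1 <= p2, s2, s1)
    lo = model.mean - model.k * model.sd
    hi = model.mean + model.k * model.sd

    out = np.full(len(pairs), "unmapped", dtype=object)
    one = m1 ^ m2
    out[one] = "one_end_unmapped"
    both = m1 & m2
    same = both & (s1 == s2)
    out[same] = "inv_like"
    fr = both & (left_strand == "+") & (right_strand == "-")
    rf = both & (left_strand == "-") & (right_strand == "+")
    out[rf & ~same] = "dup_like"
    out[fr & (ins > hi)] = "del_like"
    out[fr & (ins < lo)] = "ins_like"
    out[fr & (ins >= lo) & (ins <= hi)] = "concordant"
    return pd.Series(out, index=pairs.index, name="signature")


def classify_pair(pair, model: InsertModel) -> str:
    """Signature of a single pair: concordant / del_like / ins_like /
    inv_like / dup_like / one_end_unmapped (or 'unmapped' when neither mate
    mapped)."""
    if isinstance(pair, AlignedPair):
        pair = pd.DataFrame([pair.__dict__])
    else:
        pair = pd.DataFrame([pair])
    return str(classify_pairs(pair, model).iloc[0])


def fit_insert_model(pairs: pd.DataFrame, k: float = 3.0,
                     min_pairs: int = 1000) -> InsertModel:
    """Robust insert-size model from FR-oriented pairs.

    Location/scale are the median and 1.4826*MAD, so a moderate fraction of
    discordant contamination does not bias the concordance window.
    """
    m = pairs["mapped1"] & pairs["mapped2"]
    left_plus = np.where(pairs["pos1"] <= pairs["pos2"],
                         pairs["strand1"], pairs["strand2"]) == "+"
    right_minus = np.where(pairs["pos1"] <= pairs["pos2"],
                           pairs["strand2"], pairs["strand1"]) == "-"
    fr = pairs.loc[m & left_plus & right_minus, "insert"].to_numpy(float)
    if len(fr) < min_pairs:
        raise ValueError(f"only {len(fr)} FR pairs (< {min_pairs})")
    med = float(np.median(fr))
    mad = float(np.median(np.abs(fr - med)))
    sd = max(1.4826 * mad, 1e-6)
    return InsertModel(mean=med, sd=sd, k=k)


# ---------------------------------------------------------------------------
# clustering and calling
# ---------------------------------------------------------------------------

def _breakpoint_intervals(df: pd.DataFrame, sig: np.ndarray) -> pd.DataFrame:
    """Per-pair breakpoint interval used for clustering."""
    p1 = df["pos1"].to_numpy(np.int64)
    e1 = df["end1"].to_numpy(np.int64)
    p2 = df["pos2"].to_numpy(np.int64)
    e2 = df["end2"].to_numpy(np.int64)
    m1 = df["mapped1"].to_numpy(bool)
    swap = (p2 < p1) & df["mapped2"].to_numpy(bool) & m1
    lp = np.where(swap, p2, p1)
    le = np.where(swap, e2, e1)
    rp = np.where(swap, p1, p2)
    re = np.where(swap, e1, e2)

    lo = np.where(sig == "dup_like", lp, le)           # inner end of left read
    hi = np.select([sig == "del_like", sig == "ins_like"],
                   [rp, rp], default=re)               # start/end of right read
    # unmapped-mate pairs: a point anchor at the mapped read's inner edge
    one = sig == "one_end_unmapped"
    anchor_fwd = np.where(m1, df["strand1"] == "+", df["strand2"] == "+")
    apos = np.where(m1, p1, p2)
    aend = np.where(m1, e1, e2)
    lo = np.where(one, np.where(anchor_fwd, aend, apos), lo)
    hi = np.where(one, lo, hi)
    hi = np.maximum(hi, lo)
    out = df[["scaffold"]].copy()
    out["lo"], out["hi"] = lo, hi
    out["left_pos"], out["left_end"] = lp, le
    out["right_pos"], out["right_end"] = rp, re
    out["anchor_fwd"] = anchor_fwd
    return out


def _chain(intervals: pd.DataFrame, max_gap: int) -> list[pd.DataFrame]:
    iv = intervals.sort_values(["lo", "hi"], kind="mergesort")
    clusters, cur = [], []
    cur_end = None
    for row in iv.itertuples():
        if cur and row.lo > cur_end + max_gap:
            clusters.append(pd.DataFrame(cur))
            cur = []
            cur_end = None
        cur.append(row._asdict())
        cur_end = row.hi if cur_end is None else max(cur_end, row.hi)
    if cur:
        clusters.append(pd.DataFrame(cur))
    return clusters


def _resolve_type(signatures: set[str]) -> str:
    if signatures == {"del_like"}:
        return "deletion"
    if signatures <= {"ins_like", "one_end_unmapped"}:
        return "insertion"
    if signatures <= {"dup_like", "ins_like"}:
        return "duplication"
    if signatures == {"inv_like"}:
        return "inversion"
    return "complex"


def _trim_by_insert(cluster: pd.DataFrame, model: InsertModel) -> pd.DataFrame:
    """Drop cluster members whose insert is inconsistent with the cluster.

    Pairs spanning one size-changing event share insert ~ N(mean + delta, sd);
    a chance borderline-discordant pair chained into the cluster deviates from
    the cluster median by far more than k*sd and would corrupt the min/max
    boundary statistics.
    """
    med = float(np.median(cluster["insert"]))
    keep = (cluster["insert"] - med).abs() <= model.k * model.sd
    return cluster[keep] if keep.any() else cluster


def _estimate(kind: str, members: list[tuple[str, pd.DataFrame]],
              model: InsertModel, rl_hint: int) -> tuple[int, int, int, bool]:
    """(start, end, length, lower_bound) for a merged cluster."""
    bysig = {}
    for sig, df in members:
        bysig.setdefault(sig, []).append(df)
    bysig = {s: pd.concat(dfs, ignore_index=True) for s, dfs in bysig.items()}
    all_df = pd.concat(bysig.values(), ignore_index=True)
    lo_all = int(all_df["lo"].min())
    hi_all = int(all_df["hi"].max())

    if kind == "deletion":
        d = _trim_by_insert(bysig["del_like"], model)
        L = max(1, int(round(float(np.median(d["insert"])) - model.mean)))
        s_lo = int(d["left_end"].max())
        s_hi = int(d["right_pos"].min()) - L
        s = max(s_lo, (s_lo + s_hi) // 2) if s_hi >= s_lo else s_lo
        return s, s + L, L, False
    if kind == "insertion":
        if "ins_like" in bysig:
            d = _trim_by_insert(bysig["ins_like"], model)
            L = max(1, int(round(model.mean - float(np.median(d["insert"])))))
            q = (int(d["left_end"].max()) + int(d["right_pos"].min())) // 2
            return q, q, L, False
        d = bysig["one_end_unmapped"]
        q = int(np.median(d["lo"]))
        L = max(1, int(round(model.mean - 2 * rl_hint)))
        return q, q, L, True
    if kind == "inversion":
        d = bysig["inv_like"]
        fwd = d[d["pair_strand"] == "+"]
        rev = d[d["pair_strand"] == "-"]
        s = int(fwd["left_end"].max()) if len(fwd) else lo_all
        e = int(rev["right_pos"].min()) if len(rev) else hi_all
        if e <= s:
            s, e = lo_all, max(hi_all, lo_all + 1)
        return s, e, e - s, False
    if kind == "duplication":
        d = bysig["dup_like"]
        s = int(d["left_pos"].min())
        e = int(d["right_end"].max())
        return s, max(e, s + 1), max(e - s, 1), False
    # complex: span of the merged evidence
    return lo_all, max(hi_all, lo_all + 1), max(hi_all - lo_all, 1), False


def call_svs(pairs: pd.DataFrame, model: InsertModel, min_support: int = 6,
             max_cluster_gap: int = 150) -> SVCallSet:
    """Cluster discordant pairs into SV loci.

    ``pairs`` must be sorted by (scaffold, leftmost mapped position).  Pairs
    of one signature whose breakpoint intervals lie within ``max_cluster_gap``
    of each other chain into a cluster; clusters with support below
    ``min_support`` (default 6 = "more than 5 pairs") are discarded, and
    surviving clusters of conflicting signatures that overlap merge into one
    ``complex`` locus.  Loci are sorted by (scaffold, start, type).
    """
    required = {"scaffold", "pos1", "end1", "strand1", "mapped1",
                "pos2", "end2", "strand2", "mapped2", "insert"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pair table lacks columns: {sorted(missing)}")
    key = np.where(pairs["mapped1"] & pairs["mapped2"],
                   np.minimum(pairs["pos1"], pairs["pos2"]),
                   np.where(pairs["mapped1"], pairs["pos1"], pairs["pos2"]))
    # fully unmapped records carry no position; they sort last by convention
    key = np.where(pairs["mapped1"] | pairs["mapped2"], key,
                   np.iinfo(np.int64).max)
    scaf = pairs["scaffold"].to_numpy()
    order_ok = all(
        (key[np.nonzero(scaf == s)[0]][:-1] <= key[np.nonzero(scaf == s)[0]][1:]).all()
        for s in pd.unique(scaf)) if len(pairs) else True
    if not order_ok:
        raise ValueError("pairs must be sorted by scaffold and position")

    sig = classify_pairs(pairs, model).to_numpy()
    disc = np.isin(sig, ("del_like", "ins_like", "inv_like", "dup_like",
                         "one_end_unmapped"))
    if not disc.any():
        return SVCallSet([])
    df = pairs.loc[disc].reset_index(drop=True)
    sig = sig[disc]
    iv = _breakpoint_intervals(df, sig)
    iv["insert"] = df["insert"].to_numpy()
    # for inversion estimation: which breakpoint a same-strand pair spans
    iv["pair_strand"] = np.where(df["strand1"].to_numpy() == "+", "+", "-")
    rl_hint = int(np.median((df["end1"] - df["pos1"])[df["mapped1"]])) \
        if df["mapped1"].any() else 100

    loci = []
    for scaffold, sub in iv.assign(signature=sig).groupby("scaffold", sort=True):
        clusters = []  # (sig, lo, hi, frame)
        for s in SIGNATURES[1:]:
            part = sub[sub["signature"] == s]
            if not len(part):
                continue
            for cl in _chain(part, max_cluster_gap):
                if len(cl) >= min_support:
                    clusters.append((s, int(cl["lo"].min()),
                                     int(cl["hi"].max()), cl))
        # merge overlapping clusters across signatures
        clusters.sort(key=lambda c: (c[1], c[2]))
        merged: list[list] = []
        for c in clusters:
            if merged and c[1] <= merged[-1][1] + max_cluster_gap:
                merged[-1][0].append((c[0], c[3]))
                merged[-1][1] = max(merged[-1][1], c[2])
            else:
                merged.append([[(c[0], c[3])], c[2]])
        for members, _hi in merged:
            kind = _resolve_type({s for s, _ in members})
            start, end, length, lb = _estimate(kind, members, model, rl_hint)
            support = int(sum(len(d) for _, d in members))
            loci.append(SVLocus(scaffold, max(start, 0), max(end, start),
                                kind, length, support, lb))
    loci.sort(key=lambda l: (l.scaffold, l.start, l.kind))
    return SVCallSet(loci)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def class_table(counts: dict[str, int], lengths: dict[str, int]) -> pd.DataFrame:
    """Per-class roll-up: count, rate (%) and total length, plus grand totals.

    Rates are 100 * count / total rounded to 2 decimals; totals are exact
    sums.  An empty table reports zeros.
    """
    rows = []
    total = sum(counts.get(k, 0) for k in SV_CLASSES)
    for k in SV_CLASSES:
        n = int(counts.get(k, 0))
        rate = round(100.0 * n / total, 2) if total else 0.0
        rows.append({"sv_kind": k, "number": n, "rate": rate,
                     "length": int(lengths.get(k, 0))})
    rows.append({"sv_kind": "Total", "number": total, "rate": 100.0 if total else 0.0,
                 "length": int(sum(lengths.get(k, 0) for k in SV_CLASSES))})
    return pd.DataFrame(rows)


def summarize_calls(calls: SVCallSet) -> pd.DataFrame:
    """Summarise a call set per SV class (count, rate %, total length)."""
    counts = {k: 0 for k in SV_CLASSES}
    lengths = {k: 0 for k in SV_CLASSES}
    for l in calls:
        counts[l.kind] += 1
        lengths[l.kind] += l.length
    return class_table(counts, lengths)
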