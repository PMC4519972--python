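"""Co-dominant PCR markers from SV loci.

An SV locus distinguishes the two parental haploid genomes by length.  A
primer pair placed on the flanking sequence (300 bp each side by default)
amplifies a product from *both* parents with the same primers; the two
products differ in size by the SV's length change, so a single PCR scores
every strain co-dominantly: reference-parent band, donor-parent band, or both
bands in a heterokaryon carrying the two nuclear types.

Primer thermodynamics are out of scope: the outer edges of the two flank
windows stand in for the primer sites, which preserves the amplicon-size
arithmetic.  Site uniqueness is enforced by exact search of the 20 bp flank
tips genome-wide in each parent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .svcall import SVCallSet, SVLocus

__all__ = ["SVMarker", "filter_candidate_loci", "predict_amplicons",
           "score_codominance", "design_markers", "band_profile",
           "attrition_table", "markers_to_frame"]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SVMarker:
    """A candidate or effective co-dominant marker derived from one SV locus.

    ``size_a`` is the predicted amplicon in the reference parent, ``size_b``
    in the donor.  ``status`` is ``candidate``, ``effective`` or ``rejected``
    with a ``reason``.
    """
    marker_id: str
    locus: SVLocus
    flank: int
    left_start: int      # reference coordinate of the left primer site
    right_end: int       # reference coordinate just past the right primer site
    status: str = "candidate"
    reason: str | None = None
    size_a: int | None = None
    size_b: int | None = None


def filter_candidate_loci(calls: SVCallSet, reference: dict[str, str],
                          min_len: int = 200, max_len: int = 800,
                          flank: int = 300) -> list[SVMarker]:
    """Select marker-suitable SV loci.

    A locus is rejected when its length falls outside [min_len, max_len]
    (bounds inclusive), when any N/gap character occurs within the locus or
    its flanks, or when a flank extends past the scaffold end.  Marker ids
    are assigned in locus order (SV001, SV002, ...).
    """
    out = []
    for i, locus in enumerate(calls):
        if locus.scaffold not in reference:
            raise KeyError(f"no reference sequence for {locus.scaffold}")
        seq = reference[locus.scaffold]
        mid = f"SV{i + 1:03d}"
        lo, hi = locus.start - flank, locus.end + flank
        status, reason = "candidate", None
        if not (min_len <= locus.length <= max_len):
            status, reason = "rejected", "length"
        elif lo < 0 or hi > len(seq):
            status, reason = "rejected", "edge"
        elif any(c not in "ACGT" for c in seq[lo:hi]):
            status, reason = "rejected", "gap"
        out.append(SVMarker(mid, locus, flank, max(lo, 0), min(hi, len(seq)),
                            status=status, reason=reason))
    return out


def _unique_site(genomes: dict[str, str], tip: str) -> tuple[str, int] | None:
    """Locate an exact 20-mer genome-wide; None unless it occurs exactly once."""
    hit = None
    for name, seq in genomes.items():
        start = 0
        while True:
            i = seq.find(tip, start)
            if i < 0:
                break
            if hit is not None:
                return None
            hit = (name, i)
            start = i + 1
    return hit


def predict_amplicons(marker: SVMarker, reference: dict[str, str],
                      donor: dict[str, str], tip: int = 20) -> SVMarker:
    """Predict the amplicon size in each parent by exact primer-site search.

    The primer sites are the ``tip``-bp outer edges of the two flanks.  Each
    site must occur exactly once in a parent, on the same scaffold and in
    amplifiable orientation; otherwise the marker is rejected
    (``non_specific`` for multi-hit sites, ``no_unique_product`` for a site
    lost in the donor).  For a pure deletion of L bp in the donor,
    size_a - size_b = L.
    """
    if marker.status == "rejected":
        return marker
    ref_seq = reference[marker.locus.scaffold]
    left_tip = ref_seq[marker.left_start:marker.left_start + tip]
    right_tip = ref_seq[marker.right_end - tip:marker.right_end]

    sizes = {}
    for label, genome in (("a", reference), ("b", donor)):
        left = _unique_site(genome, left_tip)
        right = _unique_site(genome, right_tip)
        if left is None or right is None:
            n_left = sum(g.count(left_tip) for g in genome.values())
            n_right = sum(g.count(right_tip) for g in genome.values())
            reason = "non_specific" if max(n_left, n_right) > 1 else "no_unique_product"
            return replace(marker, status="rejected", reason=reason)
        if left[0] != right[0] or right[1] + tip <= left[1]:
            return replace(marker, status="rejected", reason="no_unique_product")
        sizes[label] = right[1] + tip - left[1]
    return replace(marker, size_a=sizes["a"], size_b=sizes["b"])


def score_codominance(size_a: int, size_b: int, abs_min: int = 20,
                      rel_min: float = 0.05) -> str:
    """'effective' when the two parental bands are gel-resolvable.

    The bands must differ by at least max(abs_min, rel_min * smaller size);
    otherwise 'rejected'.  The heterokaryon profile of an effective marker is
    the union of the two bands.
    """
    if size_a is None or size_b is None:
        raise ValueError("both amplicon sizes must be defined")
    threshold = max(abs_min, rel_min * min(size_a, size_b))
    return "effective" if abs(size_a - size_b) >= threshold else "rejected"


def band_profile(marker: SVMarker, strain: str) -> set[int]:
    """Predicted gel bands for 'a' (reference parent), 'b' (donor) or 'h'
    (heterokaryon = both nuclei, both bands)."""
    if marker.size_a is None or marker.size_b is None:
        raise ValueError("marker has no predicted amplicons")
    return {"a": {marker.size_a}, "b": {marker.size_b},
            "h": {marker.size_a, marker.size_b}}[strain]


def design_markers(calls: SVCallSet, reference: dict[str, str],
                   donor: dict[str, str], min_len: int = 200,
                   max_len: int = 800, flank: int = 300, tip: int = 20,
                   abs_min: int = 20, rel_min: float = 0.05) -> list[SVMarker]:
    """Full marker design: locus filtering, in-silico amplification and
    co-dominance scoring.  Returns every marker with its final status."""
    out = []
    for marker in filter_candidate_loci(calls, reference, min_len, max_len, flank):
        if marker.status != "rejected":
            marker = predict_amplicons(marker, reference, donor, tip)
        if marker.status != "rejected":
            verdict = score_codominance(marker.size_a, marker.size_b,
                                        abs_min, rel_min)
            if verdict == "effective":
                marker = replace(marker, status="effective")
            else:
                marker = replace(marker, status="rejected",
                                 reason="indistinguishable")
        out.append(marker)
    return out


def attrition_table(markers: list[SVMarker]) -> pd.DataFrame:
    """Bookkeeping: candidates = effective + one row per rejection reason."""
    rows = [{"status": "total", "count": len(markers)},
            {"status": "effective",
             "count": sum(m.status == "effective" for m in markers)}]
    reasons = pd.Series([m.reason for m in markers if m.status == "rejected"])
    for reason, n in reasons.value_counts().items():
        rows.append({"status": f"rejected({reason})", "count": int(n)})
    return pd.DataFrame(rows)


def markers_to_frame(markers: list[SVMarker]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"marker": m.marker_id, "scaffold": m.locus.scaffold,
          "start": m.locus.start, "end": m.locus.end, "type": m.locus.kind,
          "sv_length": m.locus.length, "size_a": m.size_a, "size_b": m.size_b,
          "status": m.status, "reason": m.reason or ""}
         for m in markers],
        columns=["marker", "scaffold", "start", "end", "type", "sv_length",
                 "size_a", "size_b", "status", "reason"])
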