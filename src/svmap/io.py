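"""Readers and writers for the pipeline's on-disk formats.

FASTA through Bio.SeqIO, SAM through pysam, GFF3 genes through gffutils,
tabular stage outputs as TSV through pandas.  All genomic coordinates are
0-based half-open in memory; SAM and GFF3 are written 1-based per their
conventions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PAIR_COLUMNS = ["pair_id", "scaffold", "pos1", "end1", "strand1", "mapped1",
                "pos2", "end2", "strand2", "mapped2", "insert"]


# -- FASTA ------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = (SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items())
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# -- pair tables --------------------------------------------------------------

def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    pairs[PAIR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"strand1": str, "strand2": str,
                            "mapped1": bool, "mapped2": bool})
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair TSV lacks columns: {sorted(missing)}")
    return df


# -- SAM ----------------------------------------------------------------------

def write_sam(pairs: pd.DataFrame, scaffold_lengths: dict[str, int], path,
              read_length: int | None = None) -> None:
    """Write the pair table as SAM with correct FLAG orientation bits.

    Sequences/qualities are omitted ('*'); the alignment geometry (position,
    strand, mate info, TLEN) carries all the information the caller uses.
    """
    names = list(scaffold_lengths)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": n, "LN": int(scaffold_lengths[n])} for n in names]}
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in pairs.itertuples(index=False):
            for mate in (1, 2):
                a = pysam.AlignedSegment(out.header)
                a.query_name = row.pair_id
                mapped = row.mapped1 if mate == 1 else row.mapped2
                omapped = row.mapped2 if mate == 1 else row.mapped1
                pos = row.pos1 if mate == 1 else row.pos2
                end = row.end1 if mate == 1 else row.end2
                strand = row.strand1 if mate == 1 else row.strand2
                ostrand = row.strand2 if mate == 1 else row.strand1
                opos = row.pos2 if mate == 1 else row.pos1
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if mapped:
                    a.reference_id = tid[row.scaffold]
                    a.reference_start = int(pos)
                    a.cigarstring = f"{int(end - pos)}M"
                    if strand == "-":
                        flag |= 0x10
                else:
                    flag |= 0x4
                if omapped:
                    a.next_reference_id = tid[row.scaffold]
                    a.next_reference_start = int(opos)
                    if ostrand == "-":
                        flag |= 0x20
                else:
                    flag |= 0x8
                if mapped and omapped:
                    tlen = int(row.insert)
                    a.template_length = tlen if pos <= opos else -tlen
                a.flag = flag
                out.write(a)


def read_sam_pairs(path) -> pd.DataFrame:
    """Read SAM/BAM alignments back into the pair-table layout, pairing
    mates by query name.  Output is sorted by (scaffold, leftmost position)."""
    mates: dict[str, dict] = {}
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary:
                continue
            rec = {
                "scaffold": a.reference_name if not a.is_unmapped else None,
                "pos": a.reference_start if not a.is_unmapped else -1,
                "end": a.reference_end if not a.is_unmapped else -1,
                "strand": "-" if a.is_reverse else "+",
                "mapped": not a.is_unmapped,
                "first": a.is_read1,
            }
            other = mates.pop(a.query_name, None)
            if other is None:
                mates[a.query_name] = rec
                continue
            r1, r2 = (rec, other) if rec["first"] else (other, rec)
            scaffold = r1["scaffold"] or r2["scaffold"]
            both = r1["mapped"] and r2["mapped"]
            insert = (max(r1["end"], r2["end"]) - min(r1["pos"], r2["pos"])
                      if both else -1)
            rows.append({
                "pair_id": a.query_name, "scaffold": scaffold,
                "pos1": r1["pos"], "end1": r1["end"], "strand1": r1["strand"],
                "mapped1": r1["mapped"],
                "pos2": r2["pos"], "end2": r2["end"], "strand2": r2["strand"],
                "mapped2": r2["mapped"], "insert": insert,
            })
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    key = np.where(df["mapped1"] & df["mapped2"],
                   np.minimum(df["pos1"], df["pos2"]),
                   np.where(df["mapped1"], df["pos1"], df["pos2"]))
    df["_key"] = np.where(df["mapped1"] | df["mapped2"], key,
                          np.iinfo(np.int64).max)
    df = (df.sort_values(["scaffold", "_key"], kind="mergesort")
          .drop(columns="_key").reset_index(drop=True))
    return df


# -- truth / calls / markers --------------------------------------------------

def write_variants_tsv(variants, path) -> None:
    pd.DataFrame([{"scaffold": v.scaffold, "start": v.start, "end": v.end,
                   "type": v.kind, "length": v.length, "seq": v.seq or ""}
                  for v in variants]).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_calls_bed(callset, path) -> None:
    """BED-like TSV: scaffold, start, end, type, length, support."""
    callset.to_frame().to_csv(path, sep="\t", index=False)


def write_flank_fasta(markers, reference: dict[str, str], path) -> None:
    """FASTA of each candidate/effective marker's amplified reference region
    (flank + locus + flank)."""
    seqs = {}
    for m in markers:
        if m.status == "rejected":
            continue
        seqs[m.marker_id] = reference[m.locus.scaffold][m.left_start:m.right_end]
    write_fasta(seqs, path)


# -- GFF3 ----------------------------------------------------------------------

def write_gff3_genes(annotation: pd.DataFrame, path) -> None:
    """Write a gene table (gene_id, scaffold, start, end, strand; 0-based
    half-open) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write(f"{row.scaffold}\tsvmap\tgene\t{row.start + 1}\t{row.end}\t"
                     f".\t{row.strand}\t.\tID={row.gene_id}\n")


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene records from a GFF3 file -> DataFrame(gene_id, scaffold, start,
    end, strand), 0-based half-open."""
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique")
    rows = [{"gene_id": f.id, "scaffold": f.seqid, "start": f.start - 1,
             "end": f.end, "strand": f.strand}
            for f in db.features_of_type("gene")]
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end",
                                       "strand"])


# -- anchors / AGP -------------------------------------------------------------

def write_anchors_tsv(anchors, path) -> None:
    pd.DataFrame([{"scaffold": a.scaffold, "length": a.length,
                   "group": a.group, "n_markers": a.n_markers,
                   "orientation": a.orientation}
                  for a in anchors]).to_csv(path, sep="\t", index=False)


def write_agp(anchors, path, gap: int = 100) -> None:
    """AGP-like layout: each group's scaffolds concatenated (ordered by the
    mean cM of their markers) into one super-scaffold, with fixed-size gaps."""
    by_group: dict[str, list] = {}
    for a in anchors:
        by_group.setdefault(a.group, []).append(a)
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for group in sorted(by_group, key=lambda g: int(g.split()[-1])):
            members = sorted(by_group[group],
                             key=lambda a: float(a.markers["cm"].mean()))
            obj = f"super_{group.replace(' ', '_')}"
            pos, part = 0, 1
            for i, a in enumerate(members):
                if i:
                    fh.write(f"{obj}\t{pos + 1}\t{pos + gap}\t{part}\tN\t{gap}\t"
                             f"scaffold\tyes\tmap\n")
                    pos += gap
                    part += 1
                orient = a.orientation if a.orientation in "+-" else "?"
                fh.write(f"{obj}\t{pos + 1}\t{pos + a.length}\t{part}\tW\t"
                         f"{a.scaffold}\t1\t{a.length}\t{orient}\n")
                pos += a.length
                part += 1
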