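"""Synthetic data generator: parental genome pairs, read-pair alignments,
haploid progeny.

The generator emulates the experimental design behind SV-marker mapping in a
haploid basidiomycete: a reference homokaryon assembled into scaffolds, a
second compatible homokaryon differing by a configurable spectrum of SNPs and
structural variants (insertion / deletion / duplication / inversion /
complex), a paired-end library of the donor strain expressed as alignments
against the reference, and a single-spore-isolate progeny population produced
by meioses of the heterokaryon carrying both nuclear types.

Alignments are constructed by exact coordinate liftover through the known
variant list rather than by running an aligner, so every discordant-pair
signature in the output is a deterministic consequence of the planted
variants.  Crossovers follow a no-interference (Poisson-per-Morgan) model, so
the Haldane map function is exact for this simulator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .linkage import GeneticMap, LinkageGroup

__all__ = [
    "SV_KINDS", "TrueVariant", "SimConfig", "GenomePair", "CapacityError",
    "simulate_parental_genomes", "simulate_read_pairs", "simulate_meiosis",
    "random_true_map", "simulate_annotation",
]

SV_KINDS = ("insertion", "deletion", "duplication", "inversion", "complex")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCAN"):
    _COMP[x] = y


class CapacityError(ValueError):
    """The requested variants do not fit disjointly on the scaffolds."""


@dataclass(frozen=True)
class TrueVariant:
    """One planted structural variant, in 0-based half-open reference
    coordinates on a single scaffold.

    ``length`` is the inserted/affected sequence length: the inserted length
    for insertions, otherwise the reference span.  ``seq`` carries the novel
    sequence for insertion and complex (replacement) variants.
    """
    scaffold: str
    start: int
    end: int
    kind: str
    length: int
    seq: str | None = None

    def __post_init__(self):
        if self.kind not in SV_KINDS:
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if self.length <= 0:
            raise ValueError("length must be positive")


@dataclass
class SimConfig:
    """Study conditions for one simulation.

    The library parameters mirror the sequenced-fungus setting the package
    targets: a 505 bp paired-end insert, 100 bp reads, a 192-strong haploid
    mapping population drawn from 235 single-spore isolates of which ~18% are
    heterokaryotic, and a genome-average recombination rate of ~21 cM/Mb
    (1 cM per ~47.7 kb).  Genome size defaults are a miniature (ten 300 kb
    chromosomes split into scaffolds) so that a full pipeline run stays at
    desk scale; all randomness flows from ``seed``.
    """
    n_chromosomes: int = 10
    chromosome_length: int = 300_000
    scaffolds_per_chromosome: int = 3
    sv_counts: dict[str, int] = field(default_factory=lambda: {
        "insertion": 60, "deletion": 40, "duplication": 4,
        "inversion": 2, "complex": 2})
    sv_length_ranges: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "insertion": (200, 350), "deletion": (200, 1200),
        "duplication": (500, 2000), "inversion": (500, 2000),
        "complex": (600, 1200)})
    complex_replacement_range: tuple[int, int] = (120, 200)
    snp_rate: float = 0.001
    read_length: int = 100
    insert_mean: float = 505.0
    insert_sd: float = 30.0
    coverage: float = 30.0
    seed: int = 0
    n_progeny: int = 235
    heterokaryon_rate: float = 0.18
    missing_rate: float = 0.02
    cm_per_mb: float = 21.0
    min_sv_gap: int = 2500
    edge_margin: int = 1500

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.scaffolds_per_chromosome < 1:
            raise ValueError("scaffolds_per_chromosome must be >= 1")
        for k, v in self.sv_counts.items():
            if k not in SV_KINDS or v < 0:
                raise ValueError(f"bad SV count {k}={v}")
        for k, (lo, hi) in self.sv_length_ranges.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad SV length range for {k}")
        if not 0 <= self.snp_rate < 1:
            raise ValueError("snp_rate must be in [0, 1)")
        if self.insert_mean <= 2 * self.read_length:
            raise ValueError("insert mean must exceed twice the read length")
        if self.insert_sd <= 0 or self.coverage < 0 or self.read_length < 20:
            raise ValueError("bad library parameters")
        if self.n_progeny < 0:
            raise ValueError("n_progeny must be >= 0")
        if not (0 <= self.heterokaryon_rate <= 1 and 0 <= self.missing_rate <= 1):
            raise ValueError("rates must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GenomePair:
    """Reference + donor genomes with complete ground truth.

    ``donor_maps`` gives, per scaffold, two arrays over donor positions: the
    mapped reference position (-1 for donor-only sequence) and the strand
    (+1 identity, -1 inverted, 0 unmapped) -- the liftover used to construct
    read alignments.
    """
    reference: dict[str, str]
    donor: dict[str, str]
    variants: list[TrueVariant]
    snps: pd.DataFrame              # scaffold, pos, ref, alt
    scaffolds: pd.DataFrame         # scaffold, length, chromosome, chrom_offset
    donor_maps: dict[str, tuple[np.ndarray, np.ndarray]]
    config: SimConfig

    def scaffold_lengths(self) -> dict[str, int]:
        return dict(zip(self.scaffolds["scaffold"], self.scaffolds["length"]))


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def _scaffold_layout(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 1
    for c in range(1, config.n_chromosomes + 1):
        k = config.scaffolds_per_chromosome
        w = rng.uniform(0.7, 1.3, k)
        lens = np.floor(config.chromosome_length * w / w.sum()).astype(int)
        lens[-1] += config.chromosome_length - int(lens.sum())
        off = 0
        for L in lens:
            rows.append({"scaffold": f"scaffold_{idx:03d}", "length": int(L),
                         "chromosome": c, "chrom_offset": off})
            off += int(L)
            idx += 1
    return pd.DataFrame(rows)


def _draw_variant_specs(config: SimConfig, rng: np.random.Generator) -> list[dict]:
    specs = []
    for kind in SV_KINDS:
        n = config.sv_counts.get(kind, 0)
        lo, hi = config.sv_length_ranges.get(kind, (200, 800))
        for _ in range(n):
            L = int(rng.integers(lo, hi + 1))
            spec = {"kind": kind, "length": L}
            spec["span"] = 0 if kind == "insertion" else L
            if kind == "complex":
                rlo, rhi = config.complex_replacement_range
                spec["alt_len"] = int(rng.integers(rlo, rhi + 1))
            elif kind == "insertion":
                spec["alt_len"] = L
            else:
                spec["alt_len"] = 0
            specs.append(spec)
    rng.shuffle(specs)
    return specs


def _allocate(specs: list[dict], scaffolds: pd.DataFrame, config: SimConfig,
              rng: np.random.Generator) -> dict[str, list[dict]]:
    """Distribute variants across scaffolds proportionally to usable length
    (largest-remainder), then place within each scaffold with a minimum gap."""
    usable = (scaffolds["length"] - 2 * config.edge_margin).clip(lower=0).to_numpy(float)
    if usable.sum() <= 0 and specs:
        raise CapacityError("scaffolds too short for the edge margin")
    quota = usable / usable.sum() * len(specs)
    counts = np.floor(quota).astype(int)
    rem = len(specs) - counts.sum()
    for i in np.argsort(-(quota - counts))[:rem]:
        counts[i] += 1
    out: dict[str, list[dict]] = {}
    it = iter(specs)
    for (_, row), c in zip(scaffolds.iterrows(), counts):
        mine = [next(it) for _ in range(c)]
        if not mine:
            continue
        total_span = sum(s["span"] for s in mine)
        free = (row["length"] - 2 * config.edge_margin - total_span
                - (len(mine) - 1) * config.min_sv_gap)
        if free < 0:
            raise CapacityError(
                f"{row['scaffold']}: {len(mine)} variants need more space than "
                f"{row['length']} bp allows (short by {-free} bp)")
        gaps = rng.uniform(0, 1, len(mine) + 1)
        gaps = np.floor(gaps / gaps.sum() * free).astype(int)
        pos = config.edge_margin + int(gaps[0])
        placed = []
        for s, g in zip(mine, gaps[1:]):
            s = dict(s)
            s["start"] = pos
            s["end"] = pos + s["span"]
            placed.append(s)
            pos = s["end"] + config.min_sv_gap + int(g)
        out[row["scaffold"]] = placed
    return out


def _apply_to_scaffold(ref: np.ndarray, variants: list[TrueVariant],
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the donor scaffold and its donor->reference liftover arrays."""
    seqs, refpos, strands = [], [], []

    def emit(seq, pos, strand):
        seqs.append(seq)
        refpos.append(pos)
        strands.append(np.full(len(seq), strand, dtype=np.int8))

    cur = 0
    for v in sorted(variants, key=lambda v: v.start):
        if v.start > cur:
            emit(ref[cur:v.start], np.arange(cur, v.start, dtype=np.int64), 1)
        if v.kind == "deletion":
            pass
        elif v.kind == "insertion":
            ins = np.frombuffer(v.seq.encode(), dtype=np.uint8)
            emit(ins, np.full(len(ins), -1, dtype=np.int64), 0)
        elif v.kind == "duplication":
            seg = ref[v.start:v.end]
            pos = np.arange(v.start, v.end, dtype=np.int64)
            emit(seg, pos, 1)
            emit(seg.copy(), pos.copy(), 1)
        elif v.kind == "inversion":
            emit(_revcomp(ref[v.start:v.end]),
                 np.arange(v.end - 1, v.start - 1, -1, dtype=np.int64), -1)
        elif v.kind == "complex":
            alt = np.frombuffer(v.seq.encode(), dtype=np.uint8)
            emit(alt, np.full(len(alt), -1, dtype=np.int64), 0)
        cur = v.end
    if cur < len(ref):
        emit(ref[cur:], np.arange(cur, len(ref), dtype=np.int64), 1)
    if seqs:
        return (np.concatenate(seqs), np.concatenate(refpos),
                np.concatenate(strands))
    return (np.empty(0, np.uint8), np.empty(0, np.int64), np.empty(0, np.int8))


def simulate_parental_genomes(config: SimConfig) -> GenomePair:
    """Generate the reference/donor genome pair with recorded ground truth.

    The donor is the reference with the configured variants applied; variants
    on one scaffold are pairwise disjoint and kept clear of scaffold ends.
    Raises :class:`CapacityError` when the requested variants cannot be
    placed.  Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scaffolds = _scaffold_layout(config, rng)
    specs = _draw_variant_specs(config, rng)
    placed = _allocate(specs, scaffolds, config, rng)

    reference, donor, donor_maps = {}, {}, {}
    variants: list[TrueVariant] = []
    snp_rows = []
    for _, row in scaffolds.iterrows():
        name, L = row["scaffold"], int(row["length"])
        ref = _random_seq(rng, L)
        vlist = []
        for s in placed.get(name, []):
            seq = None
            if s["alt_len"] and s["kind"] in ("insertion", "complex"):
                seq = _random_seq(rng, s["alt_len"]).tobytes().decode()
            vlist.append(TrueVariant(name, s["start"], s["end"], s["kind"],
                                     s["length"], seq))
        # SNPs in the inter-variant (identity) regions only
        if config.snp_rate > 0:
            occupied = np.zeros(L, dtype=bool)
            for v in vlist:
                occupied[v.start:max(v.end, v.start + 1)] = True
            free_pos = np.nonzero(~occupied)[0]
            n_snp = rng.binomial(len(free_pos), config.snp_rate)
            snp_pos = np.sort(rng.choice(free_pos, size=n_snp, replace=False))
        else:
            snp_pos = np.empty(0, dtype=int)

        darr, refpos, strand = _apply_to_scaffold(ref, vlist)
        if len(snp_pos):
            # donor indices of identity-mapped reference positions
            ident = np.nonzero(strand == 1)[0]
            lut = {int(r): int(d) for d, r in zip(ident, refpos[ident])}
            shift = rng.integers(1, 4, len(snp_pos))
            for p, sh in zip(snp_pos, shift):
                d = lut[int(p)]
                old = darr[d]
                new = _BASES[(np.nonzero(_BASES == old)[0][0] + sh) % 4]
                darr[d] = new
                snp_rows.append({"scaffold": name, "pos": int(p),
                                 "ref": chr(old), "alt": chr(new)})
        reference[name] = ref.tobytes().decode()
        donor[name] = darr.tobytes().decode()
        donor_maps[name] = (refpos, strand)
        variants.extend(sorted(vlist, key=lambda v: v.start))

    snps = pd.DataFrame(snp_rows, columns=["scaffold", "pos", "ref", "alt"])
    return GenomePair(reference, donor, variants, snps, scaffolds,
                      donor_maps, config)


# ---------------------------------------------------------------------------
# read pairs
# ---------------------------------------------------------------------------

def _align_reads(starts: np.ndarray, ends: np.ndarray, refpos: np.ndarray,
                 strand: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised liftover of donor intervals [start, end) to the reference.

    Returns (ref_start, ref_end, block_strand, mapped).  Reads whose span is a
    single clean liftover block take the fast path; reads straddling a
    breakpoint are resolved to their dominant block; reads with under half of
    their bases mapped are unmapped.
    """
    n = len(starts)
    span = ends - starts
    p0 = refpos[starts]
    p1 = refpos[ends - 1]
    s0 = strand[starts]
    s1 = strand[ends - 1]
    fwd = (s0 == 1) & (s1 == 1) & (p0 >= 0) & (p1 - p0 == span - 1)
    rev = (s0 == -1) & (s1 == -1) & (p1 >= 0) & (p0 - p1 == span - 1)

    rs = np.full(n, -1, dtype=np.int64)
    re = np.full(n, -1, dtype=np.int64)
    bs = np.zeros(n, dtype=np.int8)
    mapped = np.zeros(n, dtype=bool)

    rs[fwd], re[fwd], bs[fwd], mapped[fwd] = p0[fwd], p1[fwd] + 1, 1, True
    rs[rev], re[rev], bs[rev], mapped[rev] = p1[rev], p0[rev] + 1, -1, True

    for i in np.nonzero(~(fwd | rev))[0]:
        rp = refpos[starts[i]:ends[i]]
        st = strand[starts[i]:ends[i]]
        ok = rp >= 0
        if ok.sum() * 2 < len(rp):
            continue
        # split into runs contiguous in donor, constant strand, consecutive ref
        brk = np.nonzero((st[1:] != st[:-1])
                         | (rp[1:] - rp[:-1] != st[1:])
                         | ~ok[1:] | ~ok[:-1])[0] + 1
        best_len, best = 0, None
        for a, b in zip(np.r_[0, brk], np.r_[brk, len(rp)]):
            if not ok[a] or b - a <= best_len:
                continue
            best_len, best = b - a, (a, b)
        if best is None or best_len * 2 < len(rp):
            continue
        a, b = best
        lo, hi = (rp[a], rp[b - 1]) if st[a] == 1 else (rp[b - 1], rp[a])
        rs[i], re[i], bs[i], mapped[i] = lo, hi + 1, st[a], True
    return rs, re, bs, mapped


def simulate_read_pairs(pair: GenomePair, config: SimConfig | None = None,
                        ) -> pd.DataFrame:
    """Sample paired-end fragments from the donor and lift each read to the
    reference frame.

    Output columns: ``pair_id scaffold pos1 end1 strand1 mapped1 pos2 end2
    strand2 mapped2 insert`` where mate 1 is the forward (5') read of the
    fragment, positions are 0-based leftmost reference coordinates, strands
    are '+'/'-', and ``insert`` is the reference-frame outer span (-1 unless
    both mates map).  Rows are sorted by (scaffold, leftmost position).
    Reads falling entirely inside donor-only sequence are emitted unmapped.
    """
    config = config or pair.config
    rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    frames = []
    for name in pair.reference:
        refpos, strand = pair.donor_maps[name]
        dlen = len(refpos)
        n_frag = int(round(config.coverage * dlen / (2 * rl)))
        if n_frag == 0:
            continue
        flen = np.maximum(np.round(rng.normal(config.insert_mean, config.insert_sd,
                                              n_frag)).astype(int), 2 * rl)
        flen = np.minimum(flen, dlen)
        fstart = rng.integers(0, dlen - flen + 1)
        # mate 1: fragment 5' forward read; mate 2: reverse read at fragment 3'
        r1s, r1e, b1, m1 = _align_reads(fstart, fstart + rl, refpos, strand)
        r2s, r2e, b2, m2 = _align_reads(fstart + flen - rl, fstart + flen,
                                        refpos, strand)
        # reported strand = sequencing orientation x block strand
        strand1 = np.where(b1 == 1, "+", "-")
        strand2 = np.where(b2 == 1, "-", "+")
        both = m1 & m2
        insert = np.where(both,
                          np.maximum(r1e, r2e) - np.minimum(r1s, r2s), -1)
        frames.append(pd.DataFrame({
            "scaffold": name,
            "pos1": r1s, "end1": r1e, "strand1": strand1, "mapped1": m1,
            "pos2": r2s, "end2": r2e, "strand2": strand2, "mapped2": m2,
            "insert": insert,
        }))
    if not frames:
        return pd.DataFrame(columns=["pair_id", "scaffold", "pos1", "end1",
                                     "strand1", "mapped1", "pos2", "end2",
                                     "strand2", "mapped2", "insert"])
    df = pd.concat(frames, ignore_index=True)
    key = np.where(df["mapped1"], df["pos1"], df["pos2"]).astype(np.int64)
    key = np.where(df["mapped2"] & df["mapped1"],
                   np.minimum(df["pos1"], df["pos2"]), key)
    df["_key"] = np.where(df["mapped1"] | df["mapped2"], key, np.iinfo(np.int64).max)
    df = df.sort_values(["scaffold", "_key"], kind="mergesort").drop(columns="_key")
    df.insert(0, "pair_id", [f"pair_{i:07d}" for i in range(len(df))])
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def simulate_meiosis(true_map: GeneticMap, n_progeny: int,
                     heterokaryon_rate: float = 0.0, missing_rate: float = 0.0,
                     seed: int | np.random.Generator = 0,
                     ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate haploid single-spore-isolate genotypes from a true map.

    Per progeny and linkage group, crossover points form a Poisson process at
    one expected crossover per Morgan (no interference); alleles alternate
    a/b across crossovers and groups assort independently.  A fraction of
    strains are heterokaryons, carrying both nuclei and therefore scoring
    ``h`` at every marker; missing calls ``-`` are then placed independently.
    Returns the matrix and a per-strain truth table.
    """
    if n_progeny < 0:
        raise ValueError("n_progeny must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    marker_ids = [m for g in true_map.groups for m in g.markers]
    strains = [f"SSI{i + 1:04d}" for i in range(n_progeny)]
    if n_progeny == 0:
        return (GenotypeMatrix(pd.DataFrame(columns=marker_ids,
                                            index=pd.Index([], name="strain"))),
                pd.DataFrame(columns=["strain", "is_heterokaryon"]))

    is_het = rng.random(n_progeny) < heterokaryon_rate
    cells = np.empty((n_progeny, len(marker_ids)), dtype="U1")
    col = 0
    for g in true_map.groups:
        pos = np.asarray(g.positions, dtype=float)
        L = float(pos[-1]) if len(pos) else 0.0
        m = len(pos)
        for i in range(n_progeny):
            start = rng.integers(0, 2)
            k = rng.poisson(L / 100.0)
            cx = np.sort(rng.uniform(0.0, L, k)) if k else np.empty(0)
            par = (start + np.searchsorted(cx, pos, side="left")) % 2
            cells[i, col:col + m] = np.where(par == 0, "a", "b")
        col += m
    cells[is_het, :] = "h"
    if missing_rate > 0:
        miss = rng.random(cells.shape) < missing_rate
        cells[miss] = "-"
    gm = GenotypeMatrix(pd.DataFrame(cells, index=pd.Index(strains, name="strain"),
                                     columns=marker_ids))
    truth = pd.DataFrame({"strain": strains, "is_heterokaryon": is_het})
    return gm, truth


def random_true_map(n_groups: int = 10, markers_per_group: int = 10,
                    spacing_cm: tuple[float, float] = (5.0, 15.0),
                    seed: int | np.random.Generator = 0,
                    prefix: str = "SV") -> GeneticMap:
    """A synthetic truth map: ``n_groups`` groups with markers at random
    spacings drawn uniformly from ``spacing_cm``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = []
    k = 1
    for gi in range(n_groups):
        gaps = rng.uniform(*spacing_cm, markers_per_group - 1)
        pos = np.concatenate([[0.0], np.cumsum(gaps)])
        ids = [f"{prefix}{k + i:03d}" for i in range(markers_per_group)]
        k += markers_per_group
        groups.append(LinkageGroup(f"Group {gi + 1}", ids, pos))
    return GeneticMap(groups=groups)


def simulate_annotation(scaffolds: pd.DataFrame, n_genes: int = 200,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Random gene annotation: genes placed uniformly, count per scaffold
    proportional to length.  Columns: gene_id, scaffold, start, end, strand
    (0-based half-open; the GFF3 writer converts to 1-based)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lens = scaffolds["length"].to_numpy(float)
    quota = lens / lens.sum() * n_genes
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[:n_genes - counts.sum()]:
        counts[i] += 1
    rows = []
    g = 1
    for (_, row), c in zip(scaffolds.iterrows(), counts):
        for _ in range(c):
            glen = int(rng.integers(500, 3000))
            glen = min(glen, row["length"] - 1)
            start = int(rng.integers(0, row["length"] - glen))
            rows.append({"gene_id": f"gene_{g:05d}", "scaffold": row["scaffold"],
                         "start": start, "end": start + glen,
                         "strand": "+" if rng.random() < 0.5 else "-"})
            g += 1
    return pd.DataFrame(rows)
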