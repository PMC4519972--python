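# Methods

This note records the models behind `svmap`, the parameter defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
tests do and do not establish about real data.

## Study system and scope

The package targets the haploid (basidiomycete-style) mapping design: a
reference homokaryon assembled into scaffolds, a second compatible homokaryon
re-sequenced with paired-end reads, and a mapping population of single-spore
isolates (SSIs) from their heterokaryon.  Each SSI is one meiotic product, so
genotypes are directly scorable haplotypes, the recombination fraction
between two markers is the fraction of progeny whose alleles differ, and no
phase or dominance modelling is needed.  Wet-lab steps (DNA extraction, PCR
thermodynamics, gel imaging), de-novo assembly and SNP/indel calling are out
of scope; alignments enter the pipeline as SAM or the simulator's pair
tables.

## Simulator

`simulate_parental_genomes` draws i.i.d. uniform-composition scaffold
sequences, plants structural variants disjointly (largest-remainder
allocation across scaffolds proportional to usable length, then a
stars-and-bars placement with a minimum inter-variant gap), applies them
piecewise to build the donor, and sprinkles SNPs over the identity regions.
Novel (insertion/replacement) sequence is drawn from the same base
composition as the reference.  The construction simultaneously produces a
per-base donor→reference liftover (position + strand), so
`simulate_read_pairs` needs no aligner: a fragment is sampled from the
donor (length ~ N(insert_mean, insert_sd), position uniform) and each read
is mapped through the liftover.  A read straddling a breakpoint is assigned
to its dominant collinear block, mimicking a best-local-alignment mapper; a
read with under half of its bases mappable is reported unmapped.  Because
alignment is exact by construction, every discordant signature in the output
is a deterministic consequence of the planted variants — which is what makes
the caller testable against truth with recall/precision of exactly 1.

Crossovers in `simulate_meiosis` form a Poisson process at one expected
crossover per Morgan with no interference, so the Haldane map function is an
exact closed form for this generator and serves as the oracle for
recombination-fraction recovery.  Heterokaryotic strains carry both nuclei
and score `h` at every marker (the two-band profile); missing calls are
placed independently afterwards.  All randomness flows from one seed;
identical configs give bit-identical outputs.

Default study conditions (one place, not revisited): 505 bp insert mean,
100 bp reads, 30× coverage, SNP rate 1e-3 (≈ the observed genome-wide SNP
density in the target system), 235 progeny with an 18 % heterokaryon rate
(mirroring a 235 → 192 screened population), 2 % missing calls, and a
genome-average recombination rate of 21 cM/Mb (≈ 1 cM per 47.7 kb).  The
default genome is a miniature — ten 300 kb chromosomes in 30 scaffolds — so
a complete run stays in seconds; the genome-scale spectrum (hundreds of SVs
over tens of Mb) is represented proportionally rather than literally.
Insert s.d. defaults to 30 bp (library width is rarely reported; ~6 % of the
mean is typical for short-insert libraries).  Default SV length ranges:
insertions 200–350 bp (flanking-pair detection requires the length change to
fit inside the insert window; observed mean insertion sizes in such
comparisons are ~300 bp), deletions 200–1200 bp, duplications and inversions
500–2000 bp (tandem duplications shorter than insert − read_length also shed
insertion-like pairs; ≥ ~400 bp keeps the everted signature unambiguous),
complex loci 600–1200 bp replaced by 120–200 bp of novel sequence (net loss,
so the signature mix is deletion-like + one-end-unmapped).

## SV calling

Pairs are classified against a robust insert model (median and 1.4826×MAD of
FR-oriented pairs; concordance window mean ± k·sd with k = 3 by default):

| signature        | geometry                              | resolves to |
|------------------|---------------------------------------|-------------|
| del_like         | FR, insert > mean + k·sd              | deletion    |
| ins_like         | FR, insert < mean − k·sd              | insertion   |
| inv_like         | both mates same strand                | inversion   |
| dup_like         | everted (reverse before forward)      | duplication |
| one_end_unmapped | mate in donor-only sequence           | insertion (length = lower bound) |

Same-signature pairs whose breakpoint intervals fall within `max_cluster_gap`
(150 bp) chain into clusters; a cluster calls a locus when supported by more
than 5 pairs (≥ 6; the threshold is configurable since "more than 5" is the
only stated rule).  Overlapping clusters of different signatures merge:
dup_like + ins_like → duplication (a short tandem duplication *is* an
insertion to flanking pairs), ins_like + one-end-unmapped → insertion, any
other conflicting mix → complex.  Breakpoints: deletion/insertion lengths
come from the median implied size change, with cluster members trimmed when
their insert deviates from the cluster median by more than k·sd (a chance
borderline pair chained into a cluster otherwise corrupts the boundary
statistics); inversion boundaries use the strand-split estimators (left
breakpoint from ++ pairs' inner ends, right from −− pairs' outer starts),
which are exact in the error-free simulator; duplications span the everted
pairs' outer envelope.  The signature→type table for duplication, inversion
and complex is a reconstruction: the upstream description reports these
classes without stating detection rules.

## Marker model

Primer design proper (Tm, GC, hairpins) is out of scope; the outer edges of
the two 300 bp flanks stand in for primer sites, which preserves the
amplicon-size arithmetic exactly.  A marker is rejected when the locus length
is outside 200–800 bp (bounds inclusive), when any non-ACGT character occurs
in locus ± flank, when a flank runs off the scaffold, or when a 20 bp flank
tip fails exact genome-wide uniqueness in either parent (`non_specific` for
multiple hits, `no_unique_product` for a site lost in the donor — e.g. a SNP
inside the tip).  Amplicon sizes are measured between the located sites in
each parent, so for a pure deletion size_A − size_B equals the deleted
length.  Co-dominance requires the two bands to be gel-resolvable:
|Δ| ≥ max(20 bp, 5 % of the smaller product).  Both thresholds are package
choices (agarose resolution is the only constraint mentioned upstream) and
are exposed as configuration.  An effective marker's heterokaryon profile is
the union of the two parental bands.

## Linkage mapping

Two-point statistics use the phase-known haploid formulas: r̂ = R/n capped at
0.5 and LOD = R·log₁₀(2r̂) + (n−R)·log₁₀(2(1−r̂)), with LOD = n·log₁₀2 at
R = 0.  Grouping takes connected components of the LOD ≥ 3.0 graph.  An
optional maximum-r̂ co-requirement is available because single-linkage on a
bare LOD threshold is fragile at scale: with ~100 markers and n = 192, a
cross-chromosome pair reaches LOD ≥ 3 whenever R ≤ 70 (p ≈ 1.2×10⁻⁴), and
~4.5×10³ cross pairs then contribute ≈ 0.5 expected spurious edges per
dataset.  The recovery studies therefore enable max_rf = 0.3 — the two-point
recombination fraction at the 50 cM distance cap that classical grouping
commands pair with their LOD threshold — while the default leaves the guard
off to match the bare stated rule.

Ordering seeds each group with a supplied framework (markers of known
physical order) when available, otherwise with the highest-total-LOD triple
ordered exhaustively; remaining markers are inserted one at a time
(most-informative first, ties toward the left end and by marker id) at the
position minimising the sum of adjacent r̂.  The finishing pass permutes a
sliding window, starting at width 3 and widening to 5 only after the narrower
pass converges; the classic window-3 ripple is subsumed, and the wider
windows remove its rare local optima (without them the heuristic missed the
brute-force optimum on ~1 % of random ≤ 8-marker instances).  Orders are
canonicalised first-id < last-id, so "correct up to full reversal" is the
testable statement.  Distances between adjacent markers are Kosambi
transforms of r̂, accumulated into positions; group "Average Marker Spacing"
is reported as length/markers (not length/(markers−1)), mirroring the
convention of the published table this summary reproduces.  Multipoint
likelihood (EM over orders, error detection) is deliberately not reproduced:
for haploid co-dominant data two-point statistics are fully specified,
closed-form testable, and sufficient for the recovery rates demonstrated.

## Anchoring and genome statistics

A scaffold joins the group holding the majority of its markers (ties to the
lower-numbered group); orientation is the sign of the Spearman correlation
between cM and bp positions, left undetermined with fewer than two markers.
Scaffold lengths come from the FASTA, never from marker spans.  The reduced
scaffold count after super-scaffolding is original − anchored + groups with
≥ 1 anchor.  Interleaving conflicts report every maximal run of foreign
markers separating two consecutive markers of one scaffold, with the cM gap.
The recombination scan rates each interval between adjacent same-scaffold
markers in cM/kb against the map-wide mean; `hot` at ≥ 3× the mean and
`cold` at ≤ ⅓× are package defaults chosen so that reported hotspot
examples (≈ 5.7× and ≈ 4.5× the mean) qualify while the reported coldspot
examples (≈ 0.40× and ≈ 0.60×) require relaxing `cold_factor` (to ≈ 0.45) —
the upstream account names example intervals without a numeric rule.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally; SAM and GFF3 are written
1-based per their specifications.  Insertions have zero reference span
(start = end) with `length` carrying the inserted size.  r̂ = 0.5 maps to
LOD 0; r̂ at or above 0.5 gives an infinite Kosambi distance (adjacent pairs
inside a group are clamped at 0.4999999 before transforming, reachable only
with the rf guard disabled).  Zero-variant configurations, empty call sets,
zero progeny and all-heterokaryon matrices all have defined behaviour
(identity donor, all-zero summary, header-only matrix, explicit error).
Cluster and locus ordering, group numbering and tie-breaks are all
deterministic, so equal seeds give byte-identical reports.

## What the tests show — and do not

Against this generator the caller attains recall = precision = 1.0 (20
seeds × 12 well-separated SVs at 30×) and the map builder recovers the exact
chromosome partition and within-group orders (up to reversal) in ≥ 95 % of
40 mapping populations at n = 192.  Those figures certify the *inference
machinery*, not field performance: the simulator has no base-call errors, no
mapping ambiguity from repeats, no chimeric pairs, uniform coverage and
uniform base composition, SNPs only outside SV loci, and crossovers without
interference.  Real libraries will lose markers to primer failure modes the
amplicon model cannot see, and real callers face repeat-induced false
signatures that the clean liftover never produces.  Scaled-down problem
sizes are used throughout (miniature genomes for sequence-level studies;
mapping-scale n = 192 and ~100 markers for the linkage studies, which match
the target experiment's scale exactly).
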