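# Methods

This note documents the models, defaults and numerical choices behind
`spliceasm`, and what the synthetic experiments do and do not show.

## Input model and coordinates

All genomic coordinates are 0-based half-open internally; SAM input
(1-based) is converted at parse time and GTF output converts back.
A spliced alignment contributes one exon block per CIGAR run of
reference-consuming operations, with `M/=/X/D` extending the current
block and `N` closing it; `I/S/H/P` never touch the reference. Unmapped,
secondary and supplementary records are skipped. Tags consumed: `NM`
(mismatch count; absent ⇒ 0, which deactivates the mismatch-rate filter
because errors cannot be fabricated), `NH` (reads contribute weight
1/NH), `XS` (transcription strand), `XC` (super-read coverage, used as
the record's weight; with a known super-read *k*, the outer *k−1*
aligned bases are trimmed because super-read ends can reach into
alternatively spliced exons).

Mate resolution uses the query name, cross-checked against
`RNEXT`/`PNEXT`; pairs that cannot be resolved unambiguously are treated
as unpaired. Collapsed alignments keep a weighted multiplicity and a
symmetric map of mate-location links, so fragments can be reconstituted
without storing every read.

## Filters

For a spliced read, each junction is checked against a per-reference
junction table built from *all* reads before filtering:

| condition | requirement | default |
|---|---|---|
| mismatch rate > 1% | junction support ≥ 1.25 × `min_junction_support` | 1 read |
| intron > 100,000 bp | ≥ 25 bp anchor on both sides in some supporting read | — |
| any junction | ≥ 10 bp anchor on both sides in some supporting read | 10 bp |

The anchor of a junction within a read is the length of the exon block
flanking it; the table stores the per-side maximum over supporting
reads. Both rules are monotone: adding support can only turn drops into
keeps.

## Bundles and the splice graph

Alignments whose spans (including intron gaps) are separated by more
than `max_gap` (default 50 bp, `-g`) start a new bundle; spans rather
than covered bases are used so that one spliced read holds its own locus
together. Within a bundle, one graph is built per XS strand;
strand-unknown alignments (typically unspliced) contribute to every
strand graph of the bundle — a deliberate double-count that only affects
the rare bundle mixing two genes on opposite strands.

Node boundaries are the union of junction donor/acceptor sites, the end
points of maximal covered intervals, and guide-exon boundaries; nodes
are the covered segments between consecutive boundaries, sorted by
coordinate (hence topologically). Junction edges join the node ending at
a donor to the node starting at the acceptor; adjacency edges join
genomically contiguous nodes only when at least one read block spans the
shared boundary. Guides constrain structure (boundaries and edges with
zero read support, protected from pruning) but carry no abundance.

Bit-vector encoding: node *i* is bit *i* and edge *(i, j)* is bit
`n + n·i + j` in the dense layout — the edge region is offset past the
node bits because the raw `n·i + j` formula collides with node indices
when *i = 0*. The working representation is sparse (sets of node and
edge identifiers) since real graphs are edge-sparse; both encodings are
checked equivalent by test. A fragment's path sets the bits of both
mates and is flagged *interrupted* when its set nodes are not linked by
set edges — the same representation reused for long reads that span
pruned nodes. Compatibility of a read with a transcript path requires
bit containment plus, per contiguous read part, that the transcript
visits no node strictly inside the part that the read skips.

## Long-read mode (`-L`)

High-error reads are those with `NM`/aligned-length above
`high_error_threshold` (default 0.02; the trigger rate is not a
published constant, so it stays configurable). For each splice site of a
high-error read with zero low-error support, the site within ±10 bp
(`correction_window`) having maximal total support among sites with
positive low-error support replaces it; ties prefer the nearer, then the
smaller, coordinate. Guide splice sites count as low-error support of
weight 1. A correction that would create an empty exon or inverted
intron is skipped and logged. Correction is idempotent because corrected
sites are, by construction, low-error supported.

Pruning removes edges from least to most supported (ties: smallest
*(i, j)*) until the node count falls below `max_nodes` (default 1000);
a node that loses all incident edges and has no unspliced read coverage
is dropped, so single-exon evidence survives. Guide edges are never
removed. The removal log is non-decreasing in support by construction.
Reads are encoded on the pruned graph (or re-encoded via
`reencode_after_pruning`), with missing nodes/edges turning continuous
reads into interrupted ones.

## Transcript extraction and quantification

Extraction iterates up to `|E| + 1` times per graph:

1. **Seed & extend.** Seed at the node with maximal residual coverage;
   extend greedily both ways along the incident edge with maximal
   residual read support (ties: larger flanking node coverage, then
   smaller index), stopping when no positively supported edge continues.
2. **Flow & subtraction.** The path's flow is the bottleneck over its
   node and edge capacities computed from compatible unassigned reads.
   Node capacity is a high quantile (0.9) of the per-bp depth profile —
   robust to the depth ramps that fixed-length fragments produce near
   transcript termini — and edge capacity is the weight of compatible
   reads spanning the edge. Each compatible read then loses the fraction
   `flow / (its tightest capacity over all residual reads)`: mass at the
   path's distinctive features is consumed completely while mass that
   several isoforms could explain is shared proportionally. Total read
   mass decreases by exactly the assigned amount (asserted by test).
3. **Stop** when the maximal residual node coverage falls below
   `min_transcript_coverage` (default 1 read/bp, `-c`) or the extracted
   flow does.

The extracted paths are structure candidates only. Two refinements
produce the final models:

* **Parsimony.** A candidate with no uniquely compatible fragment mass
  is discarded (smallest-total-mass first, recomputing after each
  removal). This removes truncated sub-paths and coverage-crumb
  artifacts, which by construction are shadowed by a longer candidate;
  a genuinely nested isoform with no distinguishing fragment is
  unidentifiable from the data and is intentionally dropped with it.
* **Linear re-quantification.** Per-isoform interior densities *d* solve
  the non-negative least squares system `A d = y`, where *y* holds each
  used node's plateau depth and `A[i, j] = 1` iff candidate *j* contains
  node *i* (junction-support rows are appended only if the node rows do
  not separate the candidates). Plateaus are mean depths after trimming
  a ramp margin — the median fragment cDNA extent — at nodes where a
  candidate starts or ends; nodes too short to trim fall back to the
  0.9 depth quantile. Densities convert to mean reads/bp via
  conservation of assigned fragment bases: with `Σ_j d_j (L_j − S) = M`
  defining the effective extent *S*, coverage is `d_j (L_j − S)/L_j`.
  This estimator is exact up to tiling discretization on uniform data
  and self-calibrates *S* for both short fragments (*S* ≈ fragment
  length) and full-length long reads (*S* ≈ 0).

  An EM over fragment-compatibility classes was evaluated for this step
  and rejected: with a position-blind likelihood the unique-evidence
  windows (a few hundred bp) are tiny relative to transcript length, so
  its optimum is systematically biased toward long isoforms even on
  noiseless data. The per-feature linear decomposition uses the
  positional information directly.

Transcripts below `min_isoform_fraction` (default 0.01, `-f`) of the
locus maximum or below `min_transcript_coverage` are dropped. With
trimming enabled (default; `-t` disables, long-read mode disables),
terminal exons are shortened while the bundle's per-bp coverage is below
`trim_fraction` (0.1) of the transcript's mean. A transcript whose
intron chain equals a guide's is labelled `guide_matched`.

## Super-reads

The *k*-mer table counts every *k*-mer of every read canonically
(a *k*-mer and its reverse complement share an entry) with **no**
minimum-count threshold — transcripts may be covered by a single read.
*k*-unitigs are maximal chains in which every internal *k*-mer has
exactly one predecessor and successor; the walk runs over oriented
*k*-mers with cycle guards (a read whose *k*-mer set is closed under
reverse complement yields its chain up to cyclic rotation), finished
unitigs are stored canonically, and every canonical *k*-mer lands in
exactly one unitig (verified by brute force). A read is extended to a
super-read by locating its terminal *k*-mers in their unitigs and
splicing on the unitig remainders; unplaceable terminal *k*-mers leave
the read as-is. Default *k* = 25 (odd, avoiding self-complementary
*k*-mers; not a published value — configurable).

Quantification considers only super-reads with a genome alignment. A
read is assigned to every such super-read containing it (or its reverse
complement) as an exact substring. EM: the initial estimate sums the
mass of uniquely assigned reads; each iteration redistributes every
read's mass proportionally to the previous estimates, splitting equally
when all of a read's targets are at zero. Tolerance 1e-6 relative to
total mass, 1000-iteration guard; total mass is conserved at every
redistribution. Fragment mass is 1 per fragment. The estimate is written
as `XC:f` on the super-read SAM (tag name configurable); the same EM
routine, with length-normalized proportions, is available for
distributing reads across transcripts.

## Evaluation

Transcript matching: identical intron chains (exact coordinates) with
both terminal ends within 100 bp; single-exon transcripts use the same
two-end rule, and strand-unknown models match either strand. Pairing is
one-to-one: the matching maximizes paired references (candidates sorted
by end difference, augmenting-path assignment), surplus predictions
count as false positives. Intron-level scores use exact set overlap of
deduplicated `(chromosome, donor, acceptor)` triples. Relative change is
`100 (v₁ − v₂)/v₂`, undefined for a zero baseline. For real data the
reference can be the union of annotated transcripts each tool predicted
correctly.

## Synthetic data

Each locus places one shared first exon, a backbone of internal exons
(default 4, lengths 150–300 bp, introns 150–400 bp), and one shared last
exon (400–800 bp); isoform 1 keeps the backbone and isoform *j* ≥ 2
skips internal exon *j*−1. With skips away from the terminal exons,
every source-to-sink path of the resulting splice graph is a real
isoform, so the loci are identifiable from junction-local evidence —
the property the exact-recovery experiments require, and a property real
alternative-promoter loci do not always have (a limitation discussed
below). GT/AG (CT/AC on minus) dinucleotides are written at annotated
intron boundaries. Per-isoform coverage is drawn from 5–15 reads/bp;
short reads are 75 bp proper pairs with a 250 bp fragment span tiled
evenly along the transcript; long reads are full-length, with half kept
error-free and the rest given `NM` ≈ 3% of the aligned length and
per-junction jitter of 1–6 bp with probability `p_jitter` (alignment-
level error only — no base-level errors, since the assembler never looks
at base qualities or sequences of aligned reads). All sampling draws
from one `numpy` generator keyed by the seed, so equal seeds give
byte-identical files. Manifests record per-transcript realized coverage
and every injected jitter event for exact scoring.

Experiment sizes — 50 loci × 3 isoforms for the recovery runs, 2000-node
random graphs for pruning, 100 random matrices for the EM checks — keep
every suite and the acceptance script within seconds on one CPU.

## What passing tests do and do not show

Passing recovery at 100%/100% with ≤5% coverage error shows the
pipeline's bookkeeping (collapsing, pairing, graph construction,
compatibility, flow accounting, NNLS decomposition) is exact on clean,
identifiable loci. It does not show robustness to misalignment noise,
degraded splice motifs, overlapping genes, paralogs, intron retention,
or non-identifiable isoform mixes (alternative first/last exons paired
across shared middles longer than the fragment span — information that
is absent from short-read data for any method). The long-read experiment
exercises the correction and pruning paths under an idealized jitter
model, not a real basecaller error profile.

## Known limitations

* Greedy heaviest-path extraction is not globally optimal; on graphs
  where local support is misleading it can propose chimeric paths, which
  the parsimony filter only removes when they lack unique support.
* Strand-unknown spliced reads in a genuinely two-stranded bundle are
  assigned to both strand graphs, duplicating their mass.
* Super-read extension resolves hairpin (reverse-complement-symmetric)
  unitig placements by string comparison at the first stored position;
  pathological palindromic contexts can mis-extend (negligible at
  *k* = 25).
* No FPKM/TPM normalization, multi-sample merge, or BAM/CRAM random
  access.
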