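"""Deterministic synthetic test data: toy loci, alignments, raw reads.

Each locus is a multi-isoform gene: every isoform has its own first and
last exon (alternative promoters / polyadenylation sites) and draws its
internal exons from a shared backbone with exon skipping, so intron chains
are pairwise distinct while internal exons carry summed coverage.  GT/AG
(CT/AC on the minus strand) dinucleotides are written at annotated intron
boundaries so splice-motif logic is exercisable.

Short-read simulation tiles perfect paired (or single) alignments evenly
along each transcript at a requested per-isoform coverage; long-read
simulation emits full-length alignments per transcript with a configurable
fraction kept error-free while the rest get an elevated mismatch count and
independent junction jitter (each junction moved by up to ``jitter_max`` bp
with probability ``p_jitter``) — the alignment-level error behaviour that
motivates splice-site correction.  Every generator draws from a single
seeded stream, so equal seeds give byte-identical outputs, and a manifest
records per-transcript ground truth for exact recovery scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .gtfio import Transcript, write_gtf


@dataclass
class FixtureSpec:
    """Study conditions for the generators (all coordinates in bp)."""

    seed: int = 1
    n_loci: int = 50
    isoforms_per_locus: int = 3
    internal_exons: int = 4
    internal_exon_range: tuple[int, int] = (150, 300)
    terminal_exon_range: tuple[int, int] = (400, 800)
    intron_range: tuple[int, int] = (150, 400)
    coverage_range: tuple[int, int] = (5, 15)
    read_length: int = 75
    fragment_length: int = 250
    paired: bool = True
    # long-read error model (alignment-level)
    long_coverage: int = 8
    clean_fraction: float = 0.5
    p_jitter: float = 0.0
    jitter_max: int = 6
    long_mismatch_rate: float = 0.03
    truncation_prob: float = 0.0

    def __post_init__(self):
        for rate in (self.clean_fraction, self.p_jitter, self.truncation_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for lo, hi in (self.internal_exon_range, self.terminal_exon_range,
                       self.intron_range, self.coverage_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length/coverage ranges must be positive")


@dataclass
class Locus:
    chrom: str
    strand: str
    genome: str
    transcripts: list[Transcript]
    coverages: dict[str, float]


@dataclass
class JitterEvent:
    read_id: str
    transcript_id: str
    side: str          # "donor" | "acceptor"
    true_site: int
    jittered_site: int


@dataclass
class Dataset:
    spec: FixtureSpec
    loci: list[Locus]

    @property
    def transcripts(self) -> list[Transcript]:
        return [t for locus in self.loci for t in locus.transcripts]

    @property
    def coverages(self) -> dict[str, float]:
        out = {}
        for locus in self.loci:
            out.update(locus.coverages)
        return out

    def locus_of(self, tid: str) -> Locus:
        for locus in self.loci:
            if any(t.id == tid for t in locus.transcripts):
                return locus
        raise KeyError(tid)

    def header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": locus.chrom, "LN": len(locus.genome)}
                   for locus in self.loci],
        })


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=length)])


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def generate_locus(spec: FixtureSpec, rng: np.random.Generator,
                   index: int) -> Locus:
    """One multi-isoform locus: shared terminal exons, exon skipping over a
    shared internal backbone.

    Isoform 1 keeps the full backbone; isoform j >= 2 skips internal exon
    j-1.  With non-adjacent-to-terminal skips every source-to-sink path of
    the resulting splice graph is a real isoform, so the locus is
    identifiable from junction-local read evidence — the property the
    short-read recovery experiments rely on.
    """
    k = spec.isoforms_per_locus
    m = spec.internal_exons
    if k >= 2 and m < k + 1:
        raise ValueError("need internal_exons >= isoforms_per_locus + 1 "
                         "for distinct, identifiable intron chains")
    strand = "+" if rng.random() < 0.5 else "-"
    pos = 100

    def draw(lohi):
        return int(rng.integers(lohi[0], lohi[1] + 1))

    first_exon = (pos, pos + draw(spec.terminal_exon_range))
    pos = first_exon[1] + draw(spec.intron_range)
    backbone: list[tuple[int, int]] = []
    for _ in range(m):
        length = draw(spec.internal_exon_range)
        backbone.append((pos, pos + length))
        pos += length + draw(spec.intron_range)
    last_exon = (pos, pos + draw(spec.terminal_exon_range))
    genome_len = last_exon[1] + 100

    chains: list[list[tuple[int, int]]] = []
    for j in range(k):
        if j == 0:
            internal = list(backbone)
        else:
            internal = [e for i, e in enumerate(backbone) if i != j]
        chains.append([first_exon] + internal + [last_exon])

    chrom = f"locus{index:03d}"
    gene_id = f"G{index:03d}"
    transcripts = []
    coverages = {}
    for j, exons in enumerate(chains):
        tid = f"{gene_id}.T{j + 1}"
        transcripts.append(Transcript(chrom=chrom, strand=strand,
                                      exons=tuple(exons), id=tid,
                                      gene_id=gene_id))
        coverages[tid] = float(draw(spec.coverage_range))

    genome = _random_seq(rng, genome_len)
    donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
    for t in transcripts:
        for (d, a) in t.introns:
            genome[d:d + 2] = list(donor)
            genome[a - 2:a] = list(acceptor)
    return Locus(chrom=chrom, strand=strand, genome="".join(genome),
                 transcripts=transcripts, coverages=coverages)


def generate_dataset(spec: FixtureSpec) -> Dataset:
    rng = np.random.default_rng(spec.seed)
    loci = [generate_locus(spec, rng, i) for i in range(spec.n_loci)]
    return Dataset(spec=spec, loci=loci)


# ------------------------------------------------------------------
# coordinate mapping helpers
# ------------------------------------------------------------------

def tx_to_genome_blocks(transcript: Transcript, t_start: int, length: int
                        ) -> tuple[tuple[int, int], ...]:
    """Map a transcript-coordinate interval (genomic exon order) onto
    genomic exon blocks."""
    blocks: list[tuple[int, int]] = []
    remaining = length
    offset = t_start
    for (s, e) in transcript.exons:
        elen = e - s
        if offset >= elen:
            offset -= elen
            continue
        take = min(remaining, elen - offset)
        blocks.append((s + offset, s + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("interval exceeds transcript length")
    return tuple(blocks)


def transcript_cdna(transcript: Transcript, genome: str) -> str:
    seq = "".join(genome[s:e] for (s, e) in transcript.exons)
    return _revcomp(seq) if transcript.strand == "-" else seq


def _blocks_to_cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def _make_segment(header, qname: str, chrom: str,
                  blocks: Sequence[tuple[int, int]], flag: int,
                  nm: int, xs: Optional[str], mate_pos: Optional[int],
                  weight_tag: Optional[float] = None) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = qname
    seg.flag = flag
    seg.reference_name = chrom
    seg.reference_start = blocks[0][0]
    seg.mapping_quality = 60
    seg.cigarstring = _blocks_to_cigar(blocks)
    if mate_pos is not None:
        seg.next_reference_name = chrom
        seg.next_reference_start = mate_pos
    seg.set_tag("NM", nm, value_type="i")
    seg.set_tag("NH", 1, value_type="i")
    if xs:
        seg.set_tag("XS", xs, value_type="A")
    if weight_tag is not None:
        seg.set_tag("XC", float(weight_tag), value_type="f")
    return seg


# ------------------------------------------------------------------
# short-read alignment simulation
# ------------------------------------------------------------------

def simulate_short_alignments(dataset: Dataset, out_sam: str,
                              ) -> dict[str, dict]:
    """Tile perfect short-read alignments along every transcript.

    Paired mode emits proper FR pairs at the spec's fragment length;
    spliced mates get N CIGAR gaps and an XS strand tag; NM is 0.  Returns
    the truth manifest: per transcript the read count and realized mean
    per-bp coverage.  Transcripts shorter than the read span are skipped.
    """
    spec = dataset.spec
    header = dataset.header()
    manifest: dict[str, dict] = {}
    rlen = spec.read_length
    span = spec.fragment_length if spec.paired else rlen
    with pysam.AlignmentFile(out_sam, "wh", header=header) as out:
        for locus in dataset.loci:
            for t in locus.transcripts:
                L = t.length
                cov = locus.coverages[t.id]
                if L < span:
                    continue
                bases_per_unit = 2 * rlen if spec.paired else rlen
                n = max(1, round(cov * L / bases_per_unit))
                starts = (np.round(np.linspace(0, L - span, n)).astype(int)
                          if n > 1 else np.array([0]))
                for i, s in enumerate(starts):
                    s = int(s)
                    qname = f"{t.id}.r{i}"
                    if spec.paired:
                        b1 = tx_to_genome_blocks(t, s, rlen)
                        b2 = tx_to_genome_blocks(t, s + span - rlen, rlen)
                        xs1 = t.strand if len(b1) > 1 else None
                        xs2 = t.strand if len(b2) > 1 else None
                        f1 = 0x1 | 0x2 | 0x40 | 0x20
                        f2 = 0x1 | 0x2 | 0x80 | 0x10
                        out.write(_make_segment(header, qname, t.chrom, b1,
                                                f1, 0, xs1, b2[0][0]))
                        out.write(_make_segment(header, qname, t.chrom, b2,
                                                f2, 0, xs2, b1[0][0]))
                    else:
                        b = tx_to_genome_blocks(t, s, rlen)
                        xs = t.strand if len(b) > 1 else None
                        out.write(_make_segment(header, qname, t.chrom, b,
                                                0, 0, xs, None))
                realized = n * bases_per_unit / L
                manifest[t.id] = {"n_units": int(n),
                                  "realized_coverage": realized,
                                  "length": L}
    return manifest


# ------------------------------------------------------------------
# long-read alignment simulation
# ------------------------------------------------------------------

def simulate_long_alignments(dataset: Dataset, out_sam: str,
                             rng: Optional[np.random.Generator] = None,
                             ) -> tuple[dict[str, dict], list[JitterEvent]]:
    """Full-length long-read alignments with injected splice-site jitter.

    A ``clean_fraction`` of each transcript's reads stays error-free (NM=0,
    exact junctions) to provide low-error support; the rest get NM set to
    ``long_mismatch_rate`` of the aligned length and each junction is moved
    by 1..``jitter_max`` bp with probability ``p_jitter`` (random side and
    direction).  With ``truncation_prob`` a noisy read loses a prefix or
    suffix of its exon chain, giving partial transcripts.  Returns the
    truth manifest and the jitter event log.
    """
    spec = dataset.spec
    if rng is None:
        rng = np.random.default_rng(spec.seed + 7919)
    header = dataset.header()
    manifest: dict[str, dict] = {}
    events: list[JitterEvent] = []
    with pysam.AlignmentFile(out_sam, "wh", header=header) as out:
        for locus in dataset.loci:
            for t in locus.transcripts:
                n = max(1, int(round(spec.long_coverage)))
                n_clean = max(1, int(round(n * spec.clean_fraction)))
                for i in range(n):
                    qname = f"{t.id}.lr{i}"
                    blocks = [list(b) for b in t.exons]
                    clean = i < n_clean
                    if not clean and spec.truncation_prob > 0 and \
                            len(blocks) > 2 and rng.random() < spec.truncation_prob:
                        if rng.random() < 0.5:
                            blocks = blocks[1:]
                        else:
                            blocks = blocks[:-1]
                    if not clean:
                        for kjunc in range(len(blocks) - 1):
                            if rng.random() >= spec.p_jitter:
                                continue
                            delta = int(rng.integers(1, spec.jitter_max + 1))
                            if rng.random() < 0.5:
                                delta = -delta
                            if rng.random() < 0.5:
                                old = blocks[kjunc][1]
                                blocks[kjunc][1] = old + delta
                                events.append(JitterEvent(qname, t.id, "donor",
                                                          old, old + delta))
                            else:
                                old = blocks[kjunc + 1][0]
                                blocks[kjunc + 1][0] = old + delta
                                events.append(JitterEvent(qname, t.id,
                                                          "acceptor", old,
                                                          old + delta))
                    alen = sum(e - s for s, e in blocks)
                    nm = 0 if clean else math.ceil(spec.long_mismatch_rate * alen)
                    out.write(_make_segment(header, qname, t.chrom,
                                            [tuple(b) for b in blocks],
                                            0, nm, t.strand, None))
                manifest[t.id] = {"n_units": n, "n_clean": n_clean,
                                  "length": t.length}
    return manifest, events


# ------------------------------------------------------------------
# raw reads + file writers
# ------------------------------------------------------------------

def simulate_short_reads(dataset: Dataset) -> list[tuple[str, str]]:
    """Raw (unaligned) short reads from transcript cDNA, for the super-read
    module; evenly tiled at each transcript's coverage."""
    spec = dataset.spec
    out: list[tuple[str, str]] = []
    rlen = spec.read_length
    for locus in dataset.loci:
        for t in locus.transcripts:
            cdna = transcript_cdna(t, locus.genome)
            L = len(cdna)
            if L < rlen:
                continue
            n = max(2, round(locus.coverages[t.id] * L / rlen))
            starts = np.round(np.linspace(0, L - rlen, n)).astype(int)
            for i, s in enumerate(starts):
                out.append((f"{t.id}.sr{i}", cdna[int(s):int(s) + rlen]))
    return out


def write_genome_fasta(dataset: Dataset, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for locus in dataset.loci:
            fh.write(f">{locus.chrom}\n")
            for i in range(0, len(locus.genome), width):
                fh.write(locus.genome[i:i + width] + "\n")


def write_truth_gtf(dataset: Dataset, path: str) -> None:
    write_gtf(dataset.transcripts, path, source="fixture")


def write_fastq(reads: Sequence[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_manifest(dataset: Dataset, manifest: dict[str, dict],
                   path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tchrom\tstrand\tlength\tn_units"
                 "\trealized_coverage\texons\n")
        for locus in dataset.loci:
            for t in locus.transcripts:
                if t.id not in manifest:
                    continue
                rec = manifest[t.id]
                exons = ",".join(f"{s}-{e}" for s, e in t.exons)
                fh.write(f"{t.id}\t{t.chrom}\t{t.strand}\t{t.length}"
                         f"\t{rec['n_units']}"
                         f"\t{rec.get('realized_coverage', 'NA')}\t{exons}\n")
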