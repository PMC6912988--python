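"""Reading, collapsing and filtering of spliced SAM alignments.

Spliced RNA-seq alignments arrive as SAM records whose CIGAR ``N``
operations mark introns.  This module turns them into light-weight
:class:`AlignedRead` objects (0-based, half-open exon blocks), collapses
reads aligned to the identical genomic location into a single
:class:`CollapsedAlignment` with a multiplicity count and paired-mate
bookkeeping, and applies the spurious-spliced-alignment filters:

* a spliced read aligned with more than 1% mismatches is kept only if
  every one of its junctions is supported by 25% more reads than the
  default threshold (1 read);
* a spliced read spanning an intron longer than 100 kb is kept only if
  the junction has an anchor of at least 25 bp on both sides in at least
  one supporting read (the default anchor requirement is 10 bp).

Coordinates are 0-based half-open throughout; SAM input is converted on
the fly.  Multi-mapped reads (``NH`` > 1) contribute ``1/NH`` to counts
and junction support.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam

# CIGAR operation codes (pysam numeric encoding)
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N, _CIGAR_S = 0, 1, 2, 3, 4
_CIGAR_EQ, _CIGAR_X = 7, 8
_REF_IN_BLOCK = {_CIGAR_M, _CIGAR_D, _CIGAR_EQ, _CIGAR_X}
_READ_ONLY = {_CIGAR_I, _CIGAR_S}

# Filter defaults
MISMATCH_RATE_THRESHOLD = 0.01
SUPPORT_BOOST = 1.25
LONG_INTRON = 100_000
ANCHOR_DEFAULT = 10
ANCHOR_LONG_INTRON = 25
DEFAULT_MIN_JUNCTION_SUPPORT = 1.0


class SamParseError(ValueError):
    """Raised for malformed alignment records."""


@dataclass
class AlignedRead:
    """A single primary spliced alignment in 0-based half-open coordinates."""

    query_name: str
    reference_name: str
    start: int
    exon_blocks: tuple[tuple[int, int], ...]
    strand: str = "."          # XS tag: '+', '-' or '.' when absent
    mismatches: int = 0        # NM tag, 0 if absent
    nh: int = 1                # NH tag, 1 if absent
    weight: float = 1.0        # 1/NH, or the XC coverage tag for super-reads
    is_long_read: bool = False
    is_first_mate: bool = True
    mate_start: Optional[int] = None  # PNEXT (0-based) when mate maps to same ref

    @property
    def end(self) -> int:
        return self.exon_blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) pairs: half-open intron intervals between blocks."""
        blocks = self.exon_blocks
        return tuple((blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1))

    @property
    def mismatch_rate(self) -> float:
        alen = self.aligned_length
        return self.mismatches / alen if alen else 0.0

    @property
    def location_key(self) -> tuple:
        return (self.reference_name, self.strand, self.exon_blocks)

    def validate(self) -> None:
        prev_end = None
        for s, e in self.exon_blocks:
            if e <= s:
                raise SamParseError(f"empty exon block in read {self.query_name}")
            if prev_end is not None and s <= prev_end:
                raise SamParseError(f"unsorted/abutting blocks in read {self.query_name}")
            prev_end = e
        if self.mismatches > self.aligned_length:
            raise SamParseError(f"NM exceeds aligned length in read {self.query_name}")


@dataclass
class CollapsedAlignment:
    """A unique alignment location with a collapse count and mate links.

    ``mate_links`` maps the location key of a mate's collapsed alignment to
    the (weighted) number of fragments observed with that pairing.
    """

    reference_name: str
    strand: str
    exon_blocks: tuple[tuple[int, int], ...]
    count: float = 0.0
    mate_links: dict = field(default_factory=dict)

    @property
    def location_key(self) -> tuple:
        return (self.reference_name, self.strand, self.exon_blocks)

    @property
    def start(self) -> int:
        return self.exon_blocks[0][0]

    @property
    def end(self) -> int:
        return self.exon_blocks[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        b = self.exon_blocks
        return tuple((b[i][1], b[i + 1][0]) for i in range(len(b) - 1))

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)


@dataclass
class JunctionRecord:
    """Aggregate read support for one intron (donor, acceptor)."""

    donor: int
    acceptor: int
    strand: str = "."
    support: float = 0.0
    max_anchor_left: int = 0
    max_anchor_right: int = 0

    @property
    def length(self) -> int:
        return self.acceptor - self.donor


def cigar_to_blocks(start: int, cigartuples: Sequence[tuple[int, int]],
                    query_name: str = "?") -> tuple[tuple[int, int], ...]:
    """Walk a CIGAR, returning exon blocks in 0-based half-open coordinates.

    M/=/X and D advance the reference within the current block; N closes a
    block and opens the next; I and S advance the read only.
    """
    blocks: list[tuple[int, int]] = []
    pos = start
    block_start = start
    saw_aligned = False
    for op, length in cigartuples:
        if length < 0:
            raise SamParseError(f"negative CIGAR length in record {query_name}")
        if op in _REF_IN_BLOCK:
            pos += length
            if op != _CIGAR_D:
                saw_aligned = True
        elif op == _CIGAR_N:
            if pos == block_start:
                raise SamParseError(f"N without preceding aligned block in {query_name}")
            blocks.append((block_start, pos))
            pos += length
            block_start = pos
        elif op in _READ_ONLY or op in (5, 6):  # I, S, H, P
            continue
        else:
            raise SamParseError(f"unsupported CIGAR op {op} in record {query_name}")
    if pos > block_start:
        blocks.append((block_start, pos))
    if not blocks or not saw_aligned:
        raise SamParseError(f"CIGAR consumes no reference in record {query_name}")
    return tuple(blocks)


def trim_terminal_bases(blocks: Sequence[tuple[int, int]], left: int,
                        right: int) -> tuple[tuple[int, int], ...]:
    """Shave aligned bases off the outer ends of a block chain.

    Used to ignore the first and last k-1 bases of aligned super-reads,
    whose ends can extend into alternatively spliced exons.
    """
    out = [list(b) for b in blocks]
    rem = left
    while rem > 0 and out:
        take = min(rem, out[0][1] - out[0][0])
        out[0][0] += take
        rem -= take
        if out[0][0] >= out[0][1]:
            out.pop(0)
    rem = right
    while rem > 0 and out:
        take = min(rem, out[-1][1] - out[-1][0])
        out[-1][1] -= take
        rem -= take
        if out[-1][0] >= out[-1][1]:
            out.pop()
    return tuple(tuple(b) for b in out)


def parse_sam(path: str, is_long_read: bool = False,
              superread_k: Optional[int] = None) -> list[AlignedRead]:
    """Read a SAM file into :class:`AlignedRead` objects.

    Unmapped, secondary and supplementary records are skipped.  Tags
    consumed: NM (mismatches), NH (multiplicity; weight ``1/NH``), XS
    (strand), XC (super-read coverage; becomes the record weight).  When
    ``superread_k`` is given, XC-tagged records have their outer ``k-1``
    aligned bases trimmed.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None:
                raise SamParseError(f"record {rec.query_name} has no CIGAR")
            if rec.reference_name is None:
                raise SamParseError(f"record {rec.query_name} missing header sequence")
            blocks = cigar_to_blocks(rec.reference_start, rec.cigartuples,
                                     rec.query_name or "?")
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            weight = 1.0 / nh
            if rec.has_tag("XC"):
                weight = float(rec.get_tag("XC"))
                if superread_k and superread_k > 1:
                    blocks = trim_terminal_bases(blocks, superread_k - 1,
                                                 superread_k - 1)
                    if not blocks:
                        continue
            mate_start = None
            if rec.is_paired and not rec.mate_is_unmapped and \
                    rec.next_reference_id == rec.reference_id:
                mate_start = rec.next_reference_start
            read = AlignedRead(
                query_name=rec.query_name or "?",
                reference_name=rec.reference_name,
                start=blocks[0][0],
                exon_blocks=blocks,
                strand=rec.get_tag("XS") if rec.has_tag("XS") else ".",
                mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                nh=int(nh),
                weight=weight,
                is_long_read=is_long_read,
                is_first_mate=(not rec.is_paired) or rec.is_read1,
                mate_start=mate_start,
            )
            read.validate()
            reads.append(read)
    return reads


def build_junction_table(reads: Iterable[AlignedRead]
                         ) -> dict[tuple[str, int, int], JunctionRecord]:
    """Aggregate weighted junction support and maximal anchors over reads,
    keyed by (reference, donor, acceptor)."""
    table: dict[tuple[str, int, int], JunctionRecord] = {}
    for read in reads:
        blocks = read.exon_blocks
        for i, (donor, acceptor) in enumerate(read.introns):
            key = (read.reference_name, donor, acceptor)
            rec = table.get(key)
            if rec is None:
                rec = JunctionRecord(donor=donor, acceptor=acceptor, strand=read.strand)
                table[key] = rec
            rec.support += read.weight
            if rec.strand == "." and read.strand != ".":
                rec.strand = read.strand
            left = blocks[i][1] - blocks[i][0]
            right = blocks[i + 1][1] - blocks[i + 1][0]
            rec.max_anchor_left = max(rec.max_anchor_left, left)
            rec.max_anchor_right = max(rec.max_anchor_right, right)
    return table


def filter_spliced_alignment(
    read: AlignedRead,
    junctions: dict[tuple[int, int], JunctionRecord],
    min_junction_support: float = DEFAULT_MIN_JUNCTION_SUPPORT,
) -> tuple[bool, Optional[str]]:
    """Decide whether to keep one spliced alignment.

    Returns ``(keep, reason)`` where ``reason`` names the failed rule for
    dropped reads.  The junction table must be built from all reads of the
    bundle, before filtering.
    """
    introns = read.introns
    if not introns:
        return True, None
    high_mismatch = read.mismatch_rate > MISMATCH_RATE_THRESHOLD
    for intron in introns:
        rec = junctions.get((read.reference_name,) + intron)
        support = rec.support if rec else 0.0
        anchor_l = rec.max_anchor_left if rec else 0
        anchor_r = rec.max_anchor_right if rec else 0
        if high_mismatch and support < SUPPORT_BOOST * min_junction_support:
            return False, "high-mismatch read at weakly supported junction"
        required_anchor = ANCHOR_LONG_INTRON if (intron[1] - intron[0]) > LONG_INTRON \
            else ANCHOR_DEFAULT
        if anchor_l < required_anchor or anchor_r < required_anchor:
            return False, "junction anchor below %d bp" % required_anchor
    return True, None


def filter_reads(reads: Sequence[AlignedRead],
                 min_junction_support: float = DEFAULT_MIN_JUNCTION_SUPPORT,
                 ) -> tuple[list[AlignedRead], list[tuple[AlignedRead, str]]]:
    """Apply the spliced-alignment filters to a read collection."""
    table = build_junction_table(r for r in reads if len(r.exon_blocks) > 1)
    kept: list[AlignedRead] = []
    dropped: list[tuple[AlignedRead, str]] = []
    for read in reads:
        ok, reason = filter_spliced_alignment(read, table, min_junction_support)
        if ok:
            kept.append(read)
        else:
            dropped.append((read, reason or "filtered"))
    return kept, dropped


def collapse_alignments(reads: Sequence[AlignedRead]) -> list[CollapsedAlignment]:
    """Collapse reads aligned to the identical location, keeping counts.

    Reads aligned to the same (reference, strand, exon blocks) become one
    record whose ``count`` is the weighted number of collapsed alignments.
    Mate pairings are resolved by query name (cross-checked against PNEXT)
    and recorded with their multiplicity in ``mate_links`` on both ends;
    reads whose mate cannot be resolved stay unpaired.
    """
    cas: dict[tuple, CollapsedAlignment] = {}
    for read in reads:
        key = read.location_key
        ca = cas.get(key)
        if ca is None:
            ca = CollapsedAlignment(reference_name=read.reference_name,
                                    strand=read.strand,
                                    exon_blocks=read.exon_blocks)
            cas[key] = ca
        ca.count += read.weight

    by_qname: dict[str, list[AlignedRead]] = defaultdict(list)
    for read in reads:
        if read.mate_start is not None:
            by_qname[read.query_name].append(read)
    for group in by_qname.values():
        firsts = [r for r in group if r.is_first_mate]
        seconds = [r for r in group if not r.is_first_mate]
        if len(firsts) != 1 or len(seconds) != 1:
            continue
        a, b = firsts[0], seconds[0]
        if a.reference_name != b.reference_name:
            continue
        if a.mate_start != b.start or b.mate_start != a.start:
            continue
        w = min(a.weight, b.weight)
        ka, kb = a.location_key, b.location_key
        cas[ka].mate_links[kb] = cas[ka].mate_links.get(kb, 0.0) + w
        if ka != kb:
            cas[kb].mate_links[ka] = cas[kb].mate_links.get(ka, 0.0) + w
    return sorted(cas.values(), key=lambda c: (c.start, c.end, c.exon_blocks))
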