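"""Super-reads: k-unitig construction, read extension, EM coverage.

Short reads are extended into synthetic long "super-reads" by walking
*k-unitigs*: maximal sequences in which every k-mer except the first and
last has a unique preceding and following k-mer in the global k-mer table.
The table counts every k-mer of every read — including count-1 k-mers,
because transcripts can legitimately be covered by a single read — in
canonical orientation (a k-mer and its reverse complement share an entry).

Because many reads collapse into one super-read, each aligned super-read
carries a coverage estimate: reads are assigned to the aligned super-reads
that contain them as exact substrings (equivalently, whose k-unitig chain
contains the read's chain in order), and an expectation-maximization pass
distributes each read's mass across its super-reads in proportion to the
previous coverage estimates.  The estimate is emitted as an ``XC`` tag in
the super-read SAM so that downstream assembly can weight graph paths by
it, ignoring the first and last k-1 aligned bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pysam
from Bio import SeqIO

DEFAULT_K = 25
EM_TOLERANCE = 1e-6
EM_MAX_ITER = 1000

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KUnitig:
    """Maximal unambiguous k-mer chain (stored in canonical orientation)."""

    sequence: str
    k: int
    id: int = 0

    def __len__(self) -> int:
        return len(self.sequence)

    def kmers(self) -> list[str]:
        s, k = self.sequence, self.k
        return [s[i:i + k] for i in range(len(s) - k + 1)]


@dataclass
class SuperRead:
    """A short read extended along unique k-unitig paths."""

    id: str
    sequence: str
    k: int
    kunitig_chain: tuple[int, ...] = ()
    assigned_reads: list[tuple[str, float]] = field(default_factory=list)
    coverage: float = 0.0

    @property
    def trim(self) -> int:
        """Aligned bases ignored at each end (may extend into alternative
        exons)."""
        return self.k - 1


def _iter_sequences(reads) -> Iterable[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        path = str(reads)
        fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
        for rec in SeqIO.parse(path, fmt):
            yield rec.id, str(rec.seq).upper()
    else:
        for item in reads:
            if isinstance(item, str):
                yield "?", item.upper()
            else:
                yield item[0], item[1].upper()


def build_kmer_table(reads, k: int) -> dict[str, int]:
    """Count every k-mer of every read, canonically, with no minimum-count
    threshold; k-mers containing N are skipped."""
    if k < 2:
        raise ValueError("k must be >= 2")
    table: dict[str, int] = {}
    for _, seq in _iter_sequences(reads):
        if len(seq) < k:
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            c = canonical(kmer)
            table[c] = table.get(c, 0) + 1
    return table


def _neighbors(table: dict[str, int], kmer: str, forward: bool) -> list[str]:
    if forward:
        return [kmer[1:] + b for b in "ACGT" if canonical(kmer[1:] + b) in table]
    return [b + kmer[:-1] for b in "ACGT" if canonical(b + kmer[:-1]) in table]


def build_kunitigs(table: dict[str, int], k: int) -> list[KUnitig]:
    """Partition the k-mer table into maximal unambiguous chains.

    A k-mer with other than one successor (or predecessor) terminates a
    unitig.  The walk runs over oriented k-mers (both orientations of a
    finished unitig are marked visited, and finished unitigs are stored
    canonically), so every canonical k-mer ends up in exactly one unitig.
    Odd k avoids self-complementary k-mers.
    """
    visited: set[str] = set()
    seqs: set[str] = set()
    for seed in sorted(table):
        if seed in visited:
            continue
        # walk backwards to the chain start
        cur = seed
        back: set[str] = {seed}
        while True:
            preds = _neighbors(table, cur, forward=False)
            if len(preds) != 1:
                break
            prev = preds[0]
            if prev in visited or prev in back:
                break  # already placed, or a cycle closing on itself
            if len(_neighbors(table, prev, forward=True)) != 1:
                break
            back.add(prev)
            cur = prev
        # walk forwards collecting the chain
        chain = [cur]
        chain_set = {cur}
        while True:
            succs = _neighbors(table, chain[-1], forward=True)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if nxt in visited or nxt in chain_set:
                break
            if len(_neighbors(table, nxt, forward=False)) != 1:
                break
            chain.append(nxt)
            chain_set.add(nxt)
        for km in chain:
            visited.add(km)
            visited.add(revcomp(km))
        seq = chain[0] + "".join(km[-1] for km in chain[1:])
        seqs.add(min(seq, revcomp(seq)))
    return [KUnitig(sequence=s, k=k, id=i)
            for i, s in enumerate(sorted(seqs))]


def kunitig_index(kunitigs: Sequence[KUnitig]) -> dict[str, tuple[int, int]]:
    """Map each canonical k-mer to its unique (unitig id, offset)."""
    index: dict[str, tuple[int, int]] = {}
    for u in kunitigs:
        for pos, km in enumerate(u.kmers()):
            index[canonical(km)] = (u.id, pos)
    return index


def extend_to_superread(read: str, kunitigs: Sequence[KUnitig],
                        index: dict[str, tuple[int, int]], k: int
                        ) -> Optional[str]:
    """Extend a read to the ends of the unitigs containing its terminal
    k-mers; returns None when a terminal k-mer has no (or no unambiguous)
    unitig placement."""
    read = read.upper()
    if len(read) < k:
        return None
    first, last = read[:k], read[-k:]
    hit1 = index.get(canonical(first))
    hit2 = index.get(canonical(last))
    if hit1 is None or hit2 is None:
        return None
    u1 = kunitigs[hit1[0]]
    u2 = kunitigs[hit2[0]]
    at1 = u1.sequence[hit1[1]:hit1[1] + k]
    if first == at1:
        left = u1.sequence[:hit1[1]]
    elif revcomp(first) == at1:
        left = revcomp(u1.sequence[hit1[1] + k:])
    else:
        return None
    at2 = u2.sequence[hit2[1]:hit2[1] + k]
    if last == at2:
        right = u2.sequence[hit2[1] + k:]
    elif revcomp(last) == at2:
        right = revcomp(u2.sequence[:hit2[1]])
    else:
        return None
    sr = left + read + right
    return sr


def unitig_chain(sequence: str, index: dict[str, tuple[int, int]], k: int
                 ) -> tuple[int, ...]:
    """Ordered (deduplicated-consecutive) unitig ids along a sequence."""
    chain: list[int] = []
    for i in range(len(sequence) - k + 1):
        hit = index.get(canonical(sequence[i:i + k]))
        if hit is None:
            continue
        if not chain or chain[-1] != hit[0]:
            chain.append(hit[0])
    return tuple(chain)


def build_superreads(reads, kunitigs: Sequence[KUnitig], k: int
                     ) -> tuple[list[SuperRead], dict[str, Optional[str]]]:
    """Extend every read; deduplicate identical super-read sequences (up to
    reverse complement).  Returns the super-reads and a map from read id to
    the id of the super-read it produced (None when unextendable)."""
    index = kunitig_index(kunitigs)
    seen: dict[str, SuperRead] = {}
    produced: dict[str, Optional[str]] = {}
    counter = 0
    for rid, seq in _iter_sequences(reads):
        sr_seq = extend_to_superread(seq, kunitigs, index, k)
        if sr_seq is None:
            produced[rid] = None
            continue
        key = min(sr_seq, revcomp(sr_seq))
        sr = seen.get(key)
        if sr is None:
            sr = SuperRead(id=f"SR{counter}", sequence=sr_seq, k=k,
                           kunitig_chain=unitig_chain(sr_seq, index, k))
            seen[key] = sr
            counter += 1
        produced[rid] = sr.id
    return list(seen.values()), produced


def assign_reads(superreads: Sequence[SuperRead], reads,
                 ) -> dict[str, list[str]]:
    """Assign each read to every (aligned) super-read containing it — or its
    reverse complement — as an exact substring.

    Pass only super-reads with a genome alignment; unaligned super-reads do
    not participate in quantification.
    """
    assignments: dict[str, list[str]] = {}
    for rid, seq in _iter_sequences(reads):
        rc = revcomp(seq)
        hits = [sr.id for sr in superreads
                if seq in sr.sequence or rc in sr.sequence]
        if hits:
            assignments[rid] = hits
    for sr in superreads:
        sr.assigned_reads = []
    by_id = {sr.id: sr for sr in superreads}
    for rid, hits in assignments.items():
        for h in hits:
            by_id[h].assigned_reads.append((rid, 1.0))
    return assignments


def em_coverage(assignments: dict[str, list[str]],
                read_masses: Optional[dict[str, float]] = None,
                tolerance: float = EM_TOLERANCE,
                max_iter: int = EM_MAX_ITER,
                target_lengths: Optional[dict] = None,
                trace: Optional[list] = None) -> dict[str, float]:
    """EM distribution of read mass over super-reads (or any targets).

    The initial estimate sums the mass of reads uniquely assigned to one
    target; each iteration redistributes every read's mass proportionally
    to the previous coverage estimates (equal split when all of a read's
    targets have zero estimate).  With ``target_lengths``, proportionality
    uses per-bp density (mass / length) instead of raw mass — appropriate
    when targets of very different lengths compete for the same reads, as
    transcripts do.  Converges when the maximal change falls below
    ``tolerance`` relative to the total mass.  When ``trace`` is a list,
    per-iteration ``(total_mass, max_change)`` tuples are appended.
    """
    if not assignments:
        return {}
    if read_masses is None:
        read_masses = {rid: 1.0 for rid in assignments}
    targets = sorted({t for hits in assignments.values() for t in hits})

    def density(t, mass):
        if target_lengths is None:
            return mass
        return mass / max(target_lengths.get(t, 1.0), 1e-300)

    cov = {t: 0.0 for t in targets}
    for rid, hits in assignments.items():
        if len(hits) == 1:
            cov[hits[0]] += read_masses[rid]
    total = sum(read_masses[rid] for rid in assignments)
    scale = total if total > 0 else 1.0
    for _ in range(max_iter):
        new = {t: 0.0 for t in targets}
        for rid, hits in assignments.items():
            mass = read_masses[rid]
            dens = [density(t, cov[t]) for t in hits]
            denom = sum(dens)
            if denom <= 0.0:
                share = mass / len(hits)
                for t in hits:
                    new[t] += share
            else:
                for t, d in zip(hits, dens):
                    new[t] += mass * d / denom
        delta = max(abs(new[t] - cov[t]) for t in targets)
        cov = new
        if trace is not None:
            trace.append((sum(cov.values()), delta))
        if delta < tolerance * scale:
            break
    return cov


def emit_superread_sam(superreads: Sequence[SuperRead], alignment_sam: str,
                       out_sam: str, tag: str = "XC") -> int:
    """Copy the aligned super-read SAM, attaching each record's EM coverage
    as a float tag (default ``XC``).  Returns the number of tagged records."""
    cov = {sr.id: sr.coverage for sr in superreads}
    n = 0
    with pysam.AlignmentFile(alignment_sam, "r", check_sq=False) as sam_in, \
            pysam.AlignmentFile(out_sam, "wh", template=sam_in) as sam_out:
        for rec in sam_in:
            if rec.query_name in cov:
                rec.set_tag(tag, float(cov[rec.query_name]), value_type="f")
                n += 1
            sam_out.write(rec)
    return n


def quantify_superreads(superreads: Sequence[SuperRead], reads,
                        aligned_ids: Optional[set[str]] = None,
                        ) -> dict[str, float]:
    """Convenience pipeline: restrict to aligned super-reads, assign reads
    by exact substring, run EM, and store coverages on the objects."""
    pool = [sr for sr in superreads
            if aligned_ids is None or sr.id in aligned_ids]
    assignments = assign_reads(pool, reads)
    cov = em_coverage(assignments)
    for sr in pool:
        sr.coverage = cov.get(sr.id, 0.0)
    return cov
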