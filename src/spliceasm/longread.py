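"""Long-read mode: splice-site correction, graph pruning, re-encoding.

Third-generation RNA-seq reads carry indel-dominated errors that misplace
spliced-alignment boundaries around splice sites.  For a read whose
alignment has a high error rate, every splice site unsupported by any
low-error alignment is moved to the nearby site (within a 10 bp window by
default) with the most total alignment support, provided that site has
low-error support.  Low-error reads are never modified.

In regions of very high coverage the splice graph can still accumulate
spurious nodes and edges; the pruning pass removes edges from the least
supported to the most supported until the node count falls under a budget
(1000 nodes by default).  A node that loses all incident edges and has no
unspliced read evidence is dropped, and reads spanning dropped nodes are
re-encoded as interrupted paths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .alignment_io import AlignedRead
from .splice_graph import BitPath, SpliceGraph, _contiguous

DEFAULT_CORRECTION_WINDOW = 10
# Error rate (mismatches / aligned length) above which a long read's splice
# sites are candidates for correction.  Chosen above the Illumina-level 1%
# short-read rule; configurable because instrument error profiles vary.
DEFAULT_HIGH_ERROR_THRESHOLD = 0.02
DEFAULT_MAX_NODES = 1000

_DONOR, _ACCEPTOR = "donor", "acceptor"


@dataclass
class SpliceSiteSupport:
    site: int
    side: str                   # "donor" (intron start) | "acceptor" (intron end)
    strand: str = "."
    low_error_support: float = 0.0
    total_support: float = 0.0


@dataclass
class CorrectionEvent:
    query_name: str
    side: str
    old_site: int
    new_site: int
    support: float
    applied: bool = True
    reference_name: str = "?"


@dataclass
class PruneEvent:
    removed_edge: tuple[int, int]
    support_at_removal: float
    node_count_after: int


def build_site_support(reads: Sequence[AlignedRead],
                       high_error_threshold: float = DEFAULT_HIGH_ERROR_THRESHOLD,
                       guides=None) -> dict[tuple[str, str, int], SpliceSiteSupport]:
    """Tabulate per splice site the total and low-error alignment support,
    keyed by (reference, side, coordinate).

    Guide transcripts, when given, contribute their splice sites as
    low-error support of weight 1.
    """
    table: dict[tuple[str, str, int], SpliceSiteSupport] = {}

    def add(ref: str, side: str, pos: int, weight: float, low_error: bool,
            strand: str):
        rec = table.get((ref, side, pos))
        if rec is None:
            rec = SpliceSiteSupport(site=pos, side=side, strand=strand)
            table[(ref, side, pos)] = rec
        rec.total_support += weight
        if low_error:
            rec.low_error_support += weight

    for read in reads:
        low = read.mismatch_rate <= high_error_threshold
        for (d, a) in read.introns:
            add(read.reference_name, _DONOR, d, read.weight, low, read.strand)
            add(read.reference_name, _ACCEPTOR, a, read.weight, low, read.strand)
    for g in (guides or []):
        for k in range(len(g.exons) - 1):
            add(g.chrom, _DONOR, g.exons[k][1], 1.0, True, g.strand)
            add(g.chrom, _ACCEPTOR, g.exons[k + 1][0], 1.0, True, g.strand)
    return table


def _best_nearby_site(table, ref: str, side: str, pos: int,
                      window: int) -> Optional[int]:
    """Supported site within +-window with maximal total support; ties go to
    the smallest absolute distance, then the smaller coordinate."""
    best = None
    for cand in range(pos - window, pos + window + 1):
        rec = table.get((ref, side, cand))
        if rec is None or rec.low_error_support <= 0:
            continue
        key = (rec.total_support, -abs(cand - pos), -cand)
        if best is None or key > best[0]:
            best = (key, cand)
    return best[1] if best else None


def correct_splice_sites(
    reads: Sequence[AlignedRead],
    support: dict[tuple[str, int], SpliceSiteSupport],
    window: int = DEFAULT_CORRECTION_WINDOW,
    high_error_threshold: float = DEFAULT_HIGH_ERROR_THRESHOLD,
) -> tuple[list[AlignedRead], list[CorrectionEvent]]:
    """Move unsupported splice sites of high-error reads to nearby supported
    sites.

    For each splice site of each high-error read: if no low-error alignment
    supports the site, it is replaced by the site within ``window`` bp with
    maximal total support among sites that have low-error support.  A
    correction that would create an empty exon or inverted block is skipped
    and logged.  Low-error reads pass through unchanged.
    """
    corrected: list[AlignedRead] = []
    log: list[CorrectionEvent] = []
    for read in reads:
        if read.mismatch_rate <= high_error_threshold or len(read.exon_blocks) < 2:
            corrected.append(read)
            continue
        blocks = [list(b) for b in read.exon_blocks]
        ref = read.reference_name
        for k in range(len(blocks) - 1):
            for side, idx, col in ((_DONOR, k, 1), (_ACCEPTOR, k + 1, 0)):
                pos = blocks[idx][col]
                rec = support.get((ref, side, pos))
                if rec is not None and rec.low_error_support > 0:
                    continue
                new_pos = _best_nearby_site(support, ref, side, pos, window)
                if new_pos is None:
                    continue
                old = blocks[idx][col]
                blocks[idx][col] = new_pos
                exon_ok = blocks[idx][1] > blocks[idx][0]
                intron_ok = blocks[k + 1][0] > blocks[k][1]
                sup = support[(ref, side, new_pos)].total_support
                if exon_ok and intron_ok:
                    log.append(CorrectionEvent(read.query_name, side, old,
                                               new_pos, sup, applied=True,
                                               reference_name=ref))
                else:
                    blocks[idx][col] = old
                    log.append(CorrectionEvent(read.query_name, side, old,
                                               new_pos, sup, applied=False,
                                               reference_name=ref))
        new_blocks = tuple(tuple(b) for b in blocks)
        if new_blocks != read.exon_blocks:
            read = replace(read, exon_blocks=new_blocks, start=new_blocks[0][0])
        corrected.append(read)
    return corrected, log


def write_correction_log(events: Sequence[CorrectionEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treference\tside\told_site\tnew_site\tsupport\tapplied\n")
        for ev in events:
            fh.write(f"{ev.query_name}\t{ev.reference_name}\t{ev.side}"
                     f"\t{ev.old_site}\t{ev.new_site}"
                     f"\t{ev.support:g}\t{int(ev.applied)}\n")


# ------------------------------------------------------------------
# graph pruning (splice-graph size budget)
# ------------------------------------------------------------------

def prune_graph(graph: SpliceGraph, max_nodes: int = DEFAULT_MAX_NODES,
                ) -> tuple[SpliceGraph, list[PruneEvent], list[Optional[int]]]:
    """Remove edges from least to most supported until the node count falls
    under ``max_nodes``.

    Ties break on the smaller ``(i, j)`` pair.  A node with no incident
    edges left and no unspliced read coverage is dropped.  Guide-derived
    edges are never removed.  Returns the pruned graph (nodes renumbered),
    the ordered removal log (original node indices; supports non-decreasing),
    and the old-to-new node index map (``None`` for dropped nodes).
    """
    alive_nodes = set(range(graph.n))
    alive_edges = dict(graph.edges)
    incident: dict[int, set[tuple[int, int]]] = {i: set() for i in alive_nodes}
    for (i, j) in alive_edges:
        incident[i].add((i, j))
        incident[j].add((i, j))

    removable = sorted(((e.support, ij) for ij, e in alive_edges.items()
                        if not e.from_guide), key=lambda t: (t[0], t[1]))
    events: list[PruneEvent] = []

    def drop_if_isolated(v: int):
        if not incident[v] and graph.unspliced_support[v] <= 0:
            alive_nodes.discard(v)

    for support, (i, j) in removable:
        if len(alive_nodes) < max_nodes:
            break
        del alive_edges[(i, j)]
        incident[i].discard((i, j))
        incident[j].discard((i, j))
        drop_if_isolated(i)
        drop_if_isolated(j)
        events.append(PruneEvent((i, j), support, len(alive_nodes)))

    node_map: list[Optional[int]] = [None] * graph.n
    new_index = 0
    kept = sorted(alive_nodes)
    for old in kept:
        node_map[old] = new_index
        new_index += 1
    pruned = SpliceGraph([graph.nodes[i] for i in kept],
                         graph.reference_name, graph.strand)
    pruned.node_cov = graph.node_cov[kept].copy() if kept else np.zeros(0)
    pruned.unspliced_support = (graph.unspliced_support[kept].copy()
                                if kept else np.zeros(0))
    pruned.profile_start = graph.profile_start
    pruned.profile = graph.profile
    for (i, j), edge in alive_edges.items():
        ni, nj = node_map[i], node_map[j]
        if ni is not None and nj is not None:
            pruned.add_edge(ni, nj, edge.support, kind=edge.kind,
                            from_guide=edge.from_guide)
    return pruned, events, node_map


def reencode_after_pruning(path: BitPath, node_map: Sequence[Optional[int]],
                           pruned: SpliceGraph) -> BitPath:
    """Re-express a bit path on the pruned graph.

    Bits of removed nodes/edges are cleared; if the surviving bits are no
    longer contiguous along the read, the path becomes interrupted with the
    surviving parts retained.  A path whose bits are all removed comes back
    empty (the read is then excluded from assembly).
    """
    node_bits = set()
    overlap = {}
    for v in path.node_bits:
        nv = node_map[v]
        if nv is not None:
            node_bits.add(nv)
            if v in path.node_overlap:
                overlap[nv] = path.node_overlap[v]
    edge_bits = set()
    for (i, j) in path.edge_bits:
        ni, nj = node_map[i], node_map[j]
        if ni is not None and nj is not None and (ni, nj) in pruned.edges:
            edge_bits.add((ni, nj))
    interrupted = path.interrupted or not _contiguous(pruned, node_bits, edge_bits)
    if not node_bits:
        interrupted = False
    return BitPath(graph=pruned, node_bits=frozenset(node_bits),
                   edge_bits=frozenset(edge_bits), interrupted=interrupted,
                   node_overlap=overlap, weight=path.weight,
                   span=path.span, aligned_length=path.aligned_length,
                   blocks=path.blocks, cdna_span=path.cdna_span)
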