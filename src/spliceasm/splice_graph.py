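"""Bundles, splice-graph construction and bit-vector read paths.

A *bundle* is a maximal genomic region of overlapping alignments — a
putative gene locus — processed as one assembly unit.  Within a bundle the
*splice graph* is a DAG whose nodes are exonic segments delimited by splice
sites and coverage boundaries, and whose edges are junctions or within-exon
adjacencies weighted by read support.

Reads, fragments and transcripts are encoded on the graph as bit paths.
The dense layout assigns bit ``i`` to node ``i`` and bit ``n + n*i + j`` to
edge ``(i, j)`` (node bits first, then the edge region offset by ``n``).
Because most possible edges are absent, the working representation is
sparse: a :class:`BitPath` stores only the node indices and edge pairs a
read touches, with an ``interrupted`` flag for paths with gaps (paired
fragments, or long reads that span pruned nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignment_io import CollapsedAlignment

DEFAULT_MAX_GAP = 50


@dataclass
class Bundle:
    """A maximal group of alignments whose spans are within ``max_gap``."""

    reference_name: str
    start: int
    end: int
    alignments: list[CollapsedAlignment] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def build_bundles(alignments: Sequence[CollapsedAlignment],
                  max_gap: int = DEFAULT_MAX_GAP) -> list[Bundle]:
    """Partition alignments (sorted by start) into gap-separated bundles.

    Consecutive alignments join one bundle iff the genomic gap between the
    region covered so far and the next alignment span is <= ``max_gap``.
    """
    bundles: list[Bundle] = []
    current: Optional[Bundle] = None
    for ca in sorted(alignments, key=lambda c: (c.reference_name, c.start, c.end)):
        if (current is None or ca.reference_name != current.reference_name
                or ca.start - current.end > max_gap):
            current = Bundle(ca.reference_name, ca.start, ca.end)
            bundles.append(current)
        current.alignments.append(ca)
        current.end = max(current.end, ca.end)
        current.start = min(current.start, ca.start)
    return bundles


@dataclass
class Edge:
    support: float = 0.0
    kind: str = "junction"      # "junction" | "adjacency"
    from_guide: bool = False


class SpliceGraph:
    """Per-bundle DAG of exonic segment nodes and junction/adjacency edges.

    Nodes are half-open genomic intervals sorted by start; every edge
    ``(i, j)`` has ``i < j``, so the genomic order is a topological order.
    """

    def __init__(self, nodes: Sequence[tuple[int, int]],
                 reference_name: str = "?", strand: str = "."):
        self.reference_name = reference_name
        self.strand = strand
        self.nodes: list[tuple[int, int]] = list(nodes)
        for (s, e) in self.nodes:
            if e <= s:
                raise ValueError("empty splice-graph node")
        for a, b in zip(self.nodes, self.nodes[1:]):
            if b[0] < a[0]:
                raise ValueError("splice-graph nodes must be sorted")
        self.node_cov = np.zeros(len(self.nodes))
        self.unspliced_support = np.zeros(len(self.nodes))
        self.edges: dict[tuple[int, int], Edge] = {}
        self._start_index = {s: i for i, (s, e) in enumerate(self.nodes)}
        self._end_index = {e: i for i, (s, e) in enumerate(self.nodes)}
        # per-bp coverage profile over the bundle span, used for end trimming
        self.profile_start: int = self.nodes[0][0] if self.nodes else 0
        self.profile: Optional[np.ndarray] = None

    # -- basics --------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    def node_length(self, i: int) -> int:
        s, e = self.nodes[i]
        return e - s

    def add_edge(self, i: int, j: int, support: float = 0.0,
                 kind: str = "junction", from_guide: bool = False) -> Edge:
        if not (0 <= i < j < self.n):
            raise ValueError(f"edge ({i},{j}) out of range or not i<j")
        edge = self.edges.get((i, j))
        if edge is None:
            edge = Edge(kind=kind, from_guide=from_guide)
            self.edges[(i, j)] = edge
        edge.support += support
        edge.from_guide = edge.from_guide or from_guide
        return edge

    def out_edges(self, i: int) -> list[tuple[int, int]]:
        return [e for e in self.edges if e[0] == i]

    def in_edges(self, j: int) -> list[tuple[int, int]]:
        return [e for e in self.edges if e[1] == j]

    def node_at_start(self, pos: int) -> Optional[int]:
        return self._start_index.get(pos)

    def node_at_end(self, pos: int) -> Optional[int]:
        return self._end_index.get(pos)

    def nodes_overlapping(self, s: int, e: int) -> list[int]:
        return [i for i, (ns, ne) in enumerate(self.nodes) if ns < e and ne > s]


@dataclass
class BitPath:
    """Sparse bit-vector path of a read, fragment or transcript on a graph."""

    graph: SpliceGraph
    node_bits: frozenset[int]
    edge_bits: frozenset[tuple[int, int]]
    interrupted: bool = False
    # aligned bp of the read within each touched node (for capacity estimates)
    node_overlap: dict[int, int] = field(default_factory=dict)
    weight: float = 0.0
    span: int = 0               # genomic span of the alignment(s)
    aligned_length: int = 0
    blocks: tuple[tuple[int, int], ...] = ()  # all aligned blocks, genomic
    cdna_span: int = 0          # aligned bases plus any unobserved mate gap

    def is_empty(self) -> bool:
        return not self.node_bits

    def parts(self) -> list[list[int]]:
        """Contiguous runs of the path: consecutive set nodes linked by a
        set edge belong to one part; gaps split parts."""
        order = sorted(self.node_bits)
        runs: list[list[int]] = []
        for v in order:
            if runs and (runs[-1][-1], v) in self.edge_bits:
                runs[-1].append(v)
            else:
                runs.append([v])
        return runs


def encode_path_dense(n: int, node_set: Iterable[int],
                      edge_set: Iterable[tuple[int, int]]) -> list[int]:
    """Dense bit indices: node ``i`` -> bit ``i``; edge ``(i,j)`` -> bit
    ``n + n*i + j`` (edge region offset past the node bits)."""
    bits = set()
    for i in node_set:
        if not 0 <= i < n:
            raise ValueError(f"node index {i} out of range")
        bits.add(i)
    for i, j in edge_set:
        if i >= j:
            raise ValueError(f"edge ({i},{j}) must have i < j")
        if j >= n:
            raise ValueError(f"edge ({i},{j}) out of range")
        bits.add(n + n * i + j)
    return sorted(bits)


def dense_bits(path: BitPath) -> list[int]:
    """Dense encoding of a sparse path (restricted to existing nodes/edges)."""
    return encode_path_dense(path.graph.n, path.node_bits, path.edge_bits)


def _contiguous(graph: SpliceGraph, node_bits: set[int],
                edge_bits: set[tuple[int, int]]) -> bool:
    order = sorted(node_bits)
    return all((a, b) in edge_bits for a, b in zip(order, order[1:]))


def encode_path_sparse(graph: SpliceGraph,
                       block_chains: Sequence[Sequence[tuple[int, int]]],
                       weight: float = 1.0) -> BitPath:
    """Encode one or more exon-block chains (a read, or both mates of a
    fragment) as a sparse bit path on the graph.

    Node bits are set for every node the blocks overlap; edge bits for every
    junction of the chains present in the graph and for every within-exon
    adjacency a single block spans.  Junctions absent from the graph
    (filtered or pruned) are skipped and the path flagged interrupted; the
    unobserved gap of a paired fragment likewise yields an interrupted path.
    """
    node_bits: set[int] = set()
    edge_bits: set[tuple[int, int]] = set()
    overlap: dict[int, int] = {}
    missing_junction = False
    span_lo, span_hi, alen = None, None, 0
    for blocks in block_chains:
        for (s, e) in blocks:
            alen += e - s
            span_lo = s if span_lo is None else min(span_lo, s)
            span_hi = e if span_hi is None else max(span_hi, e)
            touched = graph.nodes_overlapping(s, e)
            for i in touched:
                ns, ne = graph.nodes[i]
                node_bits.add(i)
                overlap[i] = overlap.get(i, 0) + min(e, ne) - max(s, ns)
            # adjacency edges for node boundaries this block spans
            for a, b in zip(touched, touched[1:]):
                if graph.nodes[a][1] == graph.nodes[b][0] and (a, b) in graph.edges:
                    edge_bits.add((a, b))
        for k in range(len(blocks) - 1):
            donor, acceptor = blocks[k][1], blocks[k + 1][0]
            i = graph.node_at_end(donor)
            j = graph.node_at_start(acceptor)
            if i is not None and j is not None and (i, j) in graph.edges:
                edge_bits.add((i, j))
            else:
                missing_junction = True
    interrupted = missing_junction or len(block_chains) > 1
    if node_bits and _contiguous(graph, node_bits, edge_bits):
        interrupted = False
    all_blocks = tuple(sorted(tuple(b) for blocks in block_chains
                              for b in blocks))
    chains = sorted((tuple(map(tuple, c)) for c in block_chains if c),
                    key=lambda c: c[0][0])
    mate_gap = sum(max(0, b[0][0] - a[-1][1]) for a, b in zip(chains, chains[1:]))
    return BitPath(graph=graph, node_bits=frozenset(node_bits),
                   edge_bits=frozenset(edge_bits), interrupted=interrupted,
                   node_overlap=overlap, weight=weight,
                   span=(span_hi - span_lo) if span_lo is not None else 0,
                   aligned_length=alen, blocks=all_blocks,
                   cdna_span=alen + mate_gap)


def transcript_path(graph: SpliceGraph, node_seq: Sequence[int]) -> BitPath:
    """Bit path of a source-to-sink transcript given its node sequence."""
    edges = set()
    for a, b in zip(node_seq, node_seq[1:]):
        if (a, b) not in graph.edges:
            raise ValueError(f"transcript uses missing edge ({a},{b})")
        edges.add((a, b))
    return BitPath(graph=graph, node_bits=frozenset(node_seq),
                   edge_bits=frozenset(edges), interrupted=False)


def path_compatible(read_path: BitPath, tpath: BitPath) -> bool:
    """True iff a read (or fragment) can originate from a transcript path.

    Every bit of the read must be set in the transcript, and within each
    continuous part of the read the transcript must not visit a node the
    read skips without the corresponding shared junction.  Interrupted
    reads only require containment of each part (the transcript, being a
    path, is connected across the gaps).
    """
    if read_path.graph is not tpath.graph:
        raise ValueError("paths from different graphs are not comparable")
    if not read_path.node_bits <= tpath.node_bits:
        return False
    if not read_path.edge_bits <= tpath.edge_bits:
        return False
    tnodes = tpath.node_bits
    for part in read_path.parts():
        lo, hi = part[0], part[-1]
        covered = set(part)
        for v in tnodes:
            if lo < v < hi and v not in covered:
                return False
    return True


# ------------------------------------------------------------------
# graph construction
# ------------------------------------------------------------------

def _covered_intervals(mask: np.ndarray, offset: int) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]])) + 1
    return [(int(s) + offset, int(e) + offset) for s, e in zip(starts, ends)]


def build_splice_graph(bundle: Bundle, strand: str = ".",
                       guides=None) -> SpliceGraph:
    """Build the splice graph of one bundle (for one strand).

    Alignments of the bundle matching ``strand`` participate; strand-unknown
    alignments contribute to every strand graph of the bundle.  Node
    boundaries are the union of junction donor/acceptor sites and the
    endpoints of maximal covered regions (plus guide exon boundaries);
    nodes are the covered segments between consecutive boundaries.  Guides
    constrain structure only: their exons and junctions enter with zero
    read support.
    """
    cas = [ca for ca in bundle.alignments if ca.strand in (strand, ".")
           or strand == "."]
    guide_list = list(guides) if guides else []
    if not cas and not guide_list:
        return SpliceGraph([], bundle.reference_name, strand)

    lo = bundle.start
    hi = bundle.end
    for g in guide_list:
        lo = min(lo, g.exons[0][0])
        hi = max(hi, g.exons[-1][1])
    length = hi - lo

    mask = np.zeros(length, dtype=bool)
    profile = np.zeros(length)
    boundaries: set[int] = set()
    junctions: dict[tuple[int, int], float] = {}
    for ca in cas:
        for (s, e) in ca.exon_blocks:
            mask[s - lo:e - lo] = True
            profile[s - lo:e - lo] += ca.count
        for intron in ca.introns:
            junctions[intron] = junctions.get(intron, 0.0) + ca.count
    guide_junctions: set[tuple[int, int]] = set()
    for g in guide_list:
        for (s, e) in g.exons:
            mask[s - lo:e - lo] = True
        for k in range(len(g.exons) - 1):
            guide_junctions.add((g.exons[k][1], g.exons[k + 1][0]))
    for (d, a) in list(junctions) + list(guide_junctions):
        boundaries.add(d)
        boundaries.add(a)

    covered = _covered_intervals(mask, lo)
    for (s, e) in covered:
        boundaries.add(s)
        boundaries.add(e)

    # split covered intervals at boundaries -> nodes
    cuts = sorted(boundaries)
    nodes: list[tuple[int, int]] = []
    for (s, e) in covered:
        inner = [c for c in cuts if s < c < e]
        prev = s
        for c in inner + [e]:
            nodes.append((prev, c))
            prev = c
    nodes.sort()

    graph = SpliceGraph(nodes, bundle.reference_name, strand)
    graph.profile_start = lo
    graph.profile = profile

    # node coverage and unspliced support
    for ca in cas:
        single = len(ca.exon_blocks) == 1
        for (s, e) in ca.exon_blocks:
            for i in graph.nodes_overlapping(s, e):
                ns, ne = graph.nodes[i]
                ov = min(e, ne) - max(s, ns)
                graph.node_cov[i] += ca.count * ov / (ne - ns)
                if single:
                    graph.unspliced_support[i] += ca.count

    # junction edges
    for (d, a), support in junctions.items():
        i, j = graph.node_at_end(d), graph.node_at_start(a)
        if i is not None and j is not None and i < j:
            graph.add_edge(i, j, support, kind="junction")
    for (d, a) in guide_junctions:
        i, j = graph.node_at_end(d), graph.node_at_start(a)
        if i is not None and j is not None and i < j:
            graph.add_edge(i, j, 0.0, kind="junction", from_guide=True)

    # adjacency edges: contiguous nodes with >=1 read block spanning the shared
    # boundary (coverage abutment alone does not connect)
    contiguous_pairs = {(i, i + 1) for i in range(graph.n - 1)
                        if graph.nodes[i][1] == graph.nodes[i + 1][0]}
    for ca in cas:
        for (s, e) in ca.exon_blocks:
            touched = graph.nodes_overlapping(s, e)
            for a, b in zip(touched, touched[1:]):
                if (a, b) in contiguous_pairs:
                    graph.add_edge(a, b, ca.count, kind="adjacency")
    return graph


def bundle_strands(bundle: Bundle) -> list[str]:
    """Strands to assemble for a bundle: the XS strands of its spliced
    alignments, or '.' when none carries strand information."""
    strands = sorted({ca.strand for ca in bundle.alignments
                      if len(ca.exon_blocks) > 1 and ca.strand != "."})
    return strands if strands else ["."]
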