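"""Bundling, splice-graph construction, bit-path encoding, compatibility."""

import numpy as np
import pytest

from spliceasm.alignment_io import CollapsedAlignment, collapse_alignments
from spliceasm.splice_graph import (BitPath, Bundle, SpliceGraph,
                                    build_bundles, build_splice_graph,
                                    bundle_strands, dense_bits,
                                    encode_path_dense, encode_path_sparse,
                                    path_compatible, transcript_path)

from conftest import make_read


def mkca(blocks, count=1.0, strand="+", ref="chr1"):
    return CollapsedAlignment(reference_name=ref, strand=strand,
                              exon_blocks=tuple(map(tuple, blocks)),
                              count=count)


class TestBundles:
    def test_gap_within_limit_merges(self):
        cas = [mkca([(0, 100)]), mkca([(120, 200)])]
        assert len(build_bundles(cas, max_gap=50)) == 1

    def test_gap_above_limit_splits(self):
        cas = [mkca([(0, 100)]), mkca([(120, 200)])]
        assert len(build_bundles(cas, max_gap=10)) == 2

    def test_mixed_gaps(self):
        # gaps are 40 and 260 bp
        cas = [mkca([(0, 100)]), mkca([(140, 200)]), mkca([(460, 500)])]
        assert len(build_bundles(cas, max_gap=300)) == 1
        assert len(build_bundles(cas, max_gap=50)) == 2
        assert len(build_bundles(cas, max_gap=10)) == 3

    def test_partition_every_alignment_in_one_bundle(self):
        rng = np.random.default_rng(5)
        cas = sorted((mkca([(int(s), int(s) + int(rng.integers(10, 200)))])
                      for s in rng.integers(0, 10_000, size=60)),
                     key=lambda c: c.start)
        bundles = build_bundles(cas, max_gap=50)
        assert sum(len(b.alignments) for b in bundles) == len(cas)
        spans = sorted((b.start, b.end) for b in bundles)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 > 50


class TestBuildGraph:
    def test_single_exon(self):
        b = build_bundles([mkca([(0, 100)], 5)])[0]
        g = build_splice_graph(b, "+")
        assert g.n == 1 and g.edges == {}
        assert g.node_cov[0] == pytest.approx(5.0)

    def test_single_junction_uncovered_intron(self):
        b = build_bundles([mkca([(0, 50), (200, 250)], 3)])[0]
        g = build_splice_graph(b, "+")
        assert g.nodes == [(0, 50), (200, 250)]
        assert set(g.edges) == {(0, 1)}
        assert g.edges[(0, 1)].support == pytest.approx(3.0)

    def test_shared_donor_two_junctions(self):
        cas = [mkca([(0, 50), (200, 250)], 2),
               mkca([(0, 50), (300, 350)], 1)]
        b = build_bundles(cas)[0]
        g = build_splice_graph(b, "+")
        assert g.nodes == [(0, 50), (200, 250), (300, 350)]
        assert set(g.edges) == {(0, 1), (0, 2)}

    def test_adjacency_requires_spanning_read(self):
        # junction (20,50) cuts the covered region [0,120) into three nodes;
        # blocks across the cuts create adjacency edges
        cas = [mkca([(0, 100)], 4),
               mkca([(0, 20), (50, 120)], 2)]
        b = build_bundles(cas)[0]
        g = build_splice_graph(b, "+")
        assert g.nodes == [(0, 20), (20, 50), (50, 120)]
        assert g.edges[(0, 2)].kind == "junction"
        assert g.edges[(0, 1)].kind == "adjacency"
        assert g.edges[(1, 2)].kind == "adjacency"
        assert g.edges[(0, 1)].support == pytest.approx(4.0)

    def test_guides_constrain_without_support(self, small_dataset):
        loc = small_dataset.loci[0]
        b = Bundle(loc.chrom, loc.transcripts[0].start,
                   loc.transcripts[0].end, [])
        b.alignments = [mkca([loc.transcripts[0].exons[0]], 1.0,
                             strand=loc.strand, ref=loc.chrom)]
        g = build_splice_graph(b, loc.strand, guides=loc.transcripts[:1])
        guide_edges = [e for e, d in g.edges.items() if d.from_guide]
        assert guide_edges and all(g.edges[e].support == 0 for e in guide_edges)


class TestDenseEncoding:
    def test_offset_convention(self):
        # node bits 0..n-1, edge (i,j) at bit n + n*i + j
        assert encode_path_dense(4, {1, 2}, {(1, 2)}) == [1, 2, 10]
        assert encode_path_dense(5, set(), {(0, 4)}) == [9]
        assert encode_path_dense(4, set(), set()) == []

    def test_invalid_edge_rejected(self):
        with pytest.raises(ValueError):
            encode_path_dense(4, set(), {(2, 2)})
        with pytest.raises(ValueError):
            encode_path_dense(4, set(), {(3, 1)})

    def test_dense_sparse_equivalence_random(self):
        """Decoding a sparse path gives exactly the dense bit set."""
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(2, 10))
            nodes = [(i * 100, i * 100 + 50) for i in range(n)]
            g = SpliceGraph(nodes)
            for i in range(n - 1):
                g.add_edge(i, i + 1, 1.0)
            k = int(rng.integers(1, n + 1))
            start = int(rng.integers(0, n - k + 1))
            blocks = [nodes[j] for j in range(start, start + k)]
            path = encode_path_sparse(g, [blocks])
            expect = encode_path_dense(n, path.node_bits, path.edge_bits)
            assert dense_bits(path) == expect


class TestSparseEncoding:
    def _chain_graph(self):
        g = SpliceGraph([(0, 100), (200, 300), (400, 500), (600, 700)])
        g.add_edge(0, 1, 1)
        g.add_edge(1, 2, 1)
        g.add_edge(2, 3, 1)
        g.add_edge(1, 3, 1)
        return g

    def test_single_node_read(self):
        g = self._chain_graph()
        p = encode_path_sparse(g, [[(210, 290)]])
        assert p.node_bits == {1} and not p.edge_bits and not p.interrupted

    def test_junction_read(self):
        g = self._chain_graph()
        p = encode_path_sparse(g, [[(250, 300), (600, 650)]])
        assert p.node_bits == {1, 3}
        assert p.edge_bits == {(1, 3)} and not p.interrupted

    def test_mate_pair_interrupted(self):
        g = self._chain_graph()
        p = encode_path_sparse(g, [[(0, 50)], [(620, 680)]])
        assert p.node_bits == {0, 3} and not p.edge_bits
        assert p.interrupted

    def test_filtered_junction_reencoded_interrupted(self):
        g = self._chain_graph()
        # junction 300->450 absent from graph edges
        p = encode_path_sparse(g, [[(250, 300), (450, 500)]])
        assert p.node_bits == {1, 2} and p.interrupted


def _random_case(rng):
    n = int(rng.integers(3, 9))
    g = SpliceGraph([(i * 100, i * 100 + 50) for i in range(n)])
    # random DAG edges plus a guaranteed chain for the transcript
    tlen = int(rng.integers(2, n + 1))
    tnodes = sorted(rng.choice(n, size=tlen, replace=False).tolist())
    for a, b in zip(tnodes, tnodes[1:]):
        g.add_edge(a, b, 1)
    for _ in range(int(rng.integers(0, 6))):
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, n))
        g.add_edge(i, j, 1)
    tpath = transcript_path(g, tnodes)
    # random read: one or two parts, each a contiguous run of graph nodes
    nparts = int(rng.integers(1, 3))
    parts = []
    for _ in range(nparts):
        ln = int(rng.integers(1, 4))
        s = int(rng.integers(0, n))
        run = [v for v in range(s, min(n, s + ln))]
        parts.append(run)
    node_bits, edge_bits = set(), set()
    for run in parts:
        node_bits.update(run)
        for a, b in zip(run, run[1:]):
            if (a, b) in g.edges:
                edge_bits.add((a, b))
    read = BitPath(graph=g, node_bits=frozenset(node_bits),
                   edge_bits=frozenset(edge_bits),
                   interrupted=True)
    read = BitPath(graph=g, node_bits=read.node_bits,
                   edge_bits=read.edge_bits,
                   interrupted=not all(
                       (a, b) in edge_bits for a, b in
                       zip(sorted(node_bits), sorted(node_bits)[1:])))
    return g, tnodes, tpath, read


def _oracle_compatible(tnodes, read):
    """Brute force: each read part must embed as a contiguous subsequence of
    the transcript's node sequence; a continuous read must embed whole."""
    if not read.node_bits <= set(tnodes):
        return False
    if not read.edge_bits <= set(zip(tnodes, tnodes[1:])):
        return False
    parts = read.parts()
    seq = list(tnodes)
    for part in parts:
        found = any(seq[i:i + len(part)] == part
                    for i in range(len(seq) - len(part) + 1))
        if not found:
            return False
    return True


class TestCompatibility:
    def test_subset_no_skip(self):
        g = SpliceGraph([(i * 100, i * 100 + 50) for i in range(4)])
        for i in range(3):
            g.add_edge(i, i + 1, 1)
        t = transcript_path(g, [0, 1, 2, 3])
        r = BitPath(graph=g, node_bits=frozenset({1, 2}),
                    edge_bits=frozenset({(1, 2)}))
        assert path_compatible(r, t)

    def test_junction_mismatch_incompatible(self):
        g = SpliceGraph([(i * 100, i * 100 + 50) for i in range(4)])
        g.add_edge(1, 2, 1)
        g.add_edge(2, 3, 1)
        g.add_edge(1, 3, 1)
        t = transcript_path(g, [1, 2, 3])
        r = BitPath(graph=g, node_bits=frozenset({1, 3}),
                    edge_bits=frozenset({(1, 3)}))
        assert not path_compatible(r, t)

    def test_interrupted_per_part_containment(self):
        g = SpliceGraph([(i * 100, i * 100 + 50) for i in range(4)])
        for i in range(3):
            g.add_edge(i, i + 1, 1)
        g.add_edge(1, 3, 1)
        t = transcript_path(g, [0, 1, 3])
        r = BitPath(graph=g, node_bits=frozenset({0, 3}),
                    edge_bits=frozenset(), interrupted=True)
        assert path_compatible(r, t)

    def test_different_graphs_rejected(self):
        g1 = SpliceGraph([(0, 10)])
        g2 = SpliceGraph([(0, 10)])
        a = BitPath(graph=g1, node_bits=frozenset({0}), edge_bits=frozenset())
        b = BitPath(graph=g2, node_bits=frozenset({0}), edge_bits=frozenset())
        with pytest.raises(ValueError):
            path_compatible(a, b)

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(400):
            g, tnodes, tpath, read = _random_case(rng)
            got = path_compatible(read, tpath)
            want = _oracle_compatible(tnodes, read)
            assert got == want, (tnodes, sorted(read.node_bits),
                                 sorted(read.edge_bits), read.interrupted)
            checked += 1
        assert checked == 400


def test_graph_topologically_ordered(small_reads):
    cas = collapse_alignments(small_reads)
    for bundle in build_bundles(cas):
        for strand in bundle_strands(bundle):
            g = build_splice_graph(bundle, strand)
            for a, b in zip(g.nodes, g.nodes[1:]):
                assert a[0] <= b[0]
            for (i, j) in g.edges:
                assert i < j
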