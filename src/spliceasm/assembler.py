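"""Transcript extraction: iterative heaviest path with flow subtraction.

Within each splice graph, transcripts are extracted one at a time.  Each
round seeds at the node with maximal residual coverage and extends greedily
in both directions along the incident edge with maximal residual read
support (ties: larger flanking node coverage, then smaller index).  The
abundance of the extracted path is the maximum flow a source-to-sink path
can carry: the bottleneck, over the path's nodes, of the per-bp mass of
still-unassigned reads compatible with the path.  That flow is subtracted
from the contributing reads, and the process repeats until the residual
coverage drops below ``min_transcript_coverage``.

Capacities of the path-terminal nodes use an effective length
``len - mean_read_span/2`` per open end: fixed-length reads cannot overhang
a transcript end, so raw per-bp mass ramps down there and would bias the
bottleneck low.  The reported transcript coverage is assigned read bases
divided by transcript length (mean reads per bp).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment_io import (AlignedRead, CollapsedAlignment,
                           DEFAULT_MIN_JUNCTION_SUPPORT, collapse_alignments,
                           filter_reads)
from .gtfio import Transcript, write_gtf  # noqa: F401  (write_gtf re-exported)
from .longread import (DEFAULT_HIGH_ERROR_THRESHOLD, DEFAULT_CORRECTION_WINDOW,
                       DEFAULT_MAX_NODES, CorrectionEvent, PruneEvent,
                       build_site_support, correct_splice_sites, prune_graph)
from .splice_graph import (DEFAULT_MAX_GAP, BitPath, Bundle, SpliceGraph,
                           build_bundles, build_splice_graph, bundle_strands,
                           encode_path_sparse, path_compatible, transcript_path)

logger = logging.getLogger("spliceasm")

_EPS = 1e-9


@dataclass
class AssemblyParams:
    """Tunable assembly parameters and their defaults."""

    min_junction_support: float = DEFAULT_MIN_JUNCTION_SUPPORT
    max_gap: int = DEFAULT_MAX_GAP                  # -g
    trim_ends: bool = True                          # -t disables
    long_read_mode: bool = False                    # -L
    min_transcript_coverage: float = 1.0            # -c (reads per bp)
    min_isoform_fraction: float = 0.01              # -f
    anchor_default: int = 10
    anchor_long_intron: int = 25
    long_intron: int = 100_000
    max_nodes: int = DEFAULT_MAX_NODES
    correction_window: int = DEFAULT_CORRECTION_WINDOW
    high_error_threshold: float = DEFAULT_HIGH_ERROR_THRESHOLD
    trim_fraction: float = 0.1                      # terminal coverage cutoff

    def __post_init__(self):
        for name in ("min_junction_support", "max_gap", "min_transcript_coverage",
                     "min_isoform_fraction", "max_nodes", "correction_window",
                     "high_error_threshold", "trim_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class AssemblyResult:
    transcripts: list[Transcript]
    correction_log: list[CorrectionEvent] = field(default_factory=list)
    prune_events: list[PruneEvent] = field(default_factory=list)
    dropped_reads: int = 0


# ------------------------------------------------------------------
# heaviest path
# ------------------------------------------------------------------

def _edge_supports(reads: Sequence[BitPath]) -> dict[tuple[int, int], float]:
    sup: dict[tuple[int, int], float] = {}
    for r in reads:
        if r.weight <= _EPS:
            continue
        for e in r.edge_bits:
            sup[e] = sup.get(e, 0.0) + r.weight
    return sup


def _node_coverage(graph: SpliceGraph, reads: Sequence[BitPath]) -> np.ndarray:
    cov = np.zeros(graph.n)
    for r in reads:
        if r.weight <= _EPS:
            continue
        for i, ov in r.node_overlap.items():
            cov[i] += r.weight * ov
    lengths = np.array([graph.node_length(i) for i in range(graph.n)], dtype=float)
    return cov / lengths if graph.n else cov


def heaviest_path(graph: SpliceGraph,
                  node_cov: Optional[np.ndarray] = None,
                  edge_support: Optional[dict] = None) -> Optional[list[int]]:
    """Greedy heaviest path: seed at the maximal-coverage node, extend both
    ways along the incident edge with maximal support (ties: larger
    flanking node coverage, then smaller node index)."""
    if graph.n == 0:
        return None
    if node_cov is None:
        node_cov = graph.node_cov
    if edge_support is None:
        edge_support = {e: d.support for e, d in graph.edges.items()}
    if float(np.max(node_cov)) <= 0:
        return None
    seed = int(np.argmax(node_cov))
    path = [seed]
    cur = seed
    while True:
        cands = [(i, j) for (i, j) in graph.edges
                 if i == cur and edge_support.get((i, j), 0.0) > _EPS]
        if not cands:
            break
        best = max(cands, key=lambda e: (edge_support[e], node_cov[e[1]], -e[1]))
        cur = best[1]
        path.append(cur)
    cur = seed
    while True:
        cands = [(i, j) for (i, j) in graph.edges
                 if j == cur and edge_support.get((i, j), 0.0) > _EPS]
        if not cands:
            break
        best = max(cands, key=lambda e: (edge_support[e], node_cov[e[0]], -e[0]))
        cur = best[0]
        path.insert(0, cur)
    return path


# ------------------------------------------------------------------
# quantification by path-restricted flow with subtraction
# ------------------------------------------------------------------

_CAP_QUANTILE = 0.9


def _depth_profiles(graph: SpliceGraph, reads: Sequence[BitPath],
                    subset: Optional[set] = None) -> np.ndarray:
    """Weighted per-bp depth over the graph extent (difference-array)."""
    lo = graph.nodes[0][0]
    hi = graph.nodes[-1][1]
    diff = np.zeros(hi - lo + 1)
    for r in reads:
        if r.weight <= _EPS or (subset is not None and id(r) not in subset):
            continue
        for (s, e) in r.blocks:
            if e <= lo or s >= hi:
                continue
            diff[max(s, lo) - lo] += r.weight
            diff[min(e, hi) - lo] -= r.weight
    return np.cumsum(diff[:-1])


def _node_caps(graph: SpliceGraph, profile: np.ndarray,
               path_nodes: Sequence[int]) -> dict[int, float]:
    lo = graph.nodes[0][0]
    caps = {}
    for i in path_nodes:
        s, e = graph.nodes[i]
        caps[i] = float(np.quantile(profile[s - lo:e - lo], _CAP_QUANTILE))
    return caps


def quantify_and_subtract(graph: SpliceGraph, path_nodes: Sequence[int],
                          reads: list[BitPath]) -> tuple[float, float, float]:
    """Assign compatible read mass to a path and subtract it.

    The path's flow is the bottleneck over its node and edge capacities
    computed from *compatible* unassigned reads: a node's capacity is a
    high quantile of its per-bp depth profile (robust to the coverage
    ramps at transcript ends), an edge's capacity the weight of reads
    spanning it.  Each compatible read then loses the fraction
    ``flow / (its tightest capacity over all residual reads)``, so mass at
    the transcript's distinctive features is removed completely while mass
    that several isoforms could explain is shared proportionally.  Returns
    ``(coverage, flow, assigned_mass)`` with coverage = assigned bases /
    transcript length (mean reads per bp).
    """
    tpath = transcript_path(graph, path_nodes)
    live = [r for r in reads if r.weight > _EPS]
    compat = [r for r in live if path_compatible(r, tpath)]
    if not compat:
        return 0.0, 0.0, 0.0
    compat_ids = {id(r) for r in compat}
    prof_compat = _depth_profiles(graph, live, compat_ids)
    cap = _node_caps(graph, prof_compat, path_nodes)
    edge_cap = {e: sum(r.weight for r in compat if e in r.edge_bits)
                for e in tpath.edge_bits}
    flow = min(cap.values())
    if edge_cap:
        flow = min(flow, min(edge_cap.values()))
    if flow <= _EPS:
        return 0.0, 0.0, 0.0
    # subtraction denominators over *all* residual reads, so shared mass is
    # split in proportion to this transcript's share rather than consumed
    prof_all = _depth_profiles(graph, live)
    denom = _node_caps(graph, prof_all, path_nodes)
    edge_denom = {}
    for r in live:
        for e in r.edge_bits:
            if e in edge_cap:
                edge_denom[e] = edge_denom.get(e, 0.0) + r.weight
    assigned_mass = 0.0
    assigned_bases = 0.0
    for r in compat:
        tightest = min(denom[i] for i in r.node_bits)
        for e in r.edge_bits:
            tightest = min(tightest, edge_denom.get(e, edge_cap[e]))
        phi = min(1.0, flow / tightest) if tightest > 0 else 1.0
        assigned_mass += phi * r.weight
        assigned_bases += phi * r.weight * r.aligned_length
        r.weight *= (1.0 - phi)
    path_len = float(sum(graph.node_length(i) for i in path_nodes))
    coverage = assigned_bases / path_len
    return coverage, flow, assigned_mass


# ------------------------------------------------------------------
# bundle assembly
# ------------------------------------------------------------------

def _fragments(cas: Sequence[CollapsedAlignment]) -> list[tuple[list, float]]:
    """Pair collapsed alignments into fragments via their mate links;
    unpaired residual counts become single-chain entries."""
    camap = {ca.location_key: ca for ca in cas}
    consumed: dict[tuple, float] = {ca.location_key: 0.0 for ca in cas}
    frags: list[tuple[list, float]] = []
    for ca in cas:
        key = ca.location_key
        for okey in sorted(ca.mate_links):
            if okey not in camap or key > okey:
                continue
            w = ca.mate_links[okey]
            other = camap[okey]
            chains = sorted([ca.exon_blocks, other.exon_blocks],
                            key=lambda b: (b[0][0], b[-1][1]))
            frags.append((chains, w))
            if okey == key:
                consumed[key] += 2 * w
            else:
                consumed[key] += w
                consumed[okey] += w
    for ca in cas:
        residual = ca.count - consumed[ca.location_key]
        if residual > _EPS:
            frags.append(([ca.exon_blocks], residual))
    return frags


def _path_to_exons(graph: SpliceGraph, path_nodes: Sequence[int]
                   ) -> tuple[tuple[int, int], ...]:
    exons: list[list[int]] = []
    for i in path_nodes:
        s, e = graph.nodes[i]
        if exons and exons[-1][1] == s:
            exons[-1][1] = e
        else:
            exons.append([s, e])
    return tuple(tuple(x) for x in exons)


def _trim_ends(graph: SpliceGraph, exons: tuple[tuple[int, int], ...],
               coverage: float, frac: float) -> tuple[tuple[int, int], ...]:
    """Shorten terminal exons where per-bp coverage drops below
    ``frac * coverage``."""
    if graph.profile is None or coverage <= 0:
        return exons
    thresh = frac * coverage
    p0 = graph.profile_start
    prof = graph.profile
    out = [list(e) for e in exons]
    s, e = out[0]
    while s < e - 1 and 0 <= s - p0 < len(prof) and prof[s - p0] < thresh:
        s += 1
    out[0][0] = s
    s, e = out[-1]
    while e > s + 1 and 0 <= e - 1 - p0 < len(prof) and prof[e - 1 - p0] < thresh:
        e -= 1
    out[-1][1] = e
    return tuple(tuple(x) for x in out)


def _decompose_coverages(graph: SpliceGraph, candidates: list[list[int]],
                         read_paths: Sequence[BitPath],
                         assigned_mass: float) -> list[float]:
    """Per-bp coverage of each candidate transcript by linear decomposition.

    Every splice-graph node's plateau depth is the sum of the interior
    read densities of the transcripts containing it, so candidate
    densities solve a small non-negative least-squares system over the
    node depths (junction-support rows are added only when the node rows
    alone cannot distinguish the candidates).  Plateaus are measured as
    the mean per-bp depth after trimming a ramp margin — the median
    fragment cDNA extent — where a candidate starts or ends, since
    fixed-length fragments cannot overhang transcript termini.  Interior
    densities are converted to mean read-per-bp coverage by conservation
    of total assigned fragment bases.
    """
    from scipy.optimize import nnls

    live = [r for r in read_paths if r.weight > _EPS]
    if not live or not candidates:
        return [0.0] * len(candidates)
    lengths = [float(sum(graph.node_length(i) for i in c)) for c in candidates]
    prof = _depth_profiles(graph, live)
    lo = graph.nodes[0][0]
    margin = int(np.median([r.cdna_span for r in live]))
    firsts = {c[0] for c in candidates}
    lasts = {c[-1] for c in candidates}
    member = [set(c) for c in candidates]
    rows: list[list[float]] = []
    ys: list[float] = []
    used_nodes = sorted({i for c in candidates for i in c})
    for i in used_nodes:
        s, e = graph.nodes[i]
        a = s - lo + (margin if i in firsts else 0)
        b = e - lo - (margin if i in lasts else 0)
        if b > a:
            ys.append(float(np.mean(prof[a:b])))
        else:
            ys.append(float(np.quantile(prof[s - lo:e - lo], _CAP_QUANTILE)))
        rows.append([1.0 if i in m else 0.0 for m in member])
    A = np.array(rows)
    if np.linalg.matrix_rank(A) < len(candidates):
        edge_sets = [set(zip(c, c[1:])) for c in candidates]
        esup = _edge_supports(live)
        for e in sorted({e for es in edge_sets for e in es}):
            ys.append(esup.get(e, 0.0))
            rows.append([1.0 if e in es else 0.0 for es in edge_sets])
        A = np.array(rows)
    dens, _ = nnls(A, np.array(ys))
    total_d = dens.sum()
    if total_d <= _EPS:
        return [0.0] * len(candidates)
    # interior density -> mean coverage: fragments of extent S tile only
    # L - S start positions, so transcript mass is dens * (L - S)
    span = (float(np.dot(dens, lengths)) - assigned_mass) / total_d
    span = min(max(span, 0.0), 0.95 * min(lengths))
    return [float(d) * (L - span) / L for d, L in zip(dens, lengths)]


def assemble_graph(graph: SpliceGraph, read_paths: list[BitPath],
                   params: AssemblyParams, guides: Sequence[Transcript] = (),
                   ) -> list[Transcript]:
    """Extract transcripts from one graph.

    Candidate structures come from iterative heaviest-path extraction with
    flow subtraction.  Candidates that no fragment supports uniquely are
    then discarded (they are sub-paths of other candidates and carry no
    evidence of their own), and the final coverages are re-estimated by
    distributing every fragment's mass across the candidates it is
    compatible with, proportionally to the converging coverage estimates —
    the same EM used for super-read quantification.
    """
    original_weights = [r.weight for r in read_paths]
    candidates: list[list[int]] = []
    max_rounds = len(graph.edges) + 1
    for _ in range(max_rounds):
        node_cov = _node_coverage(graph, read_paths)
        if node_cov.size == 0 or float(node_cov.max()) < params.min_transcript_coverage:
            break
        edge_sup = _edge_supports(read_paths)
        path_nodes = heaviest_path(graph, node_cov, edge_sup)
        if path_nodes is None:
            break
        _, flow, _ = quantify_and_subtract(graph, path_nodes, read_paths)
        if flow < max(params.min_transcript_coverage, _EPS):
            break
        if path_nodes not in candidates:
            candidates.append(path_nodes)
    for r, w in zip(read_paths, original_weights):
        r.weight = w
    if not candidates:
        return []

    # compatibility matrix on the full fragment weights
    tpaths = [transcript_path(graph, nodes) for nodes in candidates]
    compat_of: dict[int, list[int]] = {}
    for ri, r in enumerate(read_paths):
        hits = [ci for ci, tp in enumerate(tpaths)
                if path_compatible(r, tp)]
        if hits:
            compat_of[ri] = hits

    # parsimony: drop candidates with no uniquely compatible fragment mass,
    # starting with the candidate of smallest total compatible mass so that
    # truncated sub-paths fall before the full-length paths that shadow them
    total_mass = {ci: 0.0 for ci in range(len(candidates))}
    for ri, hits in compat_of.items():
        for c in hits:
            total_mass[c] += read_paths[ri].weight
    alive = set(range(len(candidates)))
    while len(alive) > 1:
        unique_mass = {ci: 0.0 for ci in alive}
        for ri, hits in compat_of.items():
            live_hits = [c for c in hits if c in alive]
            if len(live_hits) == 1:
                unique_mass[live_hits[0]] += read_paths[ri].weight
        starved = [ci for ci in alive if unique_mass[ci] <= _EPS]
        if not starved:
            break
        alive.remove(min(starved,
                         key=lambda c: (total_mass[c], len(candidates[c]), c)))

    live_candidates = [candidates[ci] for ci in sorted(alive)]
    assigned_mass = sum(read_paths[ri].weight * read_paths[ri].aligned_length
                        for ri, hits in compat_of.items()
                        if any(c in alive for c in hits))
    coverages = _decompose_coverages(graph, live_candidates, read_paths,
                                     assigned_mass)
    raw = [{"exons": _path_to_exons(graph, nodes), "coverage": cov}
           for nodes, cov in zip(live_candidates, coverages)]

    max_cov = max(t["coverage"] for t in raw)
    guide_chains = {(g.strand, g.introns) for g in guides}
    out: list[Transcript] = []
    for t in raw:
        if t["coverage"] < max(params.min_isoform_fraction * max_cov,
                               params.min_transcript_coverage):
            continue
        exons = t["exons"]
        if params.trim_ends and not params.long_read_mode:
            exons = _trim_ends(graph, exons, t["coverage"], params.trim_fraction)
        introns = tuple((exons[i][1], exons[i + 1][0])
                        for i in range(len(exons) - 1))
        strand = graph.strand if len(exons) > 1 else (graph.strand or ".")
        source = "assembled"
        for gs, gi in guide_chains:
            if gi == introns and gi and (gs == strand or "." in (gs, strand)):
                source = "guide_matched"
                break
        out.append(Transcript(chrom=graph.reference_name, strand=strand,
                              exons=exons, coverage=t["coverage"], source=source))
    return out


def assemble_bundle(bundle: Bundle, params: AssemblyParams,
                    guides: Sequence[Transcript] = ()) -> AssemblyResult:
    """Assemble one bundle: per-strand splice graphs, optional pruning,
    fragment encoding, then iterative extraction."""
    transcripts: list[Transcript] = []
    prune_events: list[PruneEvent] = []
    overlapping_guides = [g for g in guides
                          if g.chrom == bundle.reference_name
                          and g.start < bundle.end and g.end > bundle.start]
    for strand in bundle_strands(bundle):
        strand_guides = [g for g in overlapping_guides
                         if g.strand == strand or "." in (g.strand, strand)]
        graph = build_splice_graph(bundle, strand, strand_guides)
        if graph.n == 0:
            continue
        if params.long_read_mode:
            graph, events, _ = prune_graph(graph, params.max_nodes)
            prune_events.extend(events)
            if graph.n == 0:
                continue
        cas = [ca for ca in bundle.alignments
               if ca.strand in (strand, ".") or strand == "."]
        read_paths = []
        for chains, weight in _fragments(cas):
            path = encode_path_sparse(graph, chains, weight)
            if not path.is_empty():
                read_paths.append(path)
        transcripts.extend(assemble_graph(graph, read_paths, params,
                                          strand_guides))
    return AssemblyResult(transcripts=transcripts, prune_events=prune_events)


def assemble(reads: Sequence[AlignedRead], params: Optional[AssemblyParams] = None,
             guides: Sequence[Transcript] = ()) -> AssemblyResult:
    """Full pipeline: (long-read correction) -> spurious-splice filters ->
    collapse -> bundles -> per-bundle assembly.  Transcript and gene ids are
    assigned per bundle in coordinate order."""
    params = params or AssemblyParams()
    result = AssemblyResult(transcripts=[])
    by_ref: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_ref.setdefault(r.reference_name, []).append(r)
    gene_counter = itertools.count(1)
    for ref in sorted(by_ref):
        ref_reads = by_ref[ref]
        if params.long_read_mode:
            support = build_site_support(ref_reads, params.high_error_threshold,
                                         [g for g in guides if g.chrom == ref])
            ref_reads, corr = correct_splice_sites(
                ref_reads, support, params.correction_window,
                params.high_error_threshold)
            result.correction_log.extend(corr)
        kept, dropped = filter_reads(ref_reads, params.min_junction_support)
        result.dropped_reads += len(dropped)
        cas = collapse_alignments(kept)
        for bundle in build_bundles(cas, params.max_gap):
            bres = assemble_bundle(bundle, params, guides)
            result.prune_events.extend(bres.prune_events)
            if bres.transcripts:
                gid = f"SPLG.{next(gene_counter)}"
                ordered = sorted(bres.transcripts,
                                 key=lambda t: (t.start, t.end, t.exons))
                for k, t in enumerate(ordered, 1):
                    t.gene_id = gid
                    t.id = f"{gid}.{k}"
                result.transcripts.extend(ordered)
    result.transcripts.sort(key=lambda t: (t.chrom, t.start, t.end, t.id))
    logger.info("assembled %d transcripts (%d reads dropped by filters)",
                len(result.transcripts), result.dropped_reads)
    return result
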