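"""Transcript- and intron-level accuracy metrics.

A predicted transcript is *correct* when it shares all splice-site
boundaries exactly with an annotated transcript and the terminal exons end
within 100 bp of each other; an intron is correct when both of its ends
precisely match an annotated intron.  Sensitivity is TP/(TP+FN), precision
TP/(TP+FP).  A reference transcript matched by several predictions yields
one TP; surplus matching predictions count as FP.  Relative percent change
between two methods is ``100 * (S1 - S2) / S2`` (so a rise from 20% to 30%
sensitivity is a 50% relative increase).  For real data, where truth is
unknowable, the reference can be taken as the union of the annotated
transcripts each tool predicted correctly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Union

from .gtfio import Transcript

DEFAULT_END_SLACK = 100


@dataclass
class MatchResult:
    TP: int
    FP: int
    FN: int
    undefined_precision: bool = False

    @property
    def sensitivity(self) -> float:
        denom = self.TP + self.FN
        return self.TP / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.TP + self.FP
        return self.TP / denom if denom else 0.0


@dataclass
class RelativeChange:
    S1: float
    P1: float
    S2: float
    P2: float

    @property
    def Sr(self) -> float:
        return relative_change(self.S1, self.S2)

    @property
    def Pr(self) -> float:
        return relative_change(self.P1, self.P2)


def _strands_compatible(a: str, b: str) -> bool:
    return a == b or "." in (a, b)


def _end_difference(a: Transcript, b: Transcript) -> int:
    return abs(a.start - b.start) + abs(a.end - b.end)


def match_transcript(predicted: Transcript, reference: Transcript,
                     end_slack: int = DEFAULT_END_SLACK) -> bool:
    """Exact intron-chain match with terminal ends within ``end_slack`` bp.

    Single-exon transcripts (empty chains) match when both interval ends
    are within the slack.  Strand-unknown transcripts may match either
    strand.
    """
    if predicted.chrom != reference.chrom:
        return False
    if not _strands_compatible(predicted.strand, reference.strand):
        return False
    if predicted.introns != reference.introns:
        return False
    return (abs(predicted.start - reference.start) <= end_slack
            and abs(predicted.end - reference.end) <= end_slack)


def _max_matching(pred_idx: list[int], ref_idx: list[int],
                  edges: dict[int, list[int]]) -> dict[int, int]:
    """Maximum bipartite matching (Kuhn's augmenting paths); candidate
    lists are pre-sorted by end difference so ties favour closer ends."""
    match_ref: dict[int, int] = {}

    def try_assign(p: int, banned: set[int]) -> bool:
        for r in edges.get(p, []):
            if r in banned:
                continue
            banned.add(r)
            if r not in match_ref or try_assign(match_ref[r], banned):
                match_ref[r] = p
                return True
        return False

    for p in pred_idx:
        try_assign(p, set())
    return match_ref


def score_predictions(predictions: Sequence[Transcript],
                      reference_set: Sequence[Transcript],
                      end_slack: int = DEFAULT_END_SLACK) -> MatchResult:
    """Transcript-level TP/FP/FN with one-to-one pairing.

    Each prediction matches at most one reference transcript (the pairing
    maximizes the number of matched references, preferring the smallest
    end difference); FP are predictions left unmatched, FN references left
    unmatched.
    """
    preds = list(predictions)
    refs = list(reference_set)
    edges: dict[int, list[int]] = {}
    for pi, p in enumerate(preds):
        cands = [(ri, _end_difference(p, r)) for ri, r in enumerate(refs)
                 if match_transcript(p, r, end_slack)]
        cands.sort(key=lambda t: (t[1], t[0]))
        if cands:
            edges[pi] = [ri for ri, _ in cands]
    match_ref = _max_matching(list(range(len(preds))), list(range(len(refs))),
                              edges)
    tp = len(match_ref)
    fp = len(preds) - tp
    fn = len(refs) - tp
    return MatchResult(TP=tp, FP=fp, FN=fn,
                       undefined_precision=(len(preds) == 0))


def _intron_set(transcripts: Iterable[Transcript]) -> set[tuple[str, int, int]]:
    out = set()
    for t in transcripts:
        for (d, a) in t.introns:
            out.add((t.chrom, d, a))
    return out


def score_introns(predictions: Sequence[Transcript],
                  reference_set: Sequence[Transcript]) -> MatchResult:
    """Intron-level TP/FP/FN over deduplicated intron sets; exact
    coordinate equality on both ends."""
    pred = _intron_set(predictions)
    ref = _intron_set(reference_set)
    tp = len(pred & ref)
    return MatchResult(TP=tp, FP=len(pred) - tp, FN=len(ref) - tp,
                       undefined_precision=(len(pred) == 0))


def relative_change(value1: float, value2: float) -> float:
    """Relative percent change ``100 * (v1 - v2) / v2`` of a metric versus a
    baseline; undefined (raises) for a zero baseline."""
    if value2 <= 0:
        raise ValueError("relative change is undefined for a zero baseline")
    return 100.0 * (value1 - value2) / value2


def union_reference(per_tool_correct_sets: Iterable[Iterable]) -> set:
    """Union of the annotated transcripts each tool predicted correctly,
    used as the 'true' set for real data."""
    out: set = set()
    for s in per_tool_correct_sets:
        out |= set(s)
    return out


def write_report(results: dict[str, MatchResult],
                 dest: Union[str, IO[str]],
                 baseline: Optional[dict[str, MatchResult]] = None) -> None:
    """TSV report of per-level TP/FP/FN/sensitivity/precision, plus the
    relative change against a baseline when given."""
    own = isinstance(dest, str)
    fh = open(dest, "w") if own else dest
    try:
        cols = ["level", "TP", "FP", "FN", "sensitivity", "precision"]
        if baseline:
            cols += ["Sr", "Pr"]
        fh.write("\t".join(cols) + "\n")
        for level, res in results.items():
            row = [level, str(res.TP), str(res.FP), str(res.FN),
                   f"{res.sensitivity:.4f}", f"{res.precision:.4f}"]
            if baseline and level in baseline:
                base = baseline[level]
                rc = RelativeChange(res.sensitivity, res.precision,
                                    base.sensitivity, base.precision)
                row += [f"{rc.Sr:.2f}", f"{rc.Pr:.2f}"]
            elif baseline:
                row += ["NA", "NA"]
            fh.write("\t".join(row) + "\n")
    finally:
        if own:
            fh.close()
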