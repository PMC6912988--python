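"""GTF reading (via gffutils) and writing for transcript models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence, Union

import gffutils


@dataclass
class Transcript:
    """An ordered exon chain with strand, coverage and provenance."""

    chrom: str
    strand: str                              # '+', '-' or '.'
    exons: tuple[tuple[int, int], ...]       # 0-based half-open, sorted
    id: str = ""
    gene_id: str = ""
    coverage: float = 0.0                    # mean reads per bp
    source: str = "assembled"                # "assembled" | "guide_matched"

    def __post_init__(self):
        prev = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon in transcript {self.id}")
            if prev is not None and s <= prev:
                raise ValueError(f"exons of {self.id} overlap or touch")
            prev = e
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.exons[i][1], self.exons[i + 1][0])
                     for i in range(len(self.exons) - 1))

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


def read_gtf(path: str) -> list[Transcript]:
    """Load transcripts from a GTF file (exon features grouped by
    transcript_id; gene_id kept)."""
    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    chains: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes.get("transcript_id", ["?"])[0]
        rec = chains.setdefault(tid, {
            "chrom": exon.seqid, "strand": exon.strand or ".",
            "gene_id": exon.attributes.get("gene_id", ["?"])[0],
            "exons": [],
        })
        rec["exons"].append((exon.start - 1, exon.end))  # GTF is 1-based inclusive
    out = []
    for tid, rec in chains.items():
        exons = tuple(sorted(rec["exons"]))
        out.append(Transcript(chrom=rec["chrom"], strand=rec["strand"],
                              exons=exons, id=tid, gene_id=rec["gene_id"]))
    out.sort(key=lambda t: (t.chrom, t.start, t.end, t.id))
    return out


def write_gtf(transcripts: Iterable[Transcript],
              dest: Union[str, IO[str]], source: str = "spliceasm") -> None:
    """Write transcript + exon features as GTF2.2 (1-based inclusive),
    ordered by coordinate."""
    own = isinstance(dest, str)
    fh = open(dest, "w") if own else dest
    try:
        fh.write("##gff-version 2\n")
        ordered = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.end, t.id))
        for t in ordered:
            attrs = (f'gene_id "{t.gene_id}"; transcript_id "{t.id}"; '
                     f'cov "{t.coverage:.6f}";')
            fh.write(f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}"
                     f"\t1000\t{t.strand}\t.\t{attrs}\n")
            for k, (s, e) in enumerate(t.exons, 1):
                fh.write(f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t1000"
                         f"\t{t.strand}\t.\t{attrs} exon_number \"{k}\";\n")
    finally:
        if own:
            fh.close()
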