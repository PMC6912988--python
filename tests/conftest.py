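import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from spliceasm import (AlignedRead, Dataset, FixtureSpec, generate_dataset,
                       parse_sam, simulate_short_alignments)


def make_read(blocks, qname="r", ref="chr1", strand="+", nm=0, nh=1,
              mate_start=None, first=True, weight=None):
    r = AlignedRead(query_name=qname, reference_name=ref,
                    start=blocks[0][0], exon_blocks=tuple(map(tuple, blocks)),
                    strand=strand, mismatches=nm, nh=nh,
                    weight=(1.0 / nh) if weight is None else weight,
                    is_first_mate=first, mate_start=mate_start)
    r.validate()
    return r


def write_sam_text(path, body_lines, refs=(("chr1", 1_000_000),)):
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in refs:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for line in body_lines:
            fh.write(line + "\n")
    return str(path)


@pytest.fixture(scope="session")
def small_dataset():
    """Five 3-isoform loci with perfect paired short-read alignments."""
    spec = FixtureSpec(seed=11, n_loci=5)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_sam(small_dataset, tmp_path_factory):
    path = tmp_path_factory.mktemp("sam") / "short.sam"
    manifest = simulate_short_alignments(small_dataset, str(path))
    return str(path), manifest


@pytest.fixture(scope="session")
def small_reads(small_sam):
    return parse_sam(small_sam[0])
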