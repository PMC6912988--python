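"""k-mer tables, k-unitigs, super-read extension, assignment and EM."""

import numpy as np
import pytest

from spliceasm import (Dataset, FixtureSpec, generate_dataset,
                       simulate_short_reads)
from spliceasm.fixtures import transcript_cdna, write_fastq
from spliceasm.superreads import (SuperRead, assign_reads, build_kmer_table,
                                  build_kunitigs, build_superreads, canonical,
                                  em_coverage, emit_superread_sam,
                                  extend_to_superread, kunitig_index,
                                  quantify_superreads, revcomp)


class TestKmerTable:
    def test_enumeration_with_canonical_merge(self):
        # ACGTA: ACG/CGT canonicalize together, GTA/TAC likewise
        table = build_kmer_table([("r", "ACGTA")], 3)
        assert table == {"ACG": 2, "GTA": 1}

    def test_duplicate_reads_double_counts(self):
        once = build_kmer_table([("a", "ACGTA")], 3)
        twice = build_kmer_table([("a", "ACGTA"), ("b", "ACGTA")], 3)
        assert twice == {k: 2 * v for k, v in once.items()}

    def test_kmers_containing_n_skipped(self):
        table = build_kmer_table([("r", "ACNGTA")], 3)
        assert set(table) == {"GTA"}

    def test_count_one_kmers_retained(self):
        # no minimum-count threshold: single-copy k-mers must survive
        table = build_kmer_table([("r", "AAACCC")], 5)
        assert all(v == 1 for v in table.values()) and len(table) == 2

    def test_short_reads_contribute_nothing(self):
        assert build_kmer_table([("r", "ACG")], 5) == {}

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_table([("r", "ACGT")], 1)


class TestKUnitigs:
    def test_linear_chain_single_unitig(self):
        # the k-mer set of ACGTAC is cyclic under canonical merging, so the
        # maximal chain is recovered up to rotation
        unis = build_kunitigs(build_kmer_table([("r", "ACGTAC")], 3), 3)
        assert len(unis) == 1
        seq = unis[0].sequence
        assert len(seq) == 6
        want = {canonical(x) for x in ("ACG", "CGT", "GTA", "TAC")}
        assert {canonical(k) for k in unis[0].kmers()} == want

    def test_branch_terminates_unitigs(self):
        table = build_kmer_table([("r", "ACGTAC"), ("q", "CGTT")], 3)
        unis = build_kunitigs(table, 3)
        assert len(unis) > 1
        # CGT has two successors, so no unitig may continue through it
        for u in unis:
            for km in u.kmers()[:-1]:
                assert canonical(km) != "AAC" or len(u) == 3

    def test_isolated_kmer_is_unitig_of_length_k(self):
        unis = build_kunitigs({"AAC": 1}, 3)
        assert [u.sequence for u in unis] == ["AAC"]

    def test_partition_every_kmer_in_exactly_one_unitig(self):
        """Brute-force partition check on random inputs, k <= 7."""
        rng = np.random.default_rng(12)
        for _ in range(15):
            seqs = [("s%d" % i,
                     "".join(rng.choice(list("ACGT"),
                                        size=int(rng.integers(20, 200)))))
                    for i in range(3)]
            for k in (3, 5, 7):
                table = build_kmer_table(seqs, k)
                unis = build_kunitigs(table, k)
                owner: dict[str, set] = {}
                for u in unis:
                    for km in u.kmers():
                        owner.setdefault(canonical(km), set()).add(u.id)
                assert set(owner) == set(table)
                assert all(len(v) == 1 for v in owner.values())


class TestExtension:
    def test_read_extended_to_unitig_ends(self):
        unis = build_kunitigs(build_kmer_table([("r", "ACGTAC")], 3), 3)
        idx = kunitig_index(unis)
        sr = extend_to_superread("CGTA", unis, idx, 3)
        assert sr is not None and "CGTA" in sr and len(sr) == 6

    def test_read_equal_to_unitig_is_identity(self):
        # odd k avoids canonical self-collisions of even-length k-mers
        unis = build_kunitigs(build_kmer_table([("r", "AATCGGT")], 5), 5)
        idx = kunitig_index(unis)
        sr = extend_to_superread("AATCGGT", unis, idx, 5)
        assert sr is not None
        assert sr in ("AATCGGT", revcomp("AATCGGT"))

    def test_unplaceable_terminal_kmer_gives_none(self):
        unis = build_kunitigs(build_kmer_table([("r", "AATCGGT")], 5), 5)
        idx = kunitig_index(unis)
        assert extend_to_superread("TTTTT", unis, idx, 5) is None


class TestAssignment:
    def _superreads(self):
        return [SuperRead(id="A", sequence="AACCGGTTACGT", k=4),
                SuperRead(id="B", sequence="GGGGAACCGGGG", k=4)]

    def test_exact_substring_single(self):
        asg = assign_reads(self._superreads(), [("r1", "GGTTAC")])
        assert asg == {"r1": ["A"]}

    def test_substring_of_both(self):
        asg = assign_reads(self._superreads(), [("r1", "AACCGG")])
        assert asg == {"r1": ["A", "B"]}

    def test_reverse_complement_assigned(self):
        asg = assign_reads(self._superreads(), [("r1", revcomp("GGTTAC"))])
        assert asg == {"r1": ["A"]}

    def test_assignments_pass_substring_oracle(self, small_dataset):
        reads = simulate_short_reads(small_dataset)[:300]
        k = 25
        table = build_kmer_table(reads, k)
        unis = build_kunitigs(table, k)
        srs, _ = build_superreads(reads, unis, k)
        asg = assign_reads(srs, reads)
        by_id = {sr.id: sr.sequence for sr in srs}
        readseq = dict(reads)
        for rid, hits in asg.items():
            for h in hits:
                seq = readseq[rid]
                assert seq in by_id[h] or revcomp(seq) in by_id[h]


class TestEm:
    def test_unique_read_drives_shared_read(self):
        # r1 unique to A (mass 2); r2 shared A/B follows the estimate
        cov = em_coverage({"r1": ["A"], "r2": ["A", "B"]},
                          {"r1": 2.0, "r2": 1.0})
        assert cov["A"] == pytest.approx(3.0)
        assert cov["B"] == pytest.approx(0.0)

    def test_single_target_gets_total_mass(self):
        cov = em_coverage({"r1": ["A"], "r2": ["A"]}, {"r1": 1.5, "r2": 2.5})
        assert cov["A"] == pytest.approx(4.0)

    def test_symmetric_zero_denominator_split(self):
        cov = em_coverage({"r": ["A", "B"]}, {"r": 2.0})
        assert cov["A"] == pytest.approx(1.0)
        assert cov["B"] == pytest.approx(1.0)

    def test_conservation_and_convergence_random(self):
        """Mass is conserved at every iteration and convergence arrives
        within the iteration guard on random assignment matrices."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            n_targets = int(rng.integers(1, 6))
            targets = [f"T{i}" for i in range(n_targets)]
            assignments, masses = {}, {}
            for r in range(int(rng.integers(1, 30))):
                k = int(rng.integers(1, n_targets + 1))
                hits = sorted(rng.choice(targets, size=k, replace=False))
                assignments[f"r{r}"] = list(hits)
                masses[f"r{r}"] = float(rng.uniform(0.1, 5.0))
            trace = []
            cov = em_coverage(assignments, masses, trace=trace)
            total = sum(masses.values())
            assert len(trace) < 1000
            for iter_total, _ in trace:
                assert iter_total == pytest.approx(total, rel=1e-9)
            assert sum(cov.values()) == pytest.approx(total, rel=1e-9)


class TestEndToEnd:
    def test_superreads_reproduce_transcript_sequence(self, small_dataset):
        """Noiseless super-reads are exact substrings of their transcript's
        cDNA, i.e. realignment would reproduce the junctions."""
        reads = simulate_short_reads(small_dataset)
        k = 25
        srs, produced = build_superreads(
            reads, build_kunitigs(build_kmer_table(reads, k), k), k)
        cdnas = [transcript_cdna(t, small_dataset.locus_of(t.id).genome)
                 for t in small_dataset.transcripts]
        assert srs
        for sr in srs:
            assert any(sr.sequence in c or revcomp(sr.sequence) in c
                       for c in cdnas)

    def test_fastq_roundtrip(self, small_dataset, tmp_path):
        reads = simulate_short_reads(small_dataset)[:50]
        fq = tmp_path / "reads.fastq"
        write_fastq(reads, str(fq))
        table_file = build_kmer_table(str(fq), 25)
        table_mem = build_kmer_table(reads, 25)
        assert table_file == table_mem

    def test_emit_sam_with_coverage_tag(self, tmp_path):
        import pysam
        sam_in = tmp_path / "sr.sam"
        with open(sam_in, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n")
            fh.write("SR0\t0\tchr1\t1\t60\t100M\t*\t0\t0\t*\t*\n")
            fh.write("other\t0\tchr1\t500\t60\t50M\t*\t0\t0\t*\t*\n")
        srs = [SuperRead(id="SR0", sequence="A" * 100, k=25, coverage=3.5)]
        out = tmp_path / "out.sam"
        n = emit_superread_sam(srs, str(sam_in), str(out))
        assert n == 1
        text = out.read_text()
        assert "XC:f:3.5" in text and "other" in text
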