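"""Read simulator determinism/marginals and alignment evaluation."""

import gzip

import pytest

from bsalign import (
    AccuracySummary,
    GenomeSequence,
    SimulationConfig,
    TruthRecord,
    concordance,
    evaluate,
    simulate,
)
from bsalign.seqio import read_fastq
from conftest import random_genome, sam_line, write_sam


def read_bytes(path):
    with gzip.open(path, "rb") as fh:
        return fh.read()


@pytest.fixture(scope="module")
def sim_genome():
    return random_genome(23, {"sA": 4000, "sB": 3000})


class TestTruthRecord:
    def test_encode_decode_round_trip(self):
        t = TruthRecord("chr:odd:name", 123, "-", "1010")
        assert TruthRecord.decode(t.encode(7)) == t

    def test_plain_name_rejected(self):
        with pytest.raises(ValueError, match="truth record"):
            TruthRecord.decode("read1")


class TestSimulate:
    def test_deterministic_byte_identical(self, sim_genome, tmp_path):
        cfg = SimulationConfig(n_fragments=50, seed=9)
        p1 = simulate(sim_genome, cfg, tmp_path / "a")
        p2 = simulate(sim_genome, SimulationConfig(n_fragments=50, seed=9),
                      tmp_path / "b")
        assert [read_bytes(x) for x in p1] == [read_bytes(y) for y in p2]

    def test_seed_changes_output(self, sim_genome, tmp_path):
        p1 = simulate(sim_genome, SimulationConfig(n_fragments=50, seed=9),
                      tmp_path / "a")
        p2 = simulate(sim_genome, SimulationConfig(n_fragments=50, seed=10),
                      tmp_path / "c")
        assert read_bytes(p1[0]) != read_bytes(p2[0])

    def test_full_conversion_no_methylation_removes_cs(self, sim_genome,
                                                       tmp_path):
        cfg = SimulationConfig(
            n_fragments=40, pairing="single",
            meth_prob={"CpG": 0.0, "CHG": 0.0, "CHH": 0.0},
            conversion_rate=1.0, error_rate=0.0, seed=3,
        )
        (path,) = simulate(sim_genome, cfg, tmp_path / "s")
        for read in read_fastq(path):
            truth = TruthRecord.decode(read.name)
            if truth.strand == "+":
                assert "C" not in read.seq
            else:
                # read 1 of a bottom-strand fragment is also C-depleted
                assert "C" not in read.seq
            assert set(truth.mask) <= {"0"}

    def test_full_methylation_preserves_fragment(self, sim_genome, tmp_path):
        cfg = SimulationConfig(
            n_fragments=40, pairing="single",
            meth_prob={"CpG": 1.0, "CHG": 1.0, "CHH": 1.0},
            error_rate=0.0, seed=3,
        )
        (path,) = simulate(sim_genome, cfg, tmp_path / "m")
        from bsalign.genome import revcomp

        for read in read_fastq(path):
            t = TruthRecord.decode(read.name)
            src = sim_genome[t.chrom]
            if t.strand == "+":
                frag = src[t.start - 1 : t.start - 1 + cfg.read_len]
                assert read.seq == frag
            else:
                frag = revcomp(src)[
                    len(src) - (t.start - 1 + cfg.read_len) :
                ][: cfg.read_len]
                assert read.seq == frag
            assert set(t.mask) <= {"1"}

    def test_truth_start_within_contig(self, sim_genome, tmp_path):
        cfg = SimulationConfig(n_fragments=200, seed=5)
        paths = simulate(sim_genome, cfg, tmp_path / "t")
        for read in read_fastq(paths[0]):
            t = TruthRecord.decode(read.name)
            assert t.chrom in sim_genome
            assert 1 <= t.start <= len(sim_genome[t.chrom])

    def test_paired_files_name_matched(self, sim_genome, tmp_path):
        cfg = SimulationConfig(n_fragments=30, seed=5)
        p1, p2 = simulate(sim_genome, cfg, tmp_path / "p")
        names1 = [r.name for r in read_fastq(p1)]
        names2 = [r.name for r in read_fastq(p2)]
        assert names1 == names2 and len(names1) == 30

    def test_five_prime_unmeth_forces_ts(self, sim_genome, tmp_path):
        cfg = SimulationConfig(
            n_fragments=40, pairing="single",
            meth_prob={"CpG": 1.0, "CHG": 1.0, "CHH": 1.0},
            error_rate=0.0, five_prime_unmeth=5, seed=3,
        )
        (path,) = simulate(sim_genome, cfg, tmp_path / "f")
        from bsalign.genome import revcomp

        for read in read_fastq(path):
            t = TruthRecord.decode(read.name)
            src = sim_genome[t.chrom]
            if t.strand == "+":
                frag = src[t.start - 1 :][: cfg.read_len]
            else:
                frag = revcomp(src)[
                    len(src) - (t.start - 1 + cfg.read_len) :
                ][: cfg.read_len]
            for i in range(5):
                if frag[i] == "C":
                    assert read.seq[i] == "T"

    def test_short_contigs_rejected(self, tmp_path):
        g = GenomeSequence({"tiny": "ACGT" * 10})
        with pytest.raises(ValueError, match="long enough"):
            simulate(g, SimulationConfig(n_fragments=5), tmp_path / "x")

    def test_invalid_probability_rejected(self, sim_genome, tmp_path):
        cfg = SimulationConfig(meth_prob={"CpG": 1.5, "CHG": 0, "CHH": 0})
        with pytest.raises(ValueError, match="outside"):
            simulate(sim_genome, cfg, tmp_path / "x")


GENOME = GenomeSequence({"g": "A" * 500})
Q = "I" * 10


def truth_line(idx, start1, flag=0, pos1=None, mapq=42, chrom="g"):
    name = TruthRecord("g", start1, "+", "").encode(idx)
    return sam_line(name, flag, chrom, pos1 if pos1 else start1, mapq, "10M",
                    "A" * 10, Q, "." * 10)


class TestEvaluate:
    def test_classification(self, tmp_path):
        unmapped = (TruthRecord("g", 7, "+", "").encode(3)
                    + "\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 10 + "\t" + Q)
        lines = [
            truth_line(0, 100),                    # correct, confident
            truth_line(1, 100, pos1=150),          # incorrect, confident
            truth_line(2, 100, mapq=2),            # correct but sub-threshold
            unmapped,                              # discarded
            "plainname\t0\tg\t5\t42\t10M\t*\t0\t0\t" + "A" * 10 + "\t" + Q,
        ]
        path = write_sam(tmp_path, GENOME, lines)
        s = evaluate(path, mapq_threshold=10)
        assert (s.n_total, s.n_correct, s.n_incorrect, s.n_discarded) == (4, 2, 1, 1)
        assert (s.n_correct_thr, s.n_incorrect_thr, s.n_discarded_thr) == (1, 1, 2)
        assert s.n_unparseable == 1
        d = s.as_dict()
        assert d["pct_correct"] == pytest.approx(50.0)
        assert d["pct_discarded_mapq"] == pytest.approx(50.0)

    def test_counts_sum_invariant(self, tmp_path):
        path = write_sam(tmp_path, GENOME,
                         [truth_line(i, 10 * (i + 1)) for i in range(7)])
        s = evaluate(path)
        s.check()
        assert s.n_total == 7 and s.n_correct == 7

    def test_pair_unit_uses_leftmost_and_min_mapq(self, tmp_path):
        name = TruthRecord("g", 100, "+", "").encode(0)
        lines = [
            sam_line(name, 99, "g", 100, 42, "10M", "A" * 10, Q, "." * 10,
                     rnext="=", pnext=160, tlen=70),
            sam_line(name, 147, "g", 160, 4, "10M", "A" * 10, Q, "." * 10,
                     xr="GA", rnext="=", pnext=100, tlen=-70),
        ]
        path = write_sam(tmp_path, GENOME, lines)
        s = evaluate(path, mapq_threshold=10)
        # correct overall, but the weaker mate's MAPQ discards it at threshold
        assert (s.n_correct, s.n_discarded_thr) == (1, 1)


class TestConcordance:
    def line(self, name, pos1, mapq=42):
        return sam_line(name, 0, "g", pos1, mapq, "10M", "A" * 10, Q, "." * 10)

    def test_identical_files_fully_concordant(self, tmp_path):
        lines = [self.line(f"r{i}", 10 + i) for i in range(5)]
        a = write_sam(tmp_path, GENOME, lines, "a.sam")
        b = write_sam(tmp_path, GENOME, lines, "b.sam")
        s = concordance(a, b)
        assert s.as_dict() == {
            "concordant": 5, "discordant": 0, "only_a": 0, "only_b": 0,
        }

    def test_shifted_and_private_units(self, tmp_path):
        a = write_sam(tmp_path, GENOME,
                      [self.line("r1", 10), self.line("r2", 20),
                       self.line("onlyA", 30)], "a.sam")
        b = write_sam(tmp_path, GENOME,
                      [self.line("r1", 10), self.line("r2", 25, mapq=7),
                       self.line("onlyB", 40)], "b.sam")
        s = concordance(a, b)
        assert s.as_dict() == {
            "concordant": 1, "discordant": 1, "only_a": 1, "only_b": 1,
        }
        assert s.mapq_discordant == [42]  # MAPQ taken from file A's unit

    def test_duplicate_primary_rejected(self, tmp_path):
        a = write_sam(tmp_path, GENOME,
                      [self.line("r1", 10), self.line("r1", 20)], "a.sam")
        b = write_sam(tmp_path, GENOME, [self.line("r1", 10)], "b.sam")
        with pytest.raises(ValueError, match="duplicate primary"):
            concordance(a, b)
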