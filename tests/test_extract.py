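"""Methylation extraction, overlap rules, bedGraph/export round-trips."""

import pytest

from bsalign import (
    FilterConfig,
    GenomeSequence,
    MethylationCounts,
    TrimBounds,
    coverage_metrics,
    export_format,
    extract_methylation,
    merge_cpg,
    merge_replicates,
    parse_bedgraph,
    write_bedgraph,
)
from conftest import sam_line, write_sam

#            0123456789AB
GENOME_SEQ = "TTACGATTCGAA"  # CpGs: C3/G4 and C8/G9
GENOME = GenomeSequence({"g": GENOME_SEQ})

Q = "I" * 12  # Phred 40 throughout


def extract(tmp_path, lines, **filt):
    path = write_sam(tmp_path, GENOME, lines)
    return extract_methylation(path, GENOME, FilterConfig(**filt))


class TestSingleEnd:
    def test_counts_and_conservation(self, tmp_path):
        xm = "...Z....z..."
        counts = extract(
            tmp_path,
            [sam_line("r1", 0, "g", 1, 42, "12M", "TTACGATTTGAA", Q, xm)],
        )
        assert counts.counts == {
            ("g", 3, "+", "CpG"): [1, 0],
            ("g", 8, "+", "CpG"): [0, 1],
        }
        # every non-'.' symbol becomes exactly one tallied call
        assert counts.total_calls() == sum(1 for c in xm if c != ".")

    def test_bottom_strand_keyed_at_guanine(self, tmp_path):
        counts = extract(
            tmp_path,
            [sam_line("r1", 16, "g", 1, 42, "12M", "TTACGATTCGAA", Q,
                      "....Z....z..", xg="GA")],
        )
        assert counts.counts == {
            ("g", 4, "-", "CpG"): [1, 0],
            ("g", 9, "-", "CpG"): [0, 1],
        }

    def test_low_mapq_record_skipped(self, tmp_path):
        counts = extract(
            tmp_path,
            [sam_line("r1", 0, "g", 1, 5, "12M", "TTACGATTTGAA", Q,
                      "...Z....z...")],
        )
        assert len(counts) == 0

    def test_duplicate_flag_skipped(self, tmp_path):
        counts = extract(
            tmp_path,
            [sam_line("r1", 0x400, "g", 1, 42, "12M", "TTACGATTTGAA", Q,
                      "...Z....z...")],
        )
        assert len(counts) == 0

    def test_low_phred_call_dropped(self, tmp_path):
        quals = list(Q)
        quals[3] = "$"  # Phred 3 < 5 at the methylated C
        counts = extract(
            tmp_path,
            [sam_line("r1", 0, "g", 1, 42, "12M", "TTACGATTTGAA",
                      "".join(quals), "...Z....z...")],
        )
        assert counts.counts == {("g", 8, "+", "CpG"): [0, 1]}

    def test_trim_bounds_restrict_read_positions(self, tmp_path):
        trims = TrimBounds()
        trims.set("OT", 1, 5, 12)  # drop calls at read positions 1-4
        counts = extract(
            tmp_path,
            [sam_line("r1", 0, "g", 1, 42, "12M", "TTACGATTTGAA", Q,
                      "...Z....z...")],
            trims=trims,
        )
        # the Z at read position 4 is trimmed; the z at position 9 survives
        assert counts.counts == {("g", 8, "+", "CpG"): [0, 1]}

    def test_missing_xm_counted_rejected(self, tmp_path):
        path = write_sam(
            tmp_path, GENOME,
            ["r1\t0\tg\t1\t42\t12M\t*\t0\t0\tTTACGATTTGAA\t" + Q],
        )
        counts = extract_methylation(path, GENOME)
        assert counts.n_rejected == 1 and len(counts) == 0

    def test_soft_clip_shifts_nothing_extra(self, tmp_path):
        # 2 clipped bases, then the genome from position 2 (0-based)
        counts = extract(
            tmp_path,
            [sam_line("r1", 0, "g", 3, 42, "2S10M", "TTACGATTTGAA", Q,
                      "...Z....z...")],
        )
        assert counts.counts == {
            ("g", 3, "+", "CpG"): [1, 0],
            ("g", 8, "+", "CpG"): [0, 1],
        }


def pair_lines(xm1, xm2, quals1=Q, quals2=Q, seq1="TTACGATTTGAA",
               seq2="TTACGATTTGAA"):
    """A fully overlapping proper pair covering the whole toy genome."""
    return [
        sam_line("p", 99, "g", 1, 42, "12M", seq1, quals1, xm1,
                 rnext="=", pnext=1, tlen=12),
        sam_line("p", 147, "g", 1, 42, "12M", seq2, quals2, xm2, xr="GA",
                 rnext="=", pnext=1, tlen=-12),
    ]


class TestPairedOverlap:
    def test_agreeing_calls_counted_once(self, tmp_path):
        counts = extract(tmp_path, pair_lines("...Z....z...", "...Z....z..."))
        assert counts.counts == {
            ("g", 3, "+", "CpG"): [1, 0],
            ("g", 8, "+", "CpG"): [0, 1],
        }

    def test_one_usable_call_is_used(self, tmp_path):
        counts = extract(tmp_path, pair_lines("...Z........", "........z..."))
        assert counts.counts == {
            ("g", 3, "+", "CpG"): [1, 0],
            ("g", 8, "+", "CpG"): [0, 1],
        }

    def test_disagreeing_calls_dropped(self, tmp_path):
        counts = extract(tmp_path, pair_lines("...Z....z...", "...z....z..."))
        # position 3 disagrees (Z vs z) and is dropped entirely
        assert counts.counts == {("g", 8, "+", "CpG"): [0, 1]}

    def test_low_quality_mate_defers_to_other(self, tmp_path):
        quals1 = list(Q)
        quals1[3] = "$"  # mate-1 call unusable at position 3
        counts = extract(
            tmp_path, pair_lines("...z....z...", "...Z....z...",
                                 quals1="".join(quals1))
        )
        # without the Phred floor this would be a disagreement; instead the
        # usable mate-2 Z stands
        assert counts.counts == {
            ("g", 3, "+", "CpG"): [1, 0],
            ("g", 8, "+", "CpG"): [0, 1],
        }

    def test_orphan_mate_counted_alone(self, tmp_path):
        lines = pair_lines("...Z....z...", "...Z....z...")
        lines[1] = sam_line("p", 147, "g", 1, 5, "12M", "TTACGATTTGAA", Q,
                            "...Z....z...", xr="GA", rnext="=", pnext=1,
                            tlen=-12)  # mate 2 fails MAPQ
        counts = extract(tmp_path, lines)
        assert counts.counts == {
            ("g", 3, "+", "CpG"): [1, 0],
            ("g", 8, "+", "CpG"): [0, 1],
        }


def toy_counts():
    c = MethylationCounts(chrom_order=["g"])
    c.add_counts(("g", 3, "+", "CpG"), 3, 1)
    c.add_counts(("g", 4, "-", "CpG"), 1, 1)
    c.add_counts(("g", 8, "+", "CpG"), 0, 5)
    return c


class TestBedgraph:
    def test_round_trip_preserves_counts(self, tmp_path):
        c = toy_counts()
        path = write_bedgraph(c, "CpG", tmp_path / "cpg.bedGraph")
        back = parse_bedgraph(path, "CpG", GENOME)
        assert back == c

    def test_columns_and_rounding(self, tmp_path):
        path = write_bedgraph(toy_counts(), "CpG", tmp_path / "c.bedGraph")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("track type=bedGraph")
        assert lines[1] == "g\t3\t4\t75\t3\t1"
        assert lines[2] == "g\t4\t5\t50\t1\t1"
        assert lines[3] == "g\t8\t9\t0\t0\t5"

    def test_other_context_excluded(self, tmp_path):
        c = toy_counts()
        c.add_counts(("g", 6, "+", "CHH"), 2, 2)
        path = write_bedgraph(c, "CpG", tmp_path / "c.bedGraph")
        assert len(path.read_text().splitlines()) == 4  # track + 3 CpG rows


class TestMergeCpg:
    def test_bottom_strand_folded_onto_top(self):
        merged = merge_cpg(toy_counts(), GENOME)
        assert merged.counts == {
            ("g", 3, "+", "CpG"): [4, 2],
            ("g", 8, "+", "CpG"): [0, 5],
        }

    def test_total_calls_conserved(self):
        c = toy_counts()
        assert merge_cpg(c, GENOME).total_calls() == c.total_calls()

    def test_non_cpg_context_rejected(self):
        c = MethylationCounts()
        c.add_counts(("g", 6, "+", "CHH"), 1, 0)
        with pytest.raises(ValueError, match="non-CpG"):
            merge_cpg(c, GENOME)

    def test_non_cpg_position_rejected(self):
        c = MethylationCounts()
        c.add_counts(("g", 0, "+", "CpG"), 1, 0)  # genome has T at 0
        with pytest.raises(ValueError, match="not a CpG"):
            merge_cpg(c, GENOME)


class TestMergeReplicatesAndCoverage:
    def test_replicates_added_per_key(self):
        a, b = toy_counts(), toy_counts()
        merged = merge_replicates(a, b)
        assert merged.counts[("g", 3, "+", "CpG")] == [6, 2]
        assert merged.total_calls() == a.total_calls() + b.total_calls()

    def test_coverage_thresholds(self):
        c = MethylationCounts()
        c.add_counts(("g", 3, "+", "CpG"), 1, 0)  # coverage 1
        c.add_counts(("g", 8, "+", "CpG"), 2, 3)  # coverage 5
        c.add_counts(("g", 9, "-", "CpG"), 6, 6)  # coverage 12
        assert coverage_metrics(c, thresholds=(1, 3, 5, 10)) == {
            1: 3, 3: 2, 5: 2, 10: 1,
        }

    def test_non_cpg_ignored_by_coverage(self):
        c = MethylationCounts()
        c.add_counts(("g", 6, "+", "CHH"), 50, 50)
        assert coverage_metrics(c, thresholds=(1,)) == {1: 0}


class TestExports:
    def test_methylkit_rows(self, tmp_path):
        path = export_format(toy_counts(), "methylKit", tmp_path / "mk.txt")
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == [
            "chrBase", "chr", "base", "strand", "coverage", "freqC", "freqT",
        ]
        assert lines[1] == "g.4\tg\t4\tF\t4\t75.00\t25.00"
        assert lines[2] == "g.5\tg\t5\tR\t2\t50.00\t50.00"

    def test_bsseq_rows(self, tmp_path):
        path = export_format(toy_counts(), "BSseq", tmp_path / "bs.txt")
        lines = path.read_text().splitlines()
        assert lines[0] == "chrom\tpos\tcoverage\tmethylated"
        assert lines[1] == "g\t4\t4\t3"
        assert lines[3] == "g\t9\t5\t0"

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            export_format(toy_counts(), "bedops", tmp_path / "x.txt")
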