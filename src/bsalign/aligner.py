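"""End-to-end alignment stage: convert reads, map per strand, arbitrate, emit BAM.

Output records carry the recalculated MAPQ in the standard column plus the
XM (methylation string), XG (genome conversion) and XR (read conversion)
auxiliary tags; unmapped reads can optionally be diverted to FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Tuple

import pysam

from .arbitrate import STRAND_TAGS, assign_methylation, recalc_mapq, select_best
from .backend import (
    BuiltinBackend,
    CandidateAlignment,
    PairCandidate,
    ScoringScheme,
)
from .convert import BsRead, Protocol, convert_genome, convert_reads
from .genome import GenomeSequence, revcomp


@dataclass
class AlignStats:
    n_total: int = 0
    n_aligned: int = 0
    n_unmapped: int = 0

    @property
    def pct_aligned(self) -> float:
        return 100.0 * self.n_aligned / self.n_total if self.n_total else 0.0


def make_header(genome: GenomeSequence, extra_pg: Optional[str] = None) -> pysam.AlignmentHeader:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in genome.items()],
        "PG": [{"ID": "bsalign", "PN": "bsalign", "CL": extra_pg or "bsalign align"}],
    }
    return pysam.AlignmentHeader.from_dict(header)


def _flip_xr(xr: str) -> str:
    return "GA" if xr == "CT" else "CT"


def _build_record(
    header: pysam.AlignmentHeader,
    name: str,
    cand: CandidateAlignment,
    original: BsRead,
    mapq: int,
    xm: str,
    xg: str,
    xr: str,
    xs: Optional[int],
    mate: Optional[CandidateAlignment] = None,
    is_read1: bool = True,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    seq = revcomp(original.seq) if cand.is_reverse else original.seq
    quals = original.quals[::-1] if cand.is_reverse else original.quals
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array(quals)
    rec.reference_id = header.get_tid(cand.chrom)
    rec.reference_start = cand.pos
    rec.mapping_quality = mapq
    rec.cigarstring = cand.cigar
    flag = 0
    if cand.is_reverse:
        flag |= 0x10
    if mate is not None:
        flag |= 0x1 | 0x2 | (0x40 if is_read1 else 0x80)
        if mate.is_reverse:
            flag |= 0x20
        rec.next_reference_id = header.get_tid(mate.chrom)
        rec.next_reference_start = mate.pos
        left = min(cand.pos, mate.pos)
        right = max(cand.pos + cand.read_len, mate.pos + mate.read_len)
        tlen = right - left
        rec.template_length = tlen if cand.pos <= mate.pos else -tlen
    rec.flag = flag
    tags = [("AS", cand.AS), ("XM", xm), ("XG", xg), ("XR", xr)]
    if xs is not None:
        tags.insert(1, ("XS", xs))
    rec.set_tags(tags)
    return rec


class Aligner:
    """Convert-map-arbitrate pipeline over an in-memory genome."""

    def __init__(
        self,
        genome: GenomeSequence,
        protocol: Protocol = Protocol(),
        scheme: ScoringScheme = ScoringScheme(),
        max_genome_size: int = 10_000_000,
    ) -> None:
        self.genome = genome
        self.protocol = protocol
        self.scheme = scheme
        self.pair = convert_genome(genome)
        self.backend = BuiltinBackend(self.pair, scheme, max_genome_size)
        self.header = make_header(genome)
        self.stats = AlignStats()

    # ------------------------------------------------------------------ core
    def arbitrate_single(self, read: BsRead):
        entries = convert_reads(read, None, self.protocol)
        cands = [self.backend.align_single(e) for e in entries]
        return select_best(cands)

    def arbitrate_pair(self, read1: BsRead, read2: BsRead):
        entries = convert_reads(read1, read2, self.protocol)
        cands = [self.backend.align_pair(e) for e in entries]
        return select_best(cands)

    def records_single(self, read: BsRead) -> Iterator[pysam.AlignedSegment]:
        self.stats.n_total += 1
        chosen = self.arbitrate_single(read)
        if chosen is None:
            self.stats.n_unmapped += 1
            return
        assert isinstance(chosen, CandidateAlignment)
        self.stats.n_aligned += 1
        mapq = recalc_mapq(chosen.AS, chosen.XS, chosen.read_len, self.scheme)
        xg, xr = STRAND_TAGS[chosen.strand]
        xm = assign_methylation(chosen, read.seq, self.genome)
        yield _build_record(
            self.header, read.name, chosen, read, mapq, xm, xg, xr, chosen.XS
        )

    def records_pair(
        self, read1: BsRead, read2: BsRead
    ) -> Iterator[pysam.AlignedSegment]:
        self.stats.n_total += 1
        chosen = self.arbitrate_pair(read1, read2)
        if chosen is None:
            self.stats.n_unmapped += 1
            return
        assert isinstance(chosen, PairCandidate)
        self.stats.n_aligned += 1
        total_len = chosen.a1.read_len + chosen.a2.read_len
        mapq = recalc_mapq(chosen.score, chosen.XS, total_len, self.scheme, n_mates=2)
        xg, xr = STRAND_TAGS[chosen.strand]
        xm1 = assign_methylation(chosen.a1, read1.seq, self.genome)
        xm2 = assign_methylation(chosen.a2, read2.seq, self.genome)
        yield _build_record(
            self.header, read1.name, chosen.a1, read1, mapq, xm1, xg, xr,
            chosen.XS, mate=chosen.a2, is_read1=True,
        )
        yield _build_record(
            self.header, read2.name, chosen.a2, read2, mapq, xm2, xg,
            _flip_xr(xr), chosen.XS, mate=chosen.a1, is_read1=False,
        )


def align_to_bam(
    genome: GenomeSequence,
    reads: Iterable[BsRead] | Iterable[Tuple[BsRead, BsRead]],
    out_bam: str | Path,
    protocol: Protocol = Protocol(),
    scheme: ScoringScheme = ScoringScheme(),
    paired: bool = False,
    unmapped_fastq: Optional[str] = None,
    sort: bool = True,
) -> AlignStats:
    """Align a read stream and write a (coordinate-sorted) BAM.

    Returns alignment statistics.  ``unmapped_fastq`` diverts unmapped reads
    (prefix; mate files get _1/_2 suffixes when paired).
    """
    out_bam = Path(out_bam)
    aligner = Aligner(genome, protocol, scheme)
    tmp = out_bam.with_suffix(".unsorted.bam")

    unm1 = unm2 = None
    if unmapped_fastq:
        from .seqio import FastqWriter

        if paired:
            unm1 = FastqWriter(f"{unmapped_fastq}_1.fastq.gz")
            unm2 = FastqWriter(f"{unmapped_fastq}_2.fastq.gz")
        else:
            unm1 = FastqWriter(f"{unmapped_fastq}.fastq.gz")

    with pysam.AlignmentFile(str(tmp), "wb", header=aligner.header) as bam:
        if paired:
            for r1, r2 in reads:  # type: ignore[misc]
                n_before = aligner.stats.n_aligned
                for rec in aligner.records_pair(r1, r2):
                    bam.write(rec)
                if unm1 and aligner.stats.n_aligned == n_before:
                    unm1.write(r1)
                    unm2.write(r2)  # type: ignore[union-attr]
        else:
            for read in reads:  # type: ignore[assignment]
                n_before = aligner.stats.n_aligned
                for rec in aligner.records_single(read):  # type: ignore[arg-type]
                    bam.write(rec)
                if unm1 and aligner.stats.n_aligned == n_before:
                    unm1.write(read)  # type: ignore[arg-type]
    for w in (unm1, unm2):
        if w:
            w.close()

    if sort:
        pysam.sort("-o", str(out_bam), str(tmp))
        tmp.unlink()
        pysam.index(str(out_bam))
    else:
        tmp.rename(out_bam)
    return aligner.stats
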