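"""Candidate alignment generation, one strand at a time.

Two backends produce strand-constrained candidates carrying AS (best score)
and XS (second-best score) tags:

* a built-in deterministic aligner that scores a read ungapped at every
  permissible offset with quality-scaled mismatch penalties (exact, suitable
  for genomes up to a configurable cap), and
* an external bowtie2-compatible subprocess driven in end-to-end mode.

Scores follow the end-to-end convention: a perfect alignment scores 0 and
every mismatch subtracts a penalty interpolated between ``mismatch_penalty_min``
and ``mismatch_penalty_max`` by base quality; alignments scoring below
``min_score(L)`` are invalid.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from functools import lru_cache
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from ._kernels import encode, scan_offsets, score_at_offsets
from .convert import ConvertedGenomePair, DispatchEntry, Strand
from .genome import GenomeSequence, revcomp


@dataclass(frozen=True)
class ScoringScheme:
    """End-to-end alignment scoring parameters.

    ``min_score(L)`` is the affine floor below which an alignment is invalid;
    the defaults follow the common end-to-end convention (-0.6 - 0.6*L).
    """

    mismatch_penalty_max: int = 6
    mismatch_penalty_min: int = 2
    n_penalty: int = 1
    gap_open: int = 5
    gap_extend: int = 3
    min_score_const: float = -0.6
    min_score_coeff: float = -0.6
    perfect_score: int = 0

    def min_score(self, read_len: int) -> float:
        return self.min_score_const + self.min_score_coeff * read_len

    def max_penalty(self, read_len: int) -> int:
        """Largest integer total penalty still meeting min_score."""
        return math.floor(-self.min_score(read_len))

    def mismatch_penalty(self, qual: int) -> int:
        """Quality-scaled mismatch penalty: min..max, linear in min(q, 40)/40."""
        mn, mx = self.mismatch_penalty_min, self.mismatch_penalty_max
        return int(mn + (mx - mn) * (min(qual, 40) / 40.0) + 0.5)

    def penalty_vector(self, quals: str) -> np.ndarray:
        return _penalty_vector(self, quals)


@lru_cache(maxsize=4096)
def _penalty_vector(scheme: "ScoringScheme", quals: str) -> np.ndarray:
    return np.array(
        [scheme.mismatch_penalty(ord(c) - 33) for c in quals], dtype=np.int32
    )


@dataclass
class CandidateAlignment:
    """One strand-constrained alignment of a single read."""

    strand: Strand
    chrom: str
    pos: int  # 0-based leftmost
    cigar: str
    AS: int
    XS: Optional[int] = None
    mapped: bool = True
    is_reverse: bool = False
    read_len: int = 0

    @property
    def score(self) -> int:
        return self.AS


@dataclass
class PairCandidate:
    """A properly oriented mate pair on one strand; score is the AS sum."""

    strand: Strand
    a1: CandidateAlignment
    a2: CandidateAlignment
    XS: Optional[int] = None  # second-best summed score on this strand

    @property
    def score(self) -> int:
        return self.a1.AS + self.a2.AS

    @property
    def AS(self) -> int:
        return self.score


def pair_score(a1: CandidateAlignment, a2: CandidateAlignment) -> int:
    """Summed alignment score of a mate pair (both mates must be mapped)."""
    if not (a1.mapped and a2.mapped):
        raise ValueError("pair_score requires both mates mapped")
    return a1.AS + a2.AS


class GenomeTooLargeError(ValueError):
    """Built-in aligner refused a genome over its size cap."""


class BuiltinBackend:
    """Deterministic exhaustive aligner over an in-memory converted genome.

    Ungapped (all-M CIGARs); exact top-2 scoring at every permissible offset.
    Ties between equal-scoring positions are broken by smallest coordinate,
    then lexicographically smallest contig name.
    """

    def __init__(
        self,
        genomes: ConvertedGenomePair,
        scheme: ScoringScheme = ScoringScheme(),
        max_genome_size: int = 10_000_000,
        max_insert: int = 1000,
    ) -> None:
        total = genomes.source.total_length
        if total > max_genome_size:
            raise GenomeTooLargeError(
                f"genome is {total} bp, over the built-in aligner's "
                f"{max_genome_size} bp cap; use the external backend"
            )
        self.genomes = genomes
        self.scheme = scheme
        self.max_insert = max_insert
        self._codes: Dict[Tuple[str, str], np.ndarray] = {}
        self._kmer_index: Dict[Tuple[str, str, int], Optional[tuple]] = {}
        for key, g in (("ct", genomes.ct_genome), ("ga", genomes.ga_genome)):
            for name, seq in g.items():
                self._codes[(key, name)] = encode(seq)

    # ------------------------------------------------------------------ scanning
    _MIN_SEED = 6  # below this seed length indexing loses to the linear scan

    def _index(self, genome_key: str, chrom: str, k: int):
        """Sorted k-mer hash index of a contig (k-mers containing N excluded)."""
        key = (genome_key, chrom, k)
        cached = self._kmer_index.get(key)
        if cached is not None:
            return cached
        codes = self._codes[(genome_key, chrom)]
        n = codes.shape[0] - k + 1
        if n <= 0:
            self._kmer_index[key] = None
            return None
        h = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        for j in range(k):
            c = codes[j : j + n]
            h = h * 4 + np.where(c == 4, 0, c).astype(np.int64)
            bad |= c == 4
        h[bad] = -1
        order = np.argsort(h, kind="stable")
        self._kmer_index[key] = (h[order], order.astype(np.int64))
        return self._kmer_index[key]

    def _scan_contig(
        self, genome_key: str, chrom: str, seq: str, quals: str
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Exact top-scoring placements of an oriented read on one contig.

        Uses pigeonhole seeding when the mismatch budget allows seeds of at
        least _MIN_SEED bases: the read is split into (max_mismatches + 1)
        disjoint chunks, so every placement within the penalty budget matches
        at least one chunk exactly and is found by index lookup.  Otherwise
        falls back to the full linear scan.  Both paths return identical
        results.
        """
        codes = self._codes[(genome_key, chrom)]
        read = encode(seq)
        pen = self.scheme.penalty_vector(quals)
        npen = self.scheme.n_penalty
        maxpen = self.scheme.max_penalty(len(seq))
        L = len(seq)

        eff = np.where(read == 4, npen, pen)
        max_mm = int(maxpen // max(1, int(eff.min())))
        n_chunks = max_mm + 1
        k = L // n_chunks if n_chunks else 0
        if k < self._MIN_SEED or codes.shape[0] < L:
            return scan_offsets(codes, read, pen, npen, maxpen)

        idx = self._index(genome_key, chrom, k)
        if idx is None:
            return scan_offsets(codes, read, pen, npen, maxpen)
        sorted_h, order = idx
        cap = codes.shape[0] - L
        cands: List[np.ndarray] = []
        for j in range(n_chunks):
            off = j * k
            chunk = read[off : off + k]
            if (chunk == 4).any():
                continue  # an N chunk always carries penalty; never seed-exact
            t = 0
            for b in chunk:
                t = t * 4 + int(b)
            lo = np.searchsorted(sorted_h, t, side="left")
            hi = np.searchsorted(sorted_h, t, side="right")
            if hi > lo:
                p = order[lo:hi] - off
                cands.append(p[(p >= 0) & (p <= cap)])
        if not cands:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        offsets = np.unique(np.concatenate(cands))
        scores = score_at_offsets(codes, read, pen, npen, maxpen, offsets)
        keep = scores <= 0
        return offsets[keep], scores[keep]

    def _scan_all(
        self, genome_key: str, seq: str, quals: str
    ) -> List[Tuple[str, int, int]]:
        """All valid placements of an oriented read: (chrom, pos, score)."""
        hits: List[Tuple[str, int, int]] = []
        genome = self.genomes.ct_genome if genome_key == "ct" else self.genomes.ga_genome
        for chrom in genome.names:
            pos, sc = self._scan_contig(genome_key, chrom, seq, quals)
            hits.extend((chrom, int(p), int(s)) for p, s in zip(pos, sc))
        return hits

    @staticmethod
    def _oriented(seq: str, quals: str, orientation: str) -> Tuple[str, str]:
        if orientation == "revcomp":
            return revcomp(seq), quals[::-1]
        return seq, quals

    @staticmethod
    def _top2(
        hits: Sequence[Tuple[str, int, int]]
    ) -> Tuple[Optional[Tuple[str, int, int]], Optional[int]]:
        """Best placement (by score desc, then pos asc, then chrom asc) and
        the second-best score over the remaining placements."""
        if not hits:
            return None, None
        best = min(hits, key=lambda h: (-h[2], h[1], h[0]))
        others = [h[2] for h in hits if h is not best]
        return best, (max(others) if others else None)

    # ------------------------------------------------------------- single-end
    def align_single(self, entry: DispatchEntry) -> Optional[CandidateAlignment]:
        """Best single-end candidate for one strand, or None if unmapped."""
        seq, quals = self._oriented(
            entry.read1.seq, entry.read1.quals, entry.orientation
        )
        best, second = self._top2(self._scan_all(entry.target_genome, seq, quals))
        if best is None:
            return None
        chrom, pos, score = best
        return CandidateAlignment(
            strand=entry.strand,
            chrom=chrom,
            pos=pos,
            cigar=f"{len(seq)}M",
            AS=score,
            XS=second,
            is_reverse=(entry.orientation == "revcomp"),
            read_len=len(seq),
        )

    # -------------------------------------------------------------- paired-end
    def align_pair(self, entry: DispatchEntry) -> Optional[PairCandidate]:
        """Best properly oriented pair for one strand, or None.

        Mate 1 is scanned genome-wide; mate 2 is scanned exhaustively inside
        the insert window of each mate-1 placement, which is equivalent to a
        full cross of both mates' valid placements (a pair requires a valid
        mate-1 placement) but far cheaper.
        """
        assert entry.read2 is not None
        r1_rev = entry.orientation == "revcomp"
        s1, q1 = self._oriented(entry.read1.seq, entry.read1.quals, entry.orientation)
        # mate 2 always aligns in the opposite orientation
        orient2 = "forward" if r1_rev else "revcomp"
        s2, q2 = self._oriented(entry.read2.seq, entry.read2.quals, orient2)
        L1, L2 = len(s1), len(s2)
        genome = (
            self.genomes.ct_genome
            if entry.target_genome == "ct"
            else self.genomes.ga_genome
        )
        pen2 = self.scheme.penalty_vector(q2)
        read2 = encode(s2)
        maxpen2 = self.scheme.max_penalty(L2)

        pairs: List[Tuple[str, int, int, int, int]] = []  # chrom,p1,p2,s1,s2
        for chrom, p1, sc1 in self._scan_all(entry.target_genome, s1, q1):
            codes = self._codes[(entry.target_genome, chrom)]
            glen = len(genome[chrom])
            if r1_rev:
                # mate1 reverse (rightmost), mate2 forward (leftmost)
                lo = max(0, p1 + L1 - self.max_insert)
                hi = p1  # mate2 start must not pass mate1 start
            else:
                lo = p1
                hi = min(glen - L2, p1 + self.max_insert - L2)
            if hi < lo:
                continue
            window = codes[lo : hi + L2]
            pos2, sc2 = scan_offsets(
                window, read2, pen2, self.scheme.n_penalty, maxpen2
            )
            for p2, s2sc in zip(pos2, sc2):
                p2a = int(p2) + lo
                left = min(p1, p2a)
                right = max(p1 + L1, p2a + L2)
                if right - left <= self.max_insert:
                    pairs.append((chrom, p1, p2a, sc1, int(s2sc)))
        if not pairs:
            return None
        best = min(pairs, key=lambda h: (-(h[3] + h[4]), min(h[1], h[2]), h[0]))
        others = [h[3] + h[4] for h in pairs if h is not best]
        second = max(others) if others else None
        chrom, p1, p2, sc1, sc2 = best
        a1 = CandidateAlignment(
            strand=entry.strand,
            chrom=chrom,
            pos=p1,
            cigar=f"{L1}M",
            AS=sc1,
            is_reverse=r1_rev,
            read_len=L1,
        )
        a2 = CandidateAlignment(
            strand=entry.strand,
            chrom=chrom,
            pos=p2,
            cigar=f"{L2}M",
            AS=sc2,
            is_reverse=not r1_rev,
            read_len=L2,
        )
        return PairCandidate(strand=entry.strand, a1=a1, a2=a2, XS=second)

    def map_entry(self, entry: DispatchEntry):
        if entry.read2 is None:
            return self.align_single(entry)
        return self.align_pair(entry)


def align_exhaustive(
    read_seq: str,
    read_quals: str,
    genomes: ConvertedGenomePair,
    target_genome: Literal["ct", "ga"],
    orientation: Literal["forward", "revcomp"],
    strand: Strand,
    scheme: ScoringScheme = ScoringScheme(),
) -> Optional[CandidateAlignment]:
    """Functional wrapper: best ungapped placement of one converted read.

    Returns None when no placement meets the minimum valid score.
    """
    from .convert import BsRead

    backend = BuiltinBackend(genomes, scheme)
    entry = DispatchEntry(
        strand=strand,
        target_genome=target_genome,
        orientation=orientation,
        read1=BsRead("r", read_seq, read_quals, 1),
        read2=None,
        original1=BsRead("r", read_seq, read_quals, 1),
        original2=None,
    )
    return backend.align_single(entry)


# --------------------------------------------------------------------- external
#: per-strand bowtie2 orientation flags (end-to-end mode)
_STRAND_FLAGS: Dict[Strand, List[str]] = {
    "OT": ["--norc"],
    "OB": ["--nofw"],
    "CTOT": ["--nofw"],
    "CTOB": ["--norc"],
}


class ExternalBackendError(RuntimeError):
    pass


def find_external_aligner(executable: str = "bowtie2") -> Optional[str]:
    return shutil.which(executable)


def align_external(
    fastq1: str,
    index_prefix: str,
    strand: Strand,
    fastq2: Optional[str] = None,
    threads: int = 1,
    executable: str = "bowtie2",
    score_min: Optional[str] = None,
    extra_args: Optional[Sequence[str]] = None,
):
    """Run a bowtie2-compatible aligner for one strand, yielding SAM records.

    End-to-end mode with the strand's orientation constraint; mapped records
    missing an AS tag are rejected.  Raises ExternalBackendError on a nonzero
    subprocess exit, with captured stderr.
    """
    exe = find_external_aligner(executable)
    if exe is None:
        raise ExternalBackendError(f"external aligner {executable!r} not found")
    cmd = [exe, "--end-to-end", "--quiet", "-p", str(threads), "-x", index_prefix]
    cmd += _STRAND_FLAGS[strand]
    if score_min:
        cmd += ["--score-min", score_min]
    if extra_args:
        cmd += list(extra_args)
    if fastq2 is not None:
        cmd += ["-1", fastq1, "-2", fastq2, "--no-mixed", "--no-discordant"]
    else:
        cmd += ["-U", fastq1]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ExternalBackendError(
            f"{executable} exited with {proc.returncode}: {proc.stderr.strip()}"
        )
    yield from parse_sam_stream(proc.stdout)


def parse_sam_stream(text: str):
    """Parse SAM text into pysam records, enforcing AS on mapped records."""
    import pysam

    import io as _io
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write(text)
        path = fh.name
    with pysam.AlignmentFile(path, "r", check_sq=False) as af:
        for rec in af:
            if not rec.is_unmapped and not rec.has_tag("AS"):
                raise ExternalBackendError(
                    f"mapped record {rec.query_name!r} lacks an AS tag"
                )
            yield rec
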