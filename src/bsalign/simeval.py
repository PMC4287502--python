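"""Bisulfite read simulation with encoded ground truth, plus evaluation.

Fragments are drawn uniformly over genome positions and strands; each
cytosine of the fragment's originating strand is methylated with a context-
dependent probability, unmethylated cytosines read as T with the bisulfite
conversion rate, and uniform substitution errors are layered on top.  The
truth (contig, 1-based fragment start, originating strand, per-cytosine
methylation mask) is encoded in the read name so accuracy can be scored from
the alignment alone, with no sidecar files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import pysam

from .arbitrate import _context_top
from .genome import GenomeSequence, revcomp
from .convert import BsRead
from .seqio import FastqWriter

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions for read simulation.

    Defaults emulate a mammalian directional library: CpG methylation 0.7,
    negligible non-CpG methylation, complete bisulfite conversion, 0.1%
    uniform sequencing error, constant Q40 base qualities.
    """

    n_fragments: int = 1000
    read_len: int = 50
    pairing: Literal["single", "paired"] = "paired"
    insert_mean: float = 200.0
    insert_sd: float = 30.0
    directionality: Literal["directional", "non-directional"] = "directional"
    meth_prob: Dict[str, float] = field(
        default_factory=lambda: {"CpG": 0.7, "CHG": 0.01, "CHH": 0.01}
    )
    conversion_rate: float = 1.0
    error_rate: float = 0.001
    constant_qual: int = 40
    qual_3prime_decay: float = 0.0  # Phred lost per base toward the 3' end
    #: force the first N read positions' cytosines to read unmethylated
    #: (synthetic 5' end-repair bias, for M-bias testing)
    five_prime_unmeth: int = 0
    seed: int = 1

    def validate(self) -> None:
        for k, v in self.meth_prob.items():
            if not 0 <= v <= 1:
                raise ValueError(f"meth_prob[{k}]={v} outside [0, 1]")
        for name in ("conversion_rate", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")


@dataclass
class TruthRecord:
    chrom: str
    start: int  # 1-based leftmost fragment coordinate
    strand: str  # '+' (top) or '-' (bottom)
    mask: str  # per-fragment-cytosine methylation bits, 5'->3' on the strand

    def encode(self, index: int) -> str:
        return f"sim{index}:{self.chrom}:{self.start}:{self.strand}:{self.mask}"

    @classmethod
    def decode(cls, name: str) -> "TruthRecord":
        """Inverse of :meth:`encode`.

        The index prefix never contains ':' and the last three fields are
        colon-free, so contig names containing ':' (e.g. reduced-genome
        fragments) survive the round trip.
        """
        try:
            _idx, rest = name.split(":", 1)
            chrom, start, strand, mask = rest.rsplit(":", 3)
            start_i = int(start)
        except ValueError:
            raise ValueError(f"read name {name!r} carries no truth record")
        if strand not in "+-":
            raise ValueError(f"read name {name!r} carries no truth record")
        return cls(chrom, start_i, strand, mask)


def _qual_string(cfg: SimulationConfig) -> str:
    quals = [
        max(2, int(cfg.constant_qual - cfg.qual_3prime_decay * i))
        for i in range(cfg.read_len)
    ]
    return "".join(chr(33 + q) for q in quals)


def _bisulfite_fragment(
    frag: str, context_seq: str, offset: int, cfg: SimulationConfig, rng
) -> Tuple[str, str]:
    """Apply methylation + conversion to a strand-oriented fragment.

    ``context_seq``/``offset`` give the fragment's position within its
    strand's full sequence so CpG/CHG/CHH context is read past the fragment
    ends.  Returns (converted fragment, methylation mask over its Cs).
    """
    out = list(frag)
    mask = []
    for i, b in enumerate(frag):
        if b != "C":
            continue
        ctx_letter = _context_top(context_seq, offset + i)
        ctx = {"Z": "CpG", "X": "CHG", "H": "CHH"}.get(ctx_letter or "", "CHH")
        methylated = rng.random() < cfg.meth_prob[ctx]
        if not methylated and rng.random() < cfg.conversion_rate:
            out[i] = "T"
        mask.append("1" if methylated else "0")
    return "".join(out), "".join(mask)


def _apply_errors(seq: str, cfg: SimulationConfig, rng) -> str:
    if cfg.error_rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < cfg.error_rate)[0]
    for i in hits:
        choices = [b for b in _BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def _force_5prime_unmeth(read: str, genome_frag: str, k: int) -> str:
    """Rewrite the first k positions so genomic Cs read as T (unmethylated)."""
    out = list(read)
    for i in range(min(k, len(read))):
        if genome_frag[i] == "C":
            out[i] = "T"
    return "".join(out)


def simulate(
    genome: GenomeSequence,
    cfg: SimulationConfig,
    out_prefix: str | Path,
) -> List[Path]:
    """Simulate reads to FASTQ (gzipped); returns the file paths written.

    Single-end: ``<prefix>.fastq.gz``; paired: ``<prefix>_1/_2.fastq.gz``.
    Byte-identical across runs with the same seed and config.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    paired = cfg.pairing == "paired"
    frag_floor = cfg.read_len if not paired else cfg.read_len
    min_contig = cfg.insert_mean + 4 * cfg.insert_sd if paired else cfg.read_len
    names = [n for n, s in genome.items() if len(s) >= min_contig]
    if not names:
        raise ValueError(
            "no contig is long enough for the configured fragment length"
        )
    lengths = np.array([len(genome[n]) for n in names], dtype=float)
    weights = lengths / lengths.sum()
    quals = _qual_string(cfg)

    paths: List[Path] = []
    if paired:
        w1 = FastqWriter(f"{out_prefix}_1.fastq.gz")
        w2 = FastqWriter(f"{out_prefix}_2.fastq.gz")
        paths = [w1.path, w2.path]
    else:
        w1 = FastqWriter(f"{out_prefix}.fastq.gz")
        w2 = None
        paths = [w1.path]

    # precompute per-strand context sequences per contig
    bottoms = {n: revcomp(genome[n]) for n in names}

    for idx in range(cfg.n_fragments):
        ci = int(rng.choice(len(names), p=weights))
        chrom = names[ci]
        top = genome[chrom]
        glen = len(top)
        if paired:
            flen = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
            flen = max(cfg.read_len, min(flen, glen))
        else:
            flen = cfg.read_len
        start = int(rng.integers(0, glen - flen + 1))  # 0-based top-strand
        strand = "+" if rng.random() < 0.5 else "-"

        if strand == "+":
            frag = top[start : start + flen]
            conv, mask = _bisulfite_fragment(frag, top, start, cfg, rng)
        else:
            bottom = bottoms[chrom]
            boff = glen - (start + flen)  # fragment position on bottom strand
            frag = bottom[boff : boff + flen]
            conv, mask = _bisulfite_fragment(frag, bottom, boff, cfg, rng)

        # non-directional: half the fragments are sequenced from the
        # PCR-complementary strand instead
        complementary = (
            cfg.directionality == "non-directional" and rng.random() < 0.5
        )
        if complementary:
            conv_seq = revcomp(conv)
            frag_seq = revcomp(frag)
        else:
            conv_seq = conv
            frag_seq = frag

        truth = TruthRecord(chrom, start + 1, strand, mask)
        name = truth.encode(idx)
        if paired:
            r1 = conv_seq[: cfg.read_len]
            r2 = revcomp(conv_seq[-cfg.read_len :])
            if cfg.five_prime_unmeth:
                r1 = _force_5prime_unmeth(
                    r1, frag_seq[: cfg.read_len], cfg.five_prime_unmeth
                )
                r2 = _force_5prime_unmeth(
                    r2,
                    revcomp(frag_seq)[: cfg.read_len],
                    cfg.five_prime_unmeth,
                )
            r1 = _apply_errors(r1, cfg, rng)
            r2 = _apply_errors(r2, cfg, rng)
            w1.write(BsRead(name, r1, quals, 1))
            w2.write(BsRead(name, r2, quals, 2))
        else:
            r1 = conv_seq[: cfg.read_len]
            if cfg.five_prime_unmeth:
                r1 = _force_5prime_unmeth(
                    r1, frag_seq[: cfg.read_len], cfg.five_prime_unmeth
                )
            r1 = _apply_errors(r1, cfg, rng)
            w1.write(BsRead(name, r1, quals, 0))

    w1.close()
    if w2:
        w2.close()
    return paths


# ------------------------------------------------------------------ evaluation
@dataclass
class AccuracySummary:
    """Correct / incorrect / discarded unit counts, overall and at a MAPQ
    threshold (sub-threshold alignments move to the discarded stratum)."""

    n_total: int = 0
    n_correct: int = 0
    n_incorrect: int = 0
    n_discarded: int = 0
    mapq_threshold: int = 10
    n_correct_thr: int = 0
    n_incorrect_thr: int = 0
    n_discarded_thr: int = 0
    n_unparseable: int = 0

    def check(self) -> None:
        assert self.n_correct + self.n_incorrect + self.n_discarded == self.n_total
        assert (
            self.n_correct_thr + self.n_incorrect_thr + self.n_discarded_thr
            == self.n_total
        )

    def as_dict(self) -> Dict[str, float]:
        def pct(x):
            return 100.0 * x / self.n_total if self.n_total else 0.0

        return {
            "n_total": self.n_total,
            "pct_correct": pct(self.n_correct),
            "pct_incorrect": pct(self.n_incorrect),
            "pct_discarded": pct(self.n_discarded),
            "pct_correct_mapq": pct(self.n_correct_thr),
            "pct_incorrect_mapq": pct(self.n_incorrect_thr),
            "pct_discarded_mapq": pct(self.n_discarded_thr),
        }


def evaluate(bam: str | Path, mapq_threshold: int = 10) -> AccuracySummary:
    """Score alignments against the truth encoded in read names.

    A unit (read or pair) is correct iff mapped to the truth contig with its
    leftmost coordinate equal to the truth fragment start (pairs: the pair's
    leftmost mate).  Unparseable names are rejected and counted.
    """
    units: Dict[str, List[pysam.AlignedSegment]] = {}
    order: List[str] = []
    summary = AccuracySummary(mapq_threshold=mapq_threshold)
    with pysam.AlignmentFile(str(bam), check_sq=False) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name not in units:
                units[rec.query_name] = []
                order.append(rec.query_name)
            units[rec.query_name].append(rec)

    for name in order:
        try:
            truth = TruthRecord.decode(name)
        except ValueError:
            summary.n_unparseable += 1
            continue
        recs = units[name]
        summary.n_total += 1
        if any(r.is_unmapped for r in recs):
            summary.n_discarded += 1
            summary.n_discarded_thr += 1
            continue
        leftmost = min(r.reference_start for r in recs) + 1
        chrom = recs[0].reference_name
        correct = chrom == truth.chrom and leftmost == truth.start
        mapq = min(r.mapping_quality for r in recs)
        if correct:
            summary.n_correct += 1
        else:
            summary.n_incorrect += 1
        if mapq < mapq_threshold:
            summary.n_discarded_thr += 1
        elif correct:
            summary.n_correct_thr += 1
        else:
            summary.n_incorrect_thr += 1
    summary.check()
    return summary


# ----------------------------------------------------------------- concordance
@dataclass
class ConcordanceSummary:
    concordant: int = 0
    discordant: int = 0
    only_a: int = 0
    only_b: int = 0
    mapq_concordant: List[int] = field(default_factory=list)
    mapq_discordant: List[int] = field(default_factory=list)
    mapq_only_a: List[int] = field(default_factory=list)
    mapq_only_b: List[int] = field(default_factory=list)

    def as_dict(self) -> Dict[str, int]:
        return {
            "concordant": self.concordant,
            "discordant": self.discordant,
            "only_a": self.only_a,
            "only_b": self.only_b,
        }


def _primary_map(bam: str | Path) -> Dict[str, Tuple[str, int, int]]:
    """name -> (chrom, leftmost start, MAPQ) for mapped primary units."""
    out: Dict[str, Tuple[str, int, int]] = {}
    seen_mates: Dict[str, int] = {}
    with pysam.AlignmentFile(str(bam), check_sq=False) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            name = rec.query_name
            mate_bit = 2 if rec.is_read2 else 1
            prev = seen_mates.get(name, 0)
            if prev & mate_bit:
                raise ValueError(f"duplicate primary record for {name!r}")
            seen_mates[name] = prev | mate_bit
            cur = out.get(name)
            if cur is None or rec.reference_start < cur[1]:
                mapq = rec.mapping_quality if cur is None else min(
                    cur[2], rec.mapping_quality
                )
                out[name] = (rec.reference_name, rec.reference_start, mapq)
            else:
                out[name] = (cur[0], cur[1], min(cur[2], rec.mapping_quality))
    return out


def concordance(bam_a: str | Path, bam_b: str | Path) -> ConcordanceSummary:
    """Compare two alignment runs of the same read set by start coordinate.

    Units present in both files are concordant iff contig and leftmost start
    agree; units present in only one file are tallied separately, each
    category keeping its MAPQ distribution.
    """
    a = _primary_map(bam_a)
    b = _primary_map(bam_b)
    s = ConcordanceSummary()
    for name, (chrom, pos, mapq) in a.items():
        if name in b:
            bc, bp, bq = b[name]
            if (chrom, pos) == (bc, bp):
                s.concordant += 1
                s.mapq_concordant.append(mapq)
            else:
                s.discordant += 1
                s.mapq_discordant.append(mapq)
        else:
            s.only_a += 1
            s.mapq_only_a.append(mapq)
    for name, (_c, _p, mapq) in b.items():
        if name not in a:
            s.only_b += 1
            s.mapq_only_b.append(mapq)
    return s


def write_report(
    summary: AccuracySummary, path_prefix: str | Path
) -> List[Path]:
    """Write an accuracy report as TSV + JSON."""
    d = summary.as_dict()
    tsv = Path(f"{path_prefix}.tsv")
    with open(tsv, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in d.items():
            fh.write(f"{k}\t{v}\n")
    js = Path(f"{path_prefix}.json")
    with open(js, "w") as fh:
        json.dump(d, fh, indent=2)
    return [tsv, js]
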