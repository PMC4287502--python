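"""Methylation extraction: per-cytosine context-stratified counts and bedGraph.

Counts are keyed by (chrom, 0-based position, strand, context).  The position
is that of the cytosine on its own strand projected onto top-strand
coordinates: for '-' strand calls it is the position of the top-strand G.

Paired-end overlap rule: the overlapping portion of a properly paired
fragment is processed as a unit so calls are never double-counted.  Where
only one mate carries a usable call (the other has '.', an N/mismatch, or a
base below the Phred floor) that call is used; where both carry usable calls
they count once if they agree and not at all if they disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

from .calls import (
    MissingXMError,
    call_context,
    iter_calls,
    record_mate,
    record_passes,
    record_strand,
)
from .filters import FilterConfig
from .genome import GenomeSequence

CountKey = Tuple[str, int, str, str]  # chrom, pos0, strand(+/-), context

CONTEXTS = ("CpG", "CHG", "CHH")


@dataclass
class MethylationCounts:
    """Context-stratified methylated/unmethylated tallies per cytosine."""

    counts: Dict[CountKey, List[int]] = field(default_factory=dict)
    chrom_order: List[str] = field(default_factory=list)
    n_rejected: int = 0  # records lacking XM

    def add(self, key: CountKey, methylated: bool, n: int = 1) -> None:
        c = self.counts.setdefault(key, [0, 0])
        c[0 if methylated else 1] += n

    def add_counts(self, key: CountKey, n_meth: int, n_unmeth: int) -> None:
        c = self.counts.setdefault(key, [0, 0])
        c[0] += n_meth
        c[1] += n_unmeth

    def restrict(self, context: str) -> "MethylationCounts":
        return MethylationCounts(
            {k: v[:] for k, v in self.counts.items() if k[3] == context},
            self.chrom_order[:],
        )

    def total_calls(self) -> int:
        return sum(m + u for m, u in self.counts.values())

    def sorted_items(self):
        order = {c: i for i, c in enumerate(self.chrom_order)}
        return sorted(
            self.counts.items(),
            key=lambda kv: (order.get(kv[0][0], len(order)), kv[0][0], kv[0][1]),
        )

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MethylationCounts):
            return NotImplemented
        return self.counts == other.counts


def _usable_calls(rec, filters: FilterConfig):
    """Map ref_pos -> (symbol, phred) of calls passing Phred and trims."""
    strand = record_strand(rec)
    mate = record_mate(rec)
    out: Dict[int, Tuple[str, int]] = {}
    for call in iter_calls(rec):
        if call.phred < filters.min_phred:
            continue
        if filters.trims is not None and not filters.trims.keeps(
            strand, mate, call.read_pos
        ):
            continue
        out[call.ref_pos] = (call.symbol, call.phred)
    return out


def _count_single(counts: MethylationCounts, rec, filters: FilterConfig) -> None:
    chrom = rec.reference_name
    calls = _usable_calls(rec, filters)  # raises MissingXMError if untagged
    strand = "+" if rec.get_tag("XG") == "CT" else "-"
    for pos, (sym, _ph) in calls.items():
        counts.add((chrom, pos, strand, call_context(sym)), sym.isupper())


def _count_pair(counts: MethylationCounts, r1, r2, filters: FilterConfig) -> None:
    chrom = r1.reference_name
    c1 = _usable_calls(r1, filters)
    c2 = _usable_calls(r2, filters)
    strand = "+" if r1.get_tag("XG") == "CT" else "-"
    for pos in c1.keys() | c2.keys():
        in1, in2 = pos in c1, pos in c2
        if in1 and in2:
            s1, s2 = c1[pos][0], c2[pos][0]
            if s1 != s2:
                continue  # high-quality disagreement: drop the position
            sym = s1
        else:
            sym = c1[pos][0] if in1 else c2[pos][0]
        counts.add((chrom, pos, strand, call_context(sym)), sym.isupper())


def extract_methylation(
    bam: str | Path,
    genome: Optional[GenomeSequence] = None,
    filters: FilterConfig = FilterConfig(),
) -> MethylationCounts:
    """Tally methylation calls from an aligned, XM-tagged BAM/SAM file.

    Skips unmapped, secondary/supplementary, duplicate-flagged and
    low-MAPQ records; mates of a proper pair are processed jointly.
    Records lacking XM are rejected and counted in ``n_rejected``.
    """
    counts = MethylationCounts()
    pending: Dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(bam), check_sq=False) as af:
        counts.chrom_order = list(af.references)
        if genome is not None:
            for name in af.references:
                if name not in genome:
                    raise ValueError(f"BAM contig {name!r} absent from genome")
        for rec in af:
            if not record_passes(rec, filters.min_mapq):
                continue
            try:
                if rec.is_paired and rec.is_proper_pair:
                    other = pending.pop(rec.query_name, None)
                    if other is None:
                        pending[rec.query_name] = rec
                    else:
                        _count_pair(counts, other, rec, filters)
                else:
                    _count_single(counts, rec, filters)
            except MissingXMError:
                counts.n_rejected += 1
    # mates whose partner never passed the filters count alone
    for rec in pending.values():
        try:
            _count_single(counts, rec, filters)
        except MissingXMError:
            counts.n_rejected += 1
    return counts


# ------------------------------------------------------------------- bedGraph
def write_bedgraph(
    counts: MethylationCounts, context: str, path: str | Path
) -> Path:
    """Write one context's counts as a 6-column methylation bedGraph.

    Columns: chrom, start (0-based), end, percent methylation (integer-
    rounded), n_meth, n_unmeth.  Zero-coverage keys are never present.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph description="{context} methylation"\n')
        for (chrom, pos, _strand, ctx), (m, u) in counts.sorted_items():
            if ctx != context or m + u == 0:
                continue
            pct = int(100.0 * m / (m + u) + 0.5)
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{pct}\t{m}\t{u}\n")
    return path


def write_all_bedgraphs(
    counts: MethylationCounts, prefix: str | Path
) -> Dict[str, Path]:
    return {
        ctx: write_bedgraph(counts, ctx, f"{prefix}_{ctx}.bedGraph")
        for ctx in CONTEXTS
    }


def parse_bedgraph(
    path: str | Path,
    context: str,
    genome: Optional[GenomeSequence] = None,
) -> MethylationCounts:
    """Read a 6-column methylation bedGraph back into counts.

    The strand is inferred from the genome when given (C at the position ->
    '+', G -> '-'); without a genome all records are taken as '+'.
    """
    counts = MethylationCounts()
    seen_chroms: List[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, _end, _pct, m, u = line.rstrip("\n").split("\t")
            pos = int(start)
            strand = "+"
            if genome is not None:
                base = genome[chrom][pos]
                strand = "+" if base == "C" else "-"
            if chrom not in seen_chroms:
                seen_chroms.append(chrom)
            counts.add_counts((chrom, pos, strand, context), int(m), int(u))
    counts.chrom_order = seen_chroms
    return counts


# ------------------------------------------------------------------ CpG merge
def merge_cpg(
    counts: MethylationCounts, genome: GenomeSequence
) -> MethylationCounts:
    """Merge the two cytosines of each CpG into one record at the + strand C.

    Counts from the - strand C (top-strand G at position p) are added to the
    + strand C at p-1.  Input must be CpG-context; any record not at a
    genomic CpG cytosine is rejected.
    """
    merged = MethylationCounts(chrom_order=counts.chrom_order[:])
    for (chrom, pos, strand, ctx), (m, u) in counts.counts.items():
        if ctx != "CpG":
            raise ValueError(f"non-CpG record at {chrom}:{pos} ({ctx})")
        seq = genome[chrom]
        if strand == "+":
            if not (seq[pos] == "C" and pos + 1 < len(seq) and seq[pos + 1] == "G"):
                raise ValueError(f"{chrom}:{pos}(+) is not a CpG cytosine")
            target = pos
        else:
            if not (seq[pos] == "G" and pos >= 1 and seq[pos - 1] == "C"):
                raise ValueError(f"{chrom}:{pos}(-) is not a CpG guanine")
            target = pos - 1
        merged.add_counts((chrom, target, "+", "CpG"), m, u)
    return merged


def merge_replicates(*replicates: MethylationCounts) -> MethylationCounts:
    """Per-key count addition across technical replicates."""
    out = MethylationCounts()
    for rep in replicates:
        for name in rep.chrom_order:
            if name not in out.chrom_order:
                out.chrom_order.append(name)
        for key, (m, u) in rep.counts.items():
            out.add_counts(key, m, u)
    return out


# ------------------------------------------------------------------- coverage
COVERAGE_THRESHOLDS = (1, 3, 5, 10, 30, 50, 100)


def coverage_metrics(
    counts: MethylationCounts,
    thresholds: Sequence[int] = COVERAGE_THRESHOLDS,
) -> Dict[int, int]:
    """Number of CpGs whose total call count reaches each threshold."""
    totals = [
        m + u for (_, _, _, ctx), (m, u) in counts.counts.items() if ctx == "CpG"
    ]
    return {t: sum(1 for x in totals if x >= t) for t in thresholds}


# -------------------------------------------------------------------- exports
def export_format(
    counts: MethylationCounts, dialect: str, path: str | Path
) -> Path:
    """Write counts in an R-package input dialect (methylKit or BSseq)."""
    path = Path(path)
    if dialect == "methylKit":
        with open(path, "w") as fh:
            fh.write("chrBase\tchr\tbase\tstrand\tcoverage\tfreqC\tfreqT\n")
            for (chrom, pos, strand, _ctx), (m, u) in counts.sorted_items():
                cov = m + u
                if cov == 0:
                    continue
                base = pos + 1
                st = "F" if strand == "+" else "R"
                fh.write(
                    f"{chrom}.{base}\t{chrom}\t{base}\t{st}\t{cov}\t"
                    f"{100.0 * m / cov:.2f}\t{100.0 * u / cov:.2f}\n"
                )
    elif dialect == "BSseq":
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tcoverage\tmethylated\n")
            for (chrom, pos, _strand, _ctx), (m, u) in counts.sorted_items():
                if m + u == 0:
                    continue
                fh.write(f"{chrom}\t{pos + 1}\t{m + u}\t{m}\n")
    else:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported: methylKit, BSseq"
        )
    return path
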