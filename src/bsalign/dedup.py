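"""Methylation-aware PCR duplicate marking.

Two alignments (or pairs, considered as units) are duplicate candidates if
they lie on the same strand of the same contig with identical soft-clip-
adjusted 5' coordinates.  Candidates are additionally required to carry
matching methylation calls: only calls from bases with Phred >= 5 count, and
a position where at most one of the two reads has a usable call does not
differentiate them.  This is more conservative than position-only marking —
every read marked here would also be marked by a position-only method, but
not vice versa.  Within a duplicate group the copy with the highest total
base Phred is kept unmarked.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .calls import iter_calls, record_strand


@dataclass(frozen=True)
class DuplicateSignature:
    chrom: str
    strand: str  # OT/OB/CTOT/CTOB
    five_prime: Tuple[int, ...]  # one coordinate per read; ordered for pairs


def _clips(rec: pysam.AlignedSegment) -> Tuple[int, int]:
    """(leading, trailing) soft-clipped base counts."""
    ct = rec.cigartuples or []
    lead = ct[0][1] if ct and ct[0][0] == 4 else 0
    trail = ct[-1][1] if ct and ct[-1][0] == 4 else 0
    return lead, trail


def five_prime_coord(rec: pysam.AlignedSegment) -> int:
    """Soft-clip-adjusted 5' coordinate (0-based).

    Forward reads: alignment start minus leading clip; reverse reads: last
    aligned base plus trailing clip.
    """
    lead, trail = _clips(rec)
    if rec.is_reverse:
        return rec.reference_end - 1 + trail
    return rec.reference_start - lead


def signature(
    recs: Sequence[pysam.AlignedSegment],
) -> Optional[DuplicateSignature]:
    """Signature of a single read or a pair; None if any record is unmapped."""
    if any(r.is_unmapped for r in recs):
        return None
    coords = tuple(sorted(five_prime_coord(r) for r in recs))
    return DuplicateSignature(
        chrom=recs[0].reference_name,
        strand=record_strand(recs[0]),
        five_prime=coords,
    )


def _call_map(rec: pysam.AlignedSegment, min_phred: int) -> Dict[int, str]:
    """ref_pos -> symbol for calls with Phred >= min_phred."""
    return {
        c.ref_pos: c.symbol
        for c in iter_calls(rec)
        if c.phred >= min_phred
    }


def meth_match(
    calls_a: Dict[int, str], calls_b: Dict[int, str]
) -> bool:
    """True iff no reference position carries conflicting usable calls.

    Positions where at most one side has a usable call do not differ.
    """
    for pos, sym in calls_a.items():
        other = calls_b.get(pos)
        if other is not None and other != sym:
            return False
    return True


def unit_call_map(
    recs: Sequence[pysam.AlignedSegment], min_phred: int = 5
) -> Dict[int, str]:
    """Combined call map of a read unit (pair or single).

    Mate-overlap conflicts within one unit are dropped (no usable call)."""
    merged: Dict[int, str] = {}
    dropped = set()
    for rec in recs:
        for pos, sym in _call_map(rec, min_phred).items():
            if pos in dropped:
                continue
            if pos in merged and merged[pos] != sym:
                del merged[pos]
                dropped.add(pos)
            else:
                merged[pos] = sym
    return merged


def _phred_sum(recs: Sequence[pysam.AlignedSegment]) -> int:
    return sum(sum(r.query_qualities or []) for r in recs)


def mark_duplicates(
    in_bam: str | Path,
    out_bam: str | Path,
    min_phred: int = 5,
) -> Tuple[int, int]:
    """Mark methylation-identical positional duplicates with flag 0x400.

    Pairs are treated as units.  Within each positional bucket, units are
    greedily grouped: each unit (in coordinate-then-name order) joins the
    first existing group whose representative its calls match, else founds a
    new group.  The unit with the highest summed base Phred in each group is
    kept unmarked.  Secondary/supplementary records are never marked and
    never represent a group.

    Returns (n_units_examined, n_units_marked).  Requires coordinate-sorted
    input.
    """
    in_bam, out_bam = Path(in_bam), Path(out_bam)
    with pysam.AlignmentFile(str(in_bam), check_sq=False) as af:
        so = af.header.to_dict().get("HD", {}).get("SO", "")
        if so != "coordinate":
            raise ValueError("mark_duplicates requires a coordinate-sorted BAM")
        header = af.header
        records = list(af)

    # group primary mapped records into units by name
    units: Dict[str, List[pysam.AlignedSegment]] = defaultdict(list)
    order: List[str] = []
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.query_name not in units:
            order.append(rec.query_name)
        units[rec.query_name].append(rec)

    buckets: Dict[DuplicateSignature, List[str]] = defaultdict(list)
    for name in order:
        sig = signature(units[name])
        if sig is not None:
            buckets[sig].append(name)

    marked: set[str] = set()
    n_units = len(order)
    for sig, names in buckets.items():
        if len(names) < 2:
            continue
        # deterministic order: coordinate, then name
        names = sorted(
            names, key=lambda n: (min(r.reference_start for r in units[n]), n)
        )
        groups: List[List[str]] = []
        reps: List[Dict[int, str]] = []
        for name in names:
            calls = unit_call_map(units[name], min_phred)
            for group, rep in zip(groups, reps):
                if meth_match(rep, calls):
                    group.append(name)
                    break
            else:
                groups.append([name])
                reps.append(calls)
        for group in groups:
            if len(group) < 2:
                continue
            keep = max(group, key=lambda n: (_phred_sum(units[n]), n))
            for name in group:
                if name != keep:
                    marked.add(name)

    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as out:
        for rec in records:
            if rec.query_name in marked and not (
                rec.is_secondary or rec.is_supplementary
            ):
                rec.flag |= 0x400
            out.write(rec)
    pysam.index(str(out_bam))
    return n_units, len(marked)


def mark_duplicates_position_only(
    in_bam: str | Path, out_bam: str | Path
) -> Tuple[int, int]:
    """Position-only duplicate marking (no methylation comparison).

    Reference behaviour used to check that the methylation-aware method
    marks a subset of what a purely positional method would mark.
    """
    in_bam, out_bam = Path(in_bam), Path(out_bam)
    with pysam.AlignmentFile(str(in_bam), check_sq=False) as af:
        header = af.header
        records = list(af)
    units: Dict[str, List[pysam.AlignedSegment]] = defaultdict(list)
    order: List[str] = []
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.query_name not in units:
            order.append(rec.query_name)
        units[rec.query_name].append(rec)
    buckets: Dict[DuplicateSignature, List[str]] = defaultdict(list)
    for name in order:
        sig = signature(units[name])
        if sig is not None:
            buckets[sig].append(name)
    marked: set[str] = set()
    for names in buckets.values():
        if len(names) < 2:
            continue
        keep = max(names, key=lambda n: (_phred_sum(units[n]), n))
        marked.update(n for n in names if n != keep)
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as out:
        for rec in records:
            if rec.query_name in marked and not (
                rec.is_secondary or rec.is_supplementary
            ):
                rec.flag |= 0x400
            out.write(rec)
    return len(order), len(marked)
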