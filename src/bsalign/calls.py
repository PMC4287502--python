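"""Per-record methylation-call iteration over BAM records with XM tags.

The XM string is positionally parallel to the SAM-stored sequence; this
module maps each non-'.' symbol back to its reference coordinate (CIGAR-
aware, so insertions/soft-clips contribute nothing and deletions shift the
reference cursor) and to its 1-based position from the sequencing 5' end of
the read (needed for M-bias and trimming, which operate in read coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Tuple

import pysam

_CONSUME_QUERY = {0, 1, 4, 7, 8}  # M, I, S, =, X
_CONSUME_REF = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass(frozen=True)
class MethCall:
    ref_pos: int  # 0-based reference coordinate of the cytosine
    read_pos: int  # 1-based position from the read's sequencing 5' end
    symbol: str  # one of Z z X x H h
    phred: int


class MissingXMError(ValueError):
    """The record lacks the methylation tags (XM/XG/XR) this tool emits."""


def record_strand(rec: pysam.AlignedSegment) -> str:
    """Originating strand (OT/OB/CTOT/CTOB) from the XG/XR tags.

    Mate 2 carries the complementary read conversion, so its XR is flipped
    back before the lookup.
    """
    if not (rec.has_tag("XG") and rec.has_tag("XR")):
        raise MissingXMError(
            f"record {rec.query_name!r} lacks XG/XR strand tags"
        )
    xg = rec.get_tag("XG")
    xr = rec.get_tag("XR")
    if rec.is_paired and rec.is_read2:
        xr = "GA" if xr == "CT" else "CT"
    return {
        ("CT", "CT"): "OT",
        ("GA", "CT"): "OB",
        ("CT", "GA"): "CTOT",
        ("GA", "GA"): "CTOB",
    }[(xg, xr)]


def record_mate(rec: pysam.AlignedSegment) -> int:
    if rec.is_paired and rec.is_read2:
        return 2
    return 1


def iter_calls(rec: pysam.AlignedSegment) -> Iterator[MethCall]:
    """Yield every methylation call (non-'.' XM symbol) of a record."""
    if not rec.has_tag("XM"):
        raise MissingXMError(f"record {rec.query_name!r} lacks an XM tag")
    xm = rec.get_tag("XM")
    quals = rec.query_qualities
    length = len(xm)
    q = 0
    r = rec.reference_start
    for op, n in rec.cigartuples or []:
        consumes_q = op in _CONSUME_QUERY
        consumes_r = op in _CONSUME_REF
        if consumes_q and consumes_r:
            for k in range(n):
                sym = xm[q + k]
                if sym != ".":
                    if rec.is_reverse:
                        read_pos = length - (q + k)
                    else:
                        read_pos = q + k + 1
                    yield MethCall(r + k, read_pos, sym, int(quals[q + k]))
            q += n
            r += n
        elif consumes_q:
            q += n
        elif consumes_r:
            r += n


_CONTEXT_OF = {"Z": "CpG", "X": "CHG", "H": "CHH"}


def call_context(symbol: str) -> str:
    return _CONTEXT_OF[symbol.upper()]


def record_passes(rec: pysam.AlignedSegment, min_mapq: int) -> bool:
    """Record-level filter used identically by extraction, M-bias and dedup
    grouping: mapped, primary, non-duplicate, MAPQ at or above threshold."""
    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
        return False
    if rec.is_duplicate:
        return False
    return rec.mapping_quality >= min_mapq
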