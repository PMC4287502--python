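"""Cross-strand arbitration: best-alignment selection, MAPQ, methylation calls.

A read (or pair) is aligned once per searchable strand; the candidates are
then compared by alignment score.  If exactly one strand attains the maximum
(summed, for pairs) score, that alignment wins and its XS tag is raised to
the best score among the losing strands, so the recalculated MAPQ reflects
every alignment that was actually considered.  If two or more strands tie at
the maximum, the read is reported unmapped: such placements are unreliable.

The methylation string (XM) is assigned per aligned base from the
*unconverted* read sequence against the *unconverted* genome:

=========  ==========  =========
context    methylated  unmethyl.
=========  ==========  =========
CpG        Z           z
CHG        X           x
CHH        H           h
=========  ==========  =========

'.' marks positions with no call (genome base not a relevant cytosine, read
mismatch, insertion, soft-clip, or context undefined at a contig edge).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .backend import CandidateAlignment, PairCandidate, ScoringScheme
from .convert import Strand
from .genome import GenomeSequence, revcomp

#: XG (genome conversion) and read-1 XR (read conversion) per strand.
#: Mate 2 of a pair carries the complementary read conversion.
STRAND_TAGS: Dict[Strand, Tuple[str, str]] = {
    "OT": ("CT", "CT"),
    "OB": ("GA", "CT"),
    "CTOT": ("CT", "GA"),
    "CTOB": ("GA", "GA"),
}

MAX_MAPQ = 42

Candidate = Union[CandidateAlignment, PairCandidate]


def select_best(candidates: Iterable[Optional[Candidate]]) -> Optional[Candidate]:
    """Pick the unique highest-scoring strand candidate, or None (unmapped).

    The winner's XS is combined (by max) with the best score among the other
    strands' candidates; an existing higher XS is left untouched.
    """
    cands: List[Candidate] = [c for c in candidates if c is not None]
    if not cands:
        return None
    best_score = max(c.score for c in cands)
    winners = [c for c in cands if c.score == best_score]
    if len(winners) != 1:
        return None  # cross-strand tie: unreliable placement
    chosen = winners[0]
    others = [c.score for c in cands if c is not chosen]
    if others:
        other_best = max(others)
        if chosen.XS is None or other_best > chosen.XS:
            chosen.XS = other_best
    return chosen


def recalc_mapq(
    AS: int,
    XS: Optional[int],
    read_len_total: int,
    scheme: ScoringScheme = ScoringScheme(),
    n_mates: int = 1,
) -> int:
    """Mapping quality in [0, 42] from the cross-strand AS/XS pair.

    The score is normalized to ``bestOver/diff``, the fraction of the span
    between the minimum valid score and a perfect score that the alignment
    attains; the gap ``AS - XS`` to the second-best alignment caps the result.
    For pairs, scores are summed and the floor is the sum of per-mate floors.
    """
    sc_min = n_mates * scheme.min_score_const + scheme.min_score_coeff * read_len_total
    if AS < sc_min:
        raise ValueError(f"AS={AS} below minimum valid score {sc_min:.1f}")
    diff = max(1.0, scheme.perfect_score * n_mates - sc_min)
    best_over = AS - sc_min
    o = best_over / diff

    if XS is None or XS < sc_min:
        if o >= 0.8:
            return 42
        if o >= 0.7:
            return 40
        if o >= 0.6:
            return 24
        if o >= 0.5:
            return 23
        if o >= 0.4:
            return 8
        if o >= 0.3:
            return 3
        return 0

    bestdiff = AS - XS
    if bestdiff <= 0:
        # tied with a secondary alignment: essentially ambiguous
        return 3 if o >= 0.67 else 0
    r = min(1.0, bestdiff / diff)
    base = 23 + int(round(19 * r))
    if o >= 0.8:
        cap = 42
    elif o >= 0.6:
        cap = 30
    elif o >= 0.4:
        cap = 8
    elif o >= 0.3:
        cap = 3
    else:
        cap = 0
    return min(base, cap)


# ----------------------------------------------------------------- methylation
def _context_top(seq: str, i: int) -> Optional[str]:
    """Context letter pair for a top-strand C at *i*: 'Z', 'X', 'H' or None."""
    n = len(seq)
    if i + 1 >= n:
        return None
    b1 = seq[i + 1]
    if b1 == "G":
        return "Z"
    if b1 == "N":
        return None
    if i + 2 >= n:
        return None
    b2 = seq[i + 2]
    if b2 == "G":
        return "X"
    if b2 == "N":
        return None
    return "H"


def _context_bottom(seq: str, i: int) -> Optional[str]:
    """Context for a bottom-strand C (top-strand G) at *i*, read 3'-ward on
    the bottom strand, i.e. leftward on the top strand."""
    if i - 1 < 0:
        return None
    b1 = seq[i - 1]
    if b1 == "C":
        return "Z"
    if b1 == "N":
        return None
    if i - 2 < 0:
        return None
    b2 = seq[i - 2]
    if b2 == "C":
        return "X"
    if b2 == "N":
        return None
    return "H"


_CIGAR_OPS = "MIDNSHP=X"


def parse_cigar(cigar: str) -> List[Tuple[str, int]]:
    ops: List[Tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS:
            ops.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"bad CIGAR {cigar!r}")
    return ops


def assign_methylation(
    chosen: CandidateAlignment,
    original_seq: str,
    genome: GenomeSequence,
) -> str:
    """Per-base methylation string for one aligned read.

    ``original_seq`` is the unconverted read in sequencing orientation; it is
    reverse-complemented here when the alignment is on the reverse strand so
    the string is positionally parallel to the SAM-stored sequence.
    """
    xg = STRAND_TAGS[chosen.strand][0]
    seq = revcomp(original_seq) if chosen.is_reverse else original_seq
    ref = genome[chosen.chrom]
    reflen = len(ref)
    ops = parse_cigar(chosen.cigar)
    q = 0
    r = chosen.pos
    if r < 0:
        raise ValueError("alignment before contig start")
    out: List[str] = []
    for op, length in ops:
        if op in "M=X":
            if r + length > reflen:
                raise ValueError("alignment beyond contig end")
            for k in range(length):
                out.append(_call_base(seq[q + k], ref, r + k, xg))
            q += length
            r += length
        elif op in "IS":
            out.extend("." * length)
            q += length
        elif op in "DN":
            r += length
        elif op == "H":
            pass
        elif op == "P":
            pass
    if len(out) != len(seq):
        raise ValueError("CIGAR does not span the read")
    return "".join(out)


def _call_base(read_base: str, ref: str, rpos: int, xg: str) -> str:
    if xg == "CT":
        if ref[rpos] != "C":
            return "."
        ctx = _context_top(ref, rpos)
        if ctx is None:
            return "."
        if read_base == "C":
            return ctx
        if read_base == "T":
            return ctx.lower()
        return "."  # mismatch: not applicable
    else:
        if ref[rpos] != "G":
            return "."
        ctx = _context_bottom(ref, rpos)
        if ctx is None:
            return "."
        if read_base == "G":
            return ctx
        if read_base == "A":
            return ctx.lower()
        return "."
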