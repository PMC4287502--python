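"""Numba JIT kernels for the built-in exhaustive aligner.

The scan enumerates every ungapped placement of a read on a contig and keeps
those whose (negative) alignment score clears the minimum valid score.  A
branch-and-bound cut prunes a placement as soon as its accumulated penalty
exceeds the threshold, which keeps the scan near-linear in contig length on
random sequence while remaining exact: every placement that could be reported
is fully scored.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: base encoding used throughout: A=0 C=1 G=2 T=3 N=4
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0 C=1 G=2 T=3, other=N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def scan_offsets(genome, read, penalties, n_penalty, max_penalty):
    """Score *read* ungapped at every offset of *genome*.

    Parameters are int8 genome codes, int8 read codes, an int32 per-read-
    position mismatch penalty vector (already quality-scaled), the penalty
    for any comparison involving N, and the largest total penalty still
    considered a valid alignment (floor of -min_score).

    Returns (positions, scores): all offsets whose total penalty is
    <= max_penalty, scores as negative ints, in ascending offset order.
    """
    G = genome.shape[0]
    L = read.shape[0]
    n_out = 0
    cap = G - L + 1
    if cap <= 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    pos = np.empty(cap, dtype=np.int64)
    sc = np.empty(cap, dtype=np.int64)
    for i in range(cap):
        acc = 0
        ok = True
        for j in range(L):
            g = genome[i + j]
            r = read[j]
            if g != r or g == 4:
                if g == 4 or r == 4:
                    acc += n_penalty
                else:
                    acc += penalties[j]
                if acc > max_penalty:
                    ok = False
                    break
        if ok:
            pos[n_out] = i
            sc[n_out] = -acc
            n_out += 1
    return pos[:n_out].copy(), sc[:n_out].copy()


@njit(cache=True)
def score_at_offsets(genome, read, penalties, n_penalty, max_penalty, offsets):
    """Score the read at the given offsets only.

    Returns scores parallel to *offsets*; entries above 0 (sentinel 1) mark
    placements whose penalty exceeded max_penalty.
    """
    L = read.shape[0]
    out = np.empty(offsets.shape[0], dtype=np.int64)
    for idx in range(offsets.shape[0]):
        i = offsets[idx]
        acc = 0
        ok = True
        for j in range(L):
            g = genome[i + j]
            r = read[j]
            if g != r or g == 4:
                if g == 4 or r == 4:
                    acc += n_penalty
                else:
                    acc += penalties[j]
                if acc > max_penalty:
                    ok = False
                    break
        out[idx] = -acc if ok else 1
    return out
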