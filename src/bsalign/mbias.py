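"""M-bias quality control: per-read-position CpG methylation by strand/mate.

Reliable libraries show near-constant methylation across read positions;
end-repair and quality decay commonly distort the 5' and/or 3' ends.  The
per-position CpG methylation fraction is tallied separately per originating
strand (OT/OB/CTOT/CTOB) and per mate, using exactly the record/call filters
of the methylation extractor, and an inclusion window is suggested per
stratum for use as extraction trim bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Dict, List, Optional, Tuple

import pysam

from .calls import iter_calls, record_mate, record_passes, record_strand
from .filters import FilterConfig, TrimBounds

StratumKey = Tuple[str, int]  # (strand, mate)


@dataclass
class MbiasMatrix:
    """CpG tallies: (strand, mate) -> {read position (1-based): [m, u]}."""

    tallies: Dict[StratumKey, Dict[int, List[int]]] = field(default_factory=dict)

    def add(self, strand: str, mate: int, pos: int, methylated: bool) -> None:
        stratum = self.tallies.setdefault((strand, mate), {})
        cell = stratum.setdefault(pos, [0, 0])
        cell[0 if methylated else 1] += 1

    def strata(self) -> List[StratumKey]:
        return sorted(self.tallies)

    def percent(self, strand: str, mate: int) -> Dict[int, float]:
        out = {}
        for pos, (m, u) in sorted(self.tallies.get((strand, mate), {}).items()):
            if m + u:
                out[pos] = 100.0 * m / (m + u)
        return out

    def total_calls(self) -> int:
        return sum(
            m + u for s in self.tallies.values() for m, u in s.values()
        )

    def max_position(self) -> int:
        return max(
            (p for s in self.tallies.values() for p in s), default=0
        )


def compute_mbias(
    bam: str | Path, filters: FilterConfig = FilterConfig()
) -> MbiasMatrix:
    """Per-position CpG methylation tallies stratified by strand and mate.

    Record and call filtering is identical to the methylation extractor
    (MAPQ, Phred); trim bounds are deliberately not applied — the matrix is
    what trims are derived from.
    """
    matrix = MbiasMatrix()
    with pysam.AlignmentFile(str(bam), check_sq=False) as af:
        for rec in af:
            if not record_passes(rec, filters.min_mapq):
                continue
            strand = record_strand(rec)
            mate = record_mate(rec)
            for call in iter_calls(rec):
                if call.symbol not in "Zz":
                    continue
                if call.phred < filters.min_phred:
                    continue
                matrix.add(strand, mate, call.read_pos, call.symbol == "Z")
    return matrix


def suggest_bounds(
    matrix: MbiasMatrix,
    tolerance_pct: float = 2.0,
    min_positions: int = 5,
) -> TrimBounds:
    """Suggest per-stratum inclusion windows from the M-bias matrix.

    Per stratum the reference level is the median per-position methylation
    over the central 50% of covered positions; the suggested window is the
    longest contiguous run of positions within ``tolerance_pct`` of it
    (zero-coverage positions inside the read are neutral and do not break a
    run).  A stratum without coverage gets full-length bounds and a warning.
    """
    bounds = TrimBounds()
    full_len = max(1, matrix.max_position())
    for strand, mate in matrix.strata():
        pct = matrix.percent(strand, mate)
        if len(pct) < min_positions:
            warnings.warn(
                f"stratum ({strand}, mate {mate}) has coverage at fewer than "
                f"{min_positions} positions; using full-length bounds"
            )
            bounds.set(strand, mate, 1, full_len)
            continue
        positions = sorted(pct)
        lo_q = len(positions) // 4
        hi_q = len(positions) - lo_q
        central = positions[lo_q:hi_q]
        m = median(pct[p] for p in central)

        last = positions[-1]
        ok = [
            (p not in pct) or (abs(pct[p] - m) <= tolerance_pct)
            for p in range(1, last + 1)
        ]
        best = _longest_true_run(ok)
        if best is None:
            bounds.set(strand, mate, 1, last)
        else:
            bounds.set(strand, mate, best[0] + 1, best[1] + 1)
    return bounds


def _longest_true_run(ok: List[bool]) -> Optional[Tuple[int, int]]:
    """(start, end) inclusive 0-based indices of the longest True run."""
    best = None
    start = None
    for i, v in enumerate(ok + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    return best


def write_mbias_tsv(matrix: MbiasMatrix, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("strand\tmate\tposition\tn_meth\tn_unmeth\tpercent\n")
        for strand, mate in matrix.strata():
            for pos, (m, u) in sorted(matrix.tallies[(strand, mate)].items()):
                pct = 100.0 * m / (m + u) if m + u else float("nan")
                fh.write(f"{strand}\t{mate}\t{pos}\t{m}\t{u}\t{pct:.4f}\n")
    return path


def plot_mbias(
    matrix: MbiasMatrix,
    bounds: Optional[TrimBounds] = None,
    out_prefix: str | Path = "mbias",
    fmt: str = "png",
) -> List[Path]:
    """One panel per strand, mates as separate series, bounds as vertical
    lines.  Also writes the underlying table as TSV.  Returns written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strands = sorted({s for s, _m in matrix.strata()})
    written: List[Path] = []
    if not strands:
        warnings.warn("empty M-bias matrix; no plot produced")
        return written
    fig, axes = plt.subplots(
        1, len(strands), figsize=(5 * len(strands), 4), squeeze=False
    )
    colors = {1: "tab:red", 2: "tab:blue"}
    for ax, strand in zip(axes[0], strands):
        for mate in (1, 2):
            pct = matrix.percent(strand, mate)
            if not pct:
                continue
            xs = sorted(pct)
            ax.plot(xs, [pct[x] for x in xs], color=colors[mate],
                    label=f"mate {mate}")
            if bounds is not None:
                b = bounds.get(strand, mate)
                if b:
                    ax.axvline(b[0], color=colors[mate], ls="--", lw=0.8)
                    ax.axvline(b[1], color=colors[mate], ls="--", lw=0.8)
        ax.set_title(strand)
        ax.set_xlabel("read position")
        ax.set_ylabel("% CpG methylation")
        ax.set_ylim(0, 100)
        ax.legend()
    fig.tight_layout()
    img = Path(f"{out_prefix}.{fmt}")
    fig.savefig(img)
    plt.close(fig)
    written.append(img)
    written.append(write_mbias_tsv(matrix, f"{out_prefix}.tsv"))
    return written
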