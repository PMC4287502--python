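"""Shared fixtures: synthetic genomes and hand-built SAM records."""

from __future__ import annotations

import random
from pathlib import Path

import pysam
import pytest

from bsalign import GenomeSequence


def random_genome(seed: int, sizes: dict[str, int]) -> GenomeSequence:
    rng = random.Random(seed)
    return GenomeSequence(
        {n: "".join(rng.choice("ACGT") for _ in range(sz)) for n, sz in sizes.items()}
    )


@pytest.fixture(scope="session")
def small_genome() -> GenomeSequence:
    """10 kb single-contig random genome used across backend/aligner tests."""
    return random_genome(11, {"chr1": 10000})


@pytest.fixture(scope="session")
def two_contig_genome() -> GenomeSequence:
    return random_genome(13, {"chrA": 6000, "chrB": 4000})


def sam_text(genome: GenomeSequence, body_lines: list[str]) -> str:
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{n}\tLN:{len(s)}" for n, s in genome.items()]
    return "\n".join(header + body_lines) + "\n"


def write_sam(tmp_path: Path, genome: GenomeSequence, body_lines: list[str],
              name: str = "test.sam") -> Path:
    path = tmp_path / name
    path.write_text(sam_text(genome, body_lines))
    return path


def sam_line(
    qname: str,
    flag: int,
    chrom: str,
    pos1: int,
    mapq: int,
    cigar: str,
    seq: str,
    qual: str,
    xm: str,
    xg: str = "CT",
    xr: str = "CT",
    rnext: str = "*",
    pnext: int = 0,
    tlen: int = 0,
    extra: str = "",
) -> str:
    line = (
        f"{qname}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t{rnext}\t{pnext}"
        f"\t{tlen}\t{seq}\t{qual}\tXM:Z:{xm}\tXG:Z:{xg}\tXR:Z:{xr}"
    )
    if extra:
        line += "\t" + extra
    return line
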