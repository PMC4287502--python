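"""Pipeline orchestration: index -> align -> markdup -> mbias -> extract.

Stages are plain library calls glued together with a manifest and per-stage
record counts; any stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .aligner import align_to_bam
from .convert import BsRead, Protocol, convert_genome
from .backend import ScoringScheme
from .dedup import mark_duplicates
from .extract import (
    FilterConfig,
    coverage_metrics,
    extract_methylation,
    merge_cpg,
    write_all_bedgraphs,
    write_bedgraph,
)
from .genome import GenomeSequence, revcomp
from .mbias import compute_mbias, plot_mbias, suggest_bounds, write_mbias_tsv
from .seqio import read_fastq, read_fastq_pairs

logger = logging.getLogger("bsalign")


@dataclass
class PipelineConfig:
    """Serializable configuration for a full pipeline run."""

    genome: str = ""
    reads1: str = ""
    reads2: Optional[str] = None
    out_dir: str = "bsalign_out"
    directionality: str = "directional"
    min_mapq: int = 10
    min_phred: int = 5
    backend: str = "builtin"
    threads: int = 1
    seed: int = 1
    merge_cpg: bool = True
    apply_suggested_trims: bool = False

    @property
    def protocol(self) -> Protocol:
        pairing = "paired" if self.reads2 else "single"
        return Protocol(directionality=self.directionality, pairing=pairing)  # type: ignore[arg-type]

    @property
    def filters(self) -> FilterConfig:
        return FilterConfig(min_mapq=self.min_mapq, min_phred=self.min_phred)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Writes a ``manifest.json`` listing every produced file with checksums
    plus per-stage record counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {"files": {}, "stages": {}}
    files: Dict[str, str] = manifest["files"]  # type: ignore[assignment]

    if not Path(config.genome).exists():
        raise StageError("validate", FileNotFoundError(config.genome))
    if not Path(config.reads1).exists():
        raise StageError("validate", FileNotFoundError(config.reads1))
    if config.reads2 and not Path(config.reads2).exists():
        raise StageError("validate", FileNotFoundError(config.reads2))

    try:
        genome = GenomeSequence.from_fasta(config.genome)
    except Exception as e:  # noqa: BLE001
        raise StageError("index", e)

    # ------------------------------------------------------------------ align
    bam = out / "alignments.bam"
    try:
        paired = config.reads2 is not None
        if paired:
            reads = read_fastq_pairs(config.reads1, config.reads2)  # type: ignore[arg-type]
        else:
            reads = read_fastq(config.reads1)
        stats = align_to_bam(
            genome,
            reads,
            bam,
            protocol=config.protocol,
            paired=paired,
            unmapped_fastq=str(out / "unmapped"),
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("align", e)
    logger.info(
        "align: %d units, %d aligned (%.2f%%)",
        stats.n_total, stats.n_aligned, stats.pct_aligned,
    )
    manifest["stages"]["align"] = {  # type: ignore[index]
        "n_total": stats.n_total,
        "n_aligned": stats.n_aligned,
        "pct_aligned": stats.pct_aligned,
    }
    files["alignments.bam"] = _checksum(bam)

    # ---------------------------------------------------------------- markdup
    deduped = out / "alignments.markdup.bam"
    try:
        n_units, n_marked = mark_duplicates(bam, deduped)
    except Exception as e:  # noqa: BLE001
        raise StageError("markdup", e)
    logger.info("markdup: %d units, %d marked", n_units, n_marked)
    manifest["stages"]["markdup"] = {"n_units": n_units, "n_marked": n_marked}  # type: ignore[index]
    files["alignments.markdup.bam"] = _checksum(deduped)

    # ------------------------------------------------------------------ mbias
    try:
        matrix = compute_mbias(deduped, config.filters)
        bounds = suggest_bounds(matrix)
        write_mbias_tsv(matrix, out / "mbias.tsv")
        if matrix.strata():
            plot_mbias(matrix, bounds, out / "mbias")
    except Exception as e:  # noqa: BLE001
        raise StageError("mbias", e)
    files["mbias.tsv"] = _checksum(out / "mbias.tsv")
    manifest["stages"]["mbias"] = {  # type: ignore[index]
        "bounds": {f"{s}/{m}": list(b) for (s, m), b in bounds.bounds.items()}
    }

    # ---------------------------------------------------------------- extract
    try:
        filters = config.filters
        if config.apply_suggested_trims:
            filters.trims = bounds
        counts = extract_methylation(deduped, genome, filters)
        paths = write_all_bedgraphs(counts, out / "methylation")
        if config.merge_cpg:
            merged = merge_cpg(counts.restrict("CpG"), genome)
            write_bedgraph(merged, "CpG", out / "methylation_CpG.merged.bedGraph")
            paths["CpG_merged"] = out / "methylation_CpG.merged.bedGraph"
        cov = coverage_metrics(counts)
    except Exception as e:  # noqa: BLE001
        raise StageError("extract", e)
    for p in paths.values():
        files[Path(p).name] = _checksum(Path(p))
    manifest["stages"]["extract"] = {  # type: ignore[index]
        "n_calls": counts.total_calls(),
        "n_sites": len(counts),
        "cpg_coverage": cov,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


# ---------------------------------------------------------------------fixtures
def _random_genome(rng: random.Random, sizes: Dict[str, int]) -> GenomeSequence:
    return GenomeSequence(
        {
            name: "".join(rng.choice("ACGT") for _ in range(n))
            for name, n in sizes.items()
        }
    )


def make_fixtures(seed: int, out_dir: str | Path) -> Dict[str, Path]:
    """Write a deterministic fixture bundle for tests and demos.

    Contents: a 3-contig synthetic genome (~40 kb), directional and
    non-directional FASTQ sets with truth-encoded names, and a hand-crafted
    SAM exercising edge cases (overlapping mates, N bases, soft clips,
    duplicate trios with distinct Phred sums).  All files are text.
    """
    from .simeval import SimulationConfig, simulate

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    genome = _random_genome(
        rng, {"chr1": 20000, "chr2": 12000, "chr3": 8000}
    )
    paths: Dict[str, Path] = {}
    paths["genome"] = genome.to_fasta(out / "genome.fa")

    cfg = SimulationConfig(
        n_fragments=400, pairing="paired", seed=seed % (2**31)
    )
    for f in simulate(genome, cfg, out / "directional"):
        paths[f.name] = f
    cfg_nd = SimulationConfig(
        n_fragments=400,
        pairing="paired",
        directionality="non-directional",
        seed=(seed + 1) % (2**31),
    )
    for f in simulate(genome, cfg_nd, out / "nondirectional"):
        paths[f.name] = f

    sam = out / "edge_cases.sam"
    sam.write_text(edge_case_sam(genome))
    paths["edge_cases.sam"] = sam

    checksums = {k: _checksum(p) for k, p in paths.items()}
    with open(out / "fixtures.json", "w") as fh:
        json.dump(checksums, fh, indent=2, sort_keys=True)
    paths["fixtures.json"] = out / "fixtures.json"
    return paths


def edge_case_sam(genome: GenomeSequence) -> str:
    """Hand-crafted SAM text with overlap/N/soft-clip/duplicate edge cases.

    Built against the first contig; requires it to contain a CpG within the
    first 200 bases (true with overwhelming probability for random 20 kb).
    """
    chrom = genome.names[0]
    seq = genome[chrom]
    cpg = seq.find("CG", 50, 5000)
    if cpg < 0:
        raise ValueError("fixture contig unexpectedly CpG-free")
    start = cpg - 10  # 0-based; read of 30 covers the CpG at offset 10
    read = seq[start : start + 30]
    # methylated version: read matches genome exactly at the CpG C
    xm = "".join(
        _xm_char(seq, start + i) for i in range(30)
    )
    unmeth_read = read[:10] + "T" + read[11:]
    unmeth_xm = xm[:10] + xm[10].lower() + xm[11:]
    q40 = "I" * 30
    q30 = "?" * 30
    q20 = "5" * 30
    pos1 = start + 1
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
    ]
    lines += [f"@SQ\tSN:{n}\tLN:{len(s)}" for n, s in genome.items()]

    def rec(name, flag, pos, mapq, cigar, seq_, qual, xm_, xg="CT", xr="CT",
            rnext="*", pnext=0, tlen=0):
        return (
            f"{name}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t{rnext}\t"
            f"{pnext}\t{tlen}\t{seq_}\t{qual}\tXM:Z:{xm_}\tXG:Z:{xg}\tXR:Z:{xr}"
        )

    # duplicate trio at identical positions, distinct Phred sums
    lines.append(rec("dup_a", 0, pos1, 40, "30M", read, q40, xm))
    lines.append(rec("dup_b", 0, pos1, 40, "30M", read, q30, xm))
    lines.append(rec("dup_c", 0, pos1, 40, "30M", read, q20, xm))
    # position-identical but methylation-discordant read (never a duplicate)
    lines.append(rec("discord", 0, pos1, 40, "30M", unmeth_read, q40, unmeth_xm))
    # soft-clipped copy of dup_a's locus: 5S25M starting 5 later, same 5' coord
    lines.append(
        rec("clipped", 0, pos1 + 5, 40, "5S25M", read, q30, "....." + xm[5:])
    )
    # read with an N at the CpG (no call there)
    n_read = read[:10] + "N" + read[11:]
    lines.append(rec("n_read", 0, pos1, 40, "30M", n_read, q40,
                     xm[:10] + "." + xm[11:]))
    # fully overlapping proper pair (both mates span the same window)
    lines.append(
        rec("pair_full", 0x63, pos1, 40, "30M", read, q40, xm,
            rnext="=", pnext=pos1, tlen=30)
    )
    # SAM stores reverse-strand SEQ in reference orientation, so mate 2's
    # stored sequence and XM match the forward window
    lines.append(
        rec("pair_full", 0x93, pos1, 40, "30M", read, q40,
            xm, xg="CT", xr="GA", rnext="=", pnext=pos1, tlen=-30)
    )
    return "\n".join(lines) + "\n"


def _xm_char(seq: str, i: int) -> str:
    from .arbitrate import _context_top

    if seq[i] != "C":
        return "."
    ctx = _context_top(seq, i)
    return ctx if ctx else "."
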