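"""In-silico bisulfite conversion of genomes and reads.

Three-letter alignment removes methylation-dependent mapping bias by aligning
C->T (or G->A) converted reads against similarly converted references.  Two
converted copies of the genome are kept: a C->T copy (for reads deriving from
the original top strand, OT, and its PCR complement CTOT) and a G->A copy
(for the original bottom strand, OB, and CTOB).  Directional libraries
sequence only OT and OB; non-directional libraries additionally sequence the
PCR-generated complementary strands CTOT and CTOB.

Also provided: in-silico restriction digestion producing a
reduced-representation (RRBS) genome, defaulting to MspI (C^CGG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Tuple

from .genome import GenomeSequence, revcomp

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")

Strand = Literal["OT", "OB", "CTOT", "CTOB"]

#: strands searched for each library type
DIRECTIONAL_STRANDS: Tuple[Strand, ...] = ("OT", "OB")
NON_DIRECTIONAL_STRANDS: Tuple[Strand, ...] = ("OT", "OB", "CTOT", "CTOB")


def ct_convert(seq: str) -> str:
    """Replace every C with T."""
    return seq.translate(_CT)


def ga_convert(seq: str) -> str:
    """Replace every G with A."""
    return seq.translate(_GA)


@dataclass
class ConvertedGenomePair:
    """The two in-silico converted references plus the unconverted source.

    ``source`` is retained because methylation context (CpG/CHG/CHH) must be
    read from the unconverted bases, never from a converted copy.
    """

    ct_genome: GenomeSequence
    ga_genome: GenomeSequence
    source: GenomeSequence


def convert_genome(genome: GenomeSequence) -> ConvertedGenomePair:
    """Create the C->T and G->A converted copies of *genome*.

    N bases are preserved; contig names and lengths are unchanged.
    """
    if len(genome) == 0:
        raise ValueError("cannot convert an empty genome")
    ct = GenomeSequence({n: ct_convert(s) for n, s in genome.items()})
    ga = GenomeSequence({n: ga_convert(s) for n, s in genome.items()})
    return ConvertedGenomePair(ct_genome=ct, ga_genome=ga, source=genome)


def reduce_genome_rrbs(
    genome: GenomeSequence,
    site: str = "CCGG",
    cut_offset: int = 1,
    min_frag: int = 40,
    max_frag: int = 600,
) -> GenomeSequence:
    """In-silico restriction digestion for reduced-representation libraries.

    Every occurrence of *site* is cut at ``cut_offset`` bases into the motif
    (MspI, C^CGG, cuts after the first base).  Fragments lying between two
    consecutive cut positions whose length falls within
    ``[min_frag, max_frag]`` are retained, each as a contig named
    ``<chrom>:<start>-<end>`` (0-based half-open, original coordinates).
    A genome with no site yields an empty result.
    """
    if not site or any(c not in "ACGT" for c in site):
        raise ValueError(f"invalid restriction site {site!r}")
    if not (0 <= cut_offset <= len(site)):
        raise ValueError("cut_offset must lie within the site motif")
    if not (0 < min_frag <= max_frag):
        raise ValueError("require 0 < min_frag <= max_frag")

    out: Dict[str, str] = {}
    for name, seq in genome.items():
        cuts: List[int] = []
        start = 0
        while True:
            i = seq.find(site, start)
            if i < 0:
                break
            cuts.append(i + cut_offset)
            start = i + 1
        for a, b in zip(cuts, cuts[1:]):
            if min_frag <= b - a <= max_frag:
                out[f"{name}:{a}-{b}"] = seq[a:b]
    return GenomeSequence(out)


@dataclass
class BsRead:
    """One sequencing read with its original (unconverted) sequence."""

    name: str
    seq: str
    quals: str
    mate: int = 0  # 1, 2 or 0 (single-end)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.name!r}: sequence and quality lengths differ"
            )


@dataclass
class Protocol:
    """Library protocol: directionality and pairing."""

    directionality: Literal["directional", "non-directional"] = "directional"
    pairing: Literal["single", "paired"] = "single"

    @property
    def strands(self) -> Tuple[Strand, ...]:
        if self.directionality == "directional":
            return DIRECTIONAL_STRANDS
        return NON_DIRECTIONAL_STRANDS


#: per-strand dispatch: (read1 conversion, read2 conversion,
#: target genome, read1 orientation constraint)
#: orientation "forward" means read1 aligns as given; "revcomp" means read1
#: aligns as its reverse complement.
_DISPATCH: Dict[Strand, Tuple[str, str, str, str]] = {
    "OT": ("CT", "GA", "ct", "forward"),
    "OB": ("CT", "GA", "ga", "revcomp"),
    "CTOT": ("GA", "CT", "ct", "revcomp"),
    "CTOB": ("GA", "CT", "ga", "forward"),
}

_CONVERTERS = {"CT": ct_convert, "GA": ga_convert}


@dataclass
class DispatchEntry:
    """One strand-constrained alignment task produced by read conversion.

    ``read1``/``read2`` are the *converted* variants; the unconverted
    originals travel alongside so downstream methylation calling always sees
    the true base composition.
    """

    strand: Strand
    target_genome: Literal["ct", "ga"]
    orientation: Literal["forward", "revcomp"]
    read1: BsRead
    read2: Optional[BsRead]
    original1: BsRead
    original2: Optional[BsRead]
    read1_conversion: Literal["CT", "GA"] = "CT"


def convert_reads(
    read1: BsRead,
    read2: Optional[BsRead] = None,
    protocol: Protocol = Protocol(),
) -> List[DispatchEntry]:
    """Produce one converted alignment task per searchable strand.

    Directional libraries yield 2 entries (OT, OB); non-directional yield 4
    (plus CTOT, CTOB).  Read conversion per strand: read1 is C->T converted
    for OT/OB and G->A converted for CTOT/CTOB; read2 (when paired) always
    carries the complementary conversion.  Originals are preserved verbatim.
    """
    if not read1.seq:
        raise ValueError("empty read")
    if read2 is not None and not read2.seq:
        raise ValueError("empty mate")

    entries: List[DispatchEntry] = []
    for strand in protocol.strands:
        conv1, conv2, target, orient = _DISPATCH[strand]
        c1 = BsRead(read1.name, _CONVERTERS[conv1](read1.seq), read1.quals, 1)
        c2 = None
        if read2 is not None:
            c2 = BsRead(read2.name, _CONVERTERS[conv2](read2.seq), read2.quals, 2)
        entries.append(
            DispatchEntry(
                strand=strand,
                target_genome=target,  # type: ignore[arg-type]
                orientation=orient,  # type: ignore[arg-type]
                read1=c1,
                read2=c2,
                original1=read1,
                original2=read2,
                read1_conversion=conv1,  # type: ignore[arg-type]
            )
        )
    return entries
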