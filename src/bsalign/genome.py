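"""Reference-genome container and FASTA I/O.

Coordinates are 0-based internally; the SAM/bedGraph writers convert at the
boundary. Sequences are held uppercase over the alphabet {A, C, G, T, N};
soft-masking (lowercase) in input FASTA is uppercased and ignored.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Tuple

_VALID = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidSequenceError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


def _validate(name: str, seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise InvalidSequenceError(
                f"contig {name!r}: invalid character {ch!r} at position {i}"
            )


@dataclass
class GenomeSequence:
    """An ordered collection of named contigs.

    Parameters
    ----------
    contigs
        Ordered mapping of contig name to uppercase DNA sequence.
    """

    contigs: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: Dict[str, str] = {}
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            seq = seq.upper()
            _validate(name, seq)
            cleaned[name] = seq
        self.contigs = cleaned

    # -- mapping-ish conveniences -------------------------------------------------
    def __len__(self) -> int:
        return len(self.contigs)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def items(self) -> Iterator[Tuple[str, str]]:
        return iter(self.contigs.items())

    @property
    def names(self):
        return list(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    # -- I/O ------------------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        """Load a (possibly gzipped) multi-contig FASTA file."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        contigs: Dict[str, str] = {}
        name = None
        chunks: list[str] = []
        with opener(path, "rt") as fh:
            for line in fh:
                line = line.rstrip()
                if not line:
                    continue
                if line.startswith(">"):
                    if name is not None:
                        contigs[name] = "".join(chunks)
                    name = line[1:].split()[0]
                    chunks = []
                else:
                    chunks.append(line)
            if name is not None:
                contigs[name] = "".join(chunks)
        if not contigs:
            raise ValueError(f"no sequences found in {path}")
        return cls(contigs)

    def to_fasta(self, path: str | Path, width: int = 70) -> Path:
        """Write contigs as wrapped FASTA; returns the path written."""
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path
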