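"""Record- and call-level filters shared by extraction, M-bias and dedup."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

#: (strand, mate) -> inclusive 1-based read-position bounds
BoundsMap = Dict[Tuple[str, int], Tuple[int, int]]


@dataclass
class TrimBounds:
    """Per-(strand, mate) inclusive read-position window to keep.

    Positions are 1-based from the sequencing 5' end of the read; calls
    outside the window are ignored during extraction.
    """

    bounds: BoundsMap = field(default_factory=dict)

    def get(self, strand: str, mate: int) -> Optional[Tuple[int, int]]:
        return self.bounds.get((strand, mate))

    def keeps(self, strand: str, mate: int, read_pos: int) -> bool:
        b = self.get(strand, mate)
        if b is None:
            return True
        return b[0] <= read_pos <= b[1]

    def set(self, strand: str, mate: int, start: int, end: int) -> None:
        if not (1 <= start <= end):
            raise ValueError("require 1 <= start <= end")
        self.bounds[(strand, mate)] = (start, end)


@dataclass
class FilterConfig:
    """Extraction filters: defaults are MAPQ >= 10 and Phred >= 5."""

    min_mapq: int = 10
    min_phred: int = 5
    trims: Optional[TrimBounds] = None
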