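"""Gzip-transparent FASTQ reading and writing."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator, Optional, Tuple

from .convert import BsRead


def _opener(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path, mate: int = 0) -> Iterator[BsRead]:
    """Iterate records of a (possibly gzipped) FASTQ file."""
    path = Path(path)
    with _opener(path, "r") as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                return
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ header {header!r}")
            seq = fh.readline().rstrip()
            plus = fh.readline().rstrip()
            quals = fh.readline().rstrip()
            if not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ separator for {header!r}")
            name = header[1:].split()[0]
            # strip mate suffixes like /1, /2
            if name.endswith("/1") or name.endswith("/2"):
                name = name[:-2]
            yield BsRead(name, seq.upper(), quals, mate)


def read_fastq_pairs(
    path1: str | Path, path2: str | Path
) -> Iterator[Tuple[BsRead, BsRead]]:
    it1 = read_fastq(path1, mate=1)
    it2 = read_fastq(path2, mate=2)
    for r1 in it1:
        try:
            r2 = next(it2)
        except StopIteration:
            raise ValueError("mate files have unequal record counts") from None
        yield r1, r2
    if next(it2, None) is not None:
        raise ValueError("mate files have unequal record counts")


class FastqWriter:
    """Write FASTQ records, gzip-compressed if the path ends in .gz.

    Gzip streams are written with a fixed header timestamp so identical
    content produces byte-identical files across runs.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if str(self.path).endswith(".gz"):
            import io

            raw = open(self.path, "wb")
            self._fh = io.TextIOWrapper(
                gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0),
                encoding="ascii",
            )
            self._raw = raw
        else:
            self._fh = open(self.path, "w")

    def write(self, read: BsRead, suffix: str = "") -> None:
        self._fh.write(f"@{read.name}{suffix}\n{read.seq}\n+\n{read.quals}\n")

    def close(self) -> None:
        self._fh.close()
        raw = getattr(self, "_raw", None)
        if raw is not None and not raw.closed:
            raw.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
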