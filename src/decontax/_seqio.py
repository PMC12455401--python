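"""Internal FASTA/FASTQ(.gz) helpers shared by the classifier and filter modules.

Gzip is detected by magic bytes, never by file extension, and writers mirror
the compression of their inputs.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

GZIP_MAGIC = b"\x1f\x8b"

_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def is_gzipped(path: str | Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


def open_text(path: str | Path, mode: str = "rt", *, compress: bool | None = None) -> IO[str]:
    """Open possibly-gzipped text. Reads sniff magic bytes; writes follow ``compress``."""
    if "r" in mode:
        if is_gzipped(path):
            return gzip.open(path, mode)
        return open(path, mode)
    if compress:
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) tuples; title is the header without '@'."""
    with open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq_record(fh: IO[str], title: str, seq: str, qual: str) -> None:
    fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
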