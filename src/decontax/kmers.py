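"""bbduk-style exact canonical k-mer membership classification.

A reference FASTA (e.g. the host genome) is decomposed into its set of
canonical k-mers — the lexicographic minimum of each length-k window and its
reverse complement, so both strands collapse to one entry. A read hits the
index if at least one of its windows, canonicalized the same way, is in the
set; a read pair is labeled when either mate hits. Windows containing
non-ACGT characters are skipped on both the reference and the read side,
and matching is case-insensitive.

The default k of 27 matches the common host-decontamination setting. Exact
membership only: no mismatch neighborhoods and no middle-base masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from Bio import SeqIO

from ._seqio import open_text, read_fastq, revcomp
from .errors import FormatError, PairingError
from .filtering import LabelSet, normalize_id

__all__ = ["KmerIndex", "canonical", "build_index", "classify_read", "label_fastq"]

DEFAULT_K = 27

_VALID = frozenset("ACGT")


def canonical(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement (A<C<G<T)."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _iter_canonical(seq: str, k: int) -> Iterable[str]:
    """Canonical k-mers of every valid window of ``seq`` (upper-cased)."""
    seq = seq.upper()
    # track the last position holding a non-ACGT char so invalid windows skip in O(1)
    last_bad = -1
    for i, base in enumerate(seq):
        if base not in _VALID:
            last_bad = i
        start = i - k + 1
        if start >= 0 and last_bad < start:
            yield canonical(seq[start : i + 1])


@dataclass
class KmerIndex:
    """Set of canonical k-mers drawn from a reference FASTA."""

    k: int
    kmers: set[str] = field(default_factory=set)
    source: str = ""

    def __len__(self) -> int:
        return len(self.kmers)


def build_index(
    reference: Union[str, Path, IO[str]],
    k: int = DEFAULT_K,
    source: str | None = None,
) -> KmerIndex:
    """Index every canonical length-k window of every FASTA record.

    Multi-record and line-wrapped FASTA are handled; lower-case (masked)
    reference stretches are folded to upper case rather than skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(reference, (str, Path)):
        label = str(reference)
        with open_text(reference) as fh:
            return build_index(fh, k=k, source=source or label)
    kmers: set[str] = set()
    n_records = 0
    for record in SeqIO.parse(reference, "fasta"):
        n_records += 1
        kmers.update(_iter_canonical(str(record.seq), k))
    if n_records == 0:
        raise FormatError("reference FASTA contains no records")
    return KmerIndex(k=k, kmers=kmers, source=source or "")


def classify_read(index: KmerIndex, sequence: str) -> bool:
    """True iff at least one valid window of the read is in the index.

    Reads shorter than k can never hit.
    """
    for km in _iter_canonical(sequence, index.k):
        if km in index.kmers:
            return True
    return False


def label_fastq(
    index: KmerIndex,
    r1: str | Path,
    r2: Optional[str | Path] = None,
    sample: str = "",
) -> LabelSet:
    """Label read pairs sharing at least one k-mer with the reference.

    Paired inputs must be mate-synchronized; a count or ID mismatch after
    normalization raises :class:`PairingError`.
    """
    ids: set[str] = set()
    if r2 is None:
        for title, seq, _qual in read_fastq(r1):
            if classify_read(index, seq):
                ids.add(normalize_id(title))
        return LabelSet(sample=sample, tool="kmer_classifier", ids=ids)

    it1, it2 = read_fastq(r1), read_fastq(r2)
    sentinel = object()
    n = 0
    while True:
        a = next(it1, sentinel)
        b = next(it2, sentinel)
        if a is sentinel and b is sentinel:
            break
        if a is sentinel or b is sentinel:
            short = "r1" if a is sentinel else "r2"
            raise PairingError(f"mate files out of sync: {short} ended after {n} records")
        n += 1
        ida, idb = normalize_id(a[0]), normalize_id(b[0])
        if ida != idb:
            raise PairingError(f"mate ID mismatch at record {n}: {ida!r} vs {idb!r}")
        if classify_read(index, a[1]) or classify_read(index, b[1]):
            ids.add(ida)
    return LabelSet(sample=sample, tool="kmer_classifier", ids=ids)
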