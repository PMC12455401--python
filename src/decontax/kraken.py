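"""Three-condition k-mer cutoff model over Kraken2 per-read output.

Kraken2's standard per-read output assigns every k-mer of a read (pair) to a
taxon (the LCA of all genomes containing it), to 0 (unclassified), or marks
it ``A`` (the window spans an ambiguous base). Given a filter target — a
taxon and its whole subtree — the k-mers of a read pair are tallied into

* ``T``: k-mers assigned within the target subtree,
* ``O``: k-mers assigned to any other classified taxon (ancestors of the
  target, e.g. the root, count here: only the subtree is the target),
* ``U``: unclassified k-mers,

and the pair is labeled as contamination iff all three conditions hold:

1. ``T > cutoff_tax2filter``                 (absolute k-mer count),
2. ``T / (O + T) > cutoff_tax2keep``         (target vs. other classified),
3. ``T / (U + T) > cutoff_unclassified``     (target vs. unclassified).

All comparisons are strict, so with every cutoff at 0 a pair is labeled
exactly when at least one k-mer hits the target subtree, and raising any
cutoff can only shrink the labeled set. Mates of a pair are pooled before
the conditions are evaluated; the pair is labeled as a unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from .errors import FormatError
from .filtering import LabelSet, normalize_id
from .taxonomy import TaxonomyTree, resolve_name, subtree

__all__ = [
    "AMBIGUOUS",
    "KrakenReadRecord",
    "KmerTally",
    "ModelCutoffs",
    "parse_kraken_line",
    "read_kraken_output",
    "tally",
    "decide",
    "label_kraken",
]

#: sentinel for k-mers spanning ambiguous (non-ACGT) bases, Kraken2's ``A`` token
AMBIGUOUS = -1

Assignment = int  # taxon ID, 0 = unclassified, AMBIGUOUS = -1


@dataclass(frozen=True)
class KrakenReadRecord:
    """One parsed line of Kraken2 standard per-read output."""

    classified: bool
    read_id: str
    consensus_taxon: int
    lengths: tuple[int, ...]
    kmer_runs: tuple[tuple[tuple[Assignment, int], ...], ...]  # one tuple per mate

    @property
    def paired(self) -> bool:
        return len(self.kmer_runs) == 2


@dataclass(frozen=True)
class KmerTally:
    """T/O/U counts for one read (pair); ambiguous-base k-mers are excluded."""

    t: int
    o: int
    u: int


@dataclass(frozen=True)
class ModelCutoffs:
    """The three thresholds of the labeling model.

    ``cutoff_tax2filter`` is a k-mer count; the other two are ratios in [0, 1].
    The benchmark default is all-zero: label on a single target k-mer.
    """

    cutoff_tax2filter: int = 0
    cutoff_tax2keep: float = 0.0
    cutoff_unclassified: float = 0.0

    def __post_init__(self) -> None:
        if self.cutoff_tax2filter < 0:
            raise ValueError("cutoff_tax2filter must be >= 0")
        if not 0.0 <= self.cutoff_tax2keep <= 1.0:
            raise ValueError("cutoff_tax2keep must be in [0, 1]")
        if not 0.0 <= self.cutoff_unclassified <= 1.0:
            raise ValueError("cutoff_unclassified must be in [0, 1]")


def _parse_token(token: str, line_no: int | None) -> tuple[Assignment, int]:
    where = f" at line {line_no}" if line_no is not None else ""
    head, sep, tail = token.partition(":")
    if not sep:
        raise FormatError(f"malformed k-mer token {token!r}{where}")
    try:
        count = int(tail)
    except ValueError as exc:
        raise FormatError(f"non-integer k-mer count in token {token!r}{where}") from exc
    if count <= 0:
        raise FormatError(f"non-positive k-mer count in token {token!r}{where}")
    if head == "A":
        return AMBIGUOUS, count
    try:
        taxon = int(head)
    except ValueError as exc:
        raise FormatError(f"malformed taxon in k-mer token {token!r}{where}") from exc
    if taxon < 0:
        raise FormatError(f"negative taxon in k-mer token {token!r}{where}")
    return taxon, count


def parse_kraken_line(line: str, line_no: int | None = None) -> KrakenReadRecord:
    """Parse one 5-column Kraken2 standard-output line.

    The 5th column is a space-separated list of ``taxid:count`` tokens with
    ``|:|`` separating the two mates of a pair and ``A`` marking runs of
    k-mers that span ambiguous bases.
    """
    where = f" at line {line_no}" if line_no is not None else ""
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 5:
        raise FormatError(f"expected 5 tab-separated columns, got {len(cols)}{where}")
    flag, read_id, consensus_str, lengths_str, kmer_str = cols
    if flag not in ("C", "U"):
        raise FormatError(f"classification flag must be C or U, got {flag!r}{where}")
    try:
        consensus = int(consensus_str)
        lengths = tuple(int(x) for x in lengths_str.split("|"))
    except ValueError as exc:
        raise FormatError(f"malformed consensus/length column{where}") from exc

    mates: list[list[tuple[Assignment, int]]] = [[]]
    for token in kmer_str.split():
        if token == "|:|":
            if len(mates) == 2:
                raise FormatError(f"more than one mate separator{where}")
            mates.append([])
            continue
        mates[-1].append(_parse_token(token, line_no))
    if len(mates) != len(lengths):
        raise FormatError(
            f"length column lists {len(lengths)} mates but k-mer column has {len(mates)}{where}"
        )
    return KrakenReadRecord(
        classified=flag == "C",
        read_id=read_id,
        consensus_taxon=consensus,
        lengths=lengths,
        kmer_runs=tuple(tuple(m) for m in mates),
    )


def read_kraken_output(source: Union[str, Path, IO[str], Iterable[str]]) -> Iterator[KrakenReadRecord]:
    """Yield records from a Kraken2 per-read output file or line stream."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from read_kraken_output(fh)
        return
    for i, line in enumerate(source, start=1):
        if line.strip():
            yield parse_kraken_line(line, line_no=i)


def tally(record: KrakenReadRecord, target: set[int]) -> KmerTally:
    """Sum a record's k-mer assignments into T/O/U across both mates.

    Ambiguous-base k-mers contribute to none of the three counts.
    """
    t = o = u = 0
    for mate in record.kmer_runs:
        for assignment, count in mate:
            if assignment == AMBIGUOUS:
                continue
            if assignment == 0:
                u += count
            elif assignment in target:
                t += count
            else:
                o += count
    return KmerTally(t=t, o=o, u=u)


def decide(t: KmerTally, c: ModelCutoffs) -> bool:
    """Apply the three cutoff conditions to a tally; all must hold to label."""
    if not t.t > c.cutoff_tax2filter:
        return False
    # t.t > cutoff >= 0 here, so both ratio denominators are positive
    if not t.t / (t.o + t.t) > c.cutoff_tax2keep:
        return False
    if not t.t / (t.u + t.t) > c.cutoff_unclassified:
        return False
    return True


def label_kraken(
    records: Iterable[KrakenReadRecord],
    tree: TaxonomyTree,
    tax2filter: str,
    cutoffs: ModelCutoffs = ModelCutoffs(),
    sample: str = "",
) -> LabelSet:
    """Label every read (pair) whose pooled tally passes the cutoff model.

    ``tax2filter`` is resolved to a taxon ID and expanded to its whole
    subtree; one decision is made per record (mates pooled).
    """
    target = subtree(tree, resolve_name(tree, tax2filter))
    ids = {
        normalize_id(rec.read_id)
        for rec in records
        if decide(tally(rec, target), cutoffs)
    }
    return LabelSet(sample=sample, tool="kraken_model", ids=ids)
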