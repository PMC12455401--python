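"""Label-set merging and paired-FASTQ filtering by read-pair ID.

Each classifier produces a :class:`LabelSet` — the normalized IDs of read
pairs it flags as contamination. When several classifiers run, the union of
their label sets is the final verdict, and filtering removes a pair exactly
when its normalized ID is in that union. Filtering operates at read-pair
granularity: both mates of a labeled pair are removed together, and record
order is preserved in both the kept and the removed output.

ID normalization reconciles the Kraken-side and FASTQ-side spellings of a
read ID: take the token before the first whitespace, drop a leading ``@``,
and strip one trailing ``/1`` or ``/2`` mate suffix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from ._seqio import is_gzipped, open_text, read_fastq, write_fastq_record
from .errors import FormatError, PairingError, UsageError

__all__ = [
    "LabelSet",
    "FilterCounts",
    "normalize_id",
    "merge_labels",
    "filter_fastq",
    "summarize",
    "read_label_set",
    "write_label_set",
]

_MATE_SUFFIX = re.compile(r"/[12]$")


def normalize_id(raw: str) -> str:
    """Normalize a read(-pair) ID; see module docstring for the rules."""
    token = raw.split(None, 1)[0] if raw.strip() else ""
    if token.startswith("@"):
        token = token[1:]
    token = _MATE_SUFFIX.sub("", token, count=1)
    if not token:
        raise FormatError(f"read ID {raw!r} is empty after normalization")
    return token


@dataclass
class LabelSet:
    """Normalized read-pair IDs flagged as contamination by one classifier."""

    sample: str
    tool: str
    ids: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.ids)


def merge_labels(sets: Sequence[LabelSet]) -> LabelSet:
    """Union of the label sets of several classifiers on one sample."""
    if not sets:
        raise UsageError("merge_labels needs at least one label set")
    samples = {s.sample for s in sets}
    if len(samples) > 1:
        raise UsageError(f"cannot merge label sets from different samples: {sorted(samples)}")
    merged: set[str] = set()
    for s in sets:
        merged |= s.ids
    return LabelSet(sample=sets[0].sample, tool="merged", ids=merged)


def write_label_set(labels: LabelSet, path: str | Path) -> None:
    """One normalized ID per line, sorted for byte-stable output."""
    with open(path, "w") as fh:
        for rid in sorted(labels.ids):
            fh.write(rid + "\n")


def read_label_set(path: str | Path, sample: str = "", tool: str = "") -> LabelSet:
    with open(path) as fh:
        ids = {normalize_id(line) for line in fh if line.strip()}
    return LabelSet(sample=sample, tool=tool, ids=ids)


@dataclass
class FilterCounts:
    """Pair-level accounting of one filtering run."""

    input_pairs: int
    kept_pairs: int
    removed_pairs: int
    unmatched_labels: int  # labeled IDs never seen in the FASTQ


def _paired_records(
    r1: Iterable[tuple[str, str, str]],
    r2: Optional[Iterable[tuple[str, str, str]]],
) -> Iterator[tuple[str, tuple[tuple[str, str, str], ...]]]:
    """Yield (normalized pair ID, mate records), validating mate sync."""
    if r2 is None:
        for rec in r1:
            yield normalize_id(rec[0]), (rec,)
        return
    it1, it2 = iter(r1), iter(r2)
    sentinel = object()
    n = 0
    while True:
        a = next(it1, sentinel)
        b = next(it2, sentinel)
        if a is sentinel and b is sentinel:
            return
        if a is sentinel or b is sentinel:
            short = "r1" if a is sentinel else "r2"
            raise PairingError(f"mate files out of sync: {short} ended after {n} records")
        n += 1
        ida, idb = normalize_id(a[0]), normalize_id(b[0])
        if ida != idb:
            raise PairingError(f"mate ID mismatch at record {n}: {ida!r} vs {idb!r}")
        yield ida, (a, b)


def filter_fastq(
    labels: LabelSet,
    r1_in: str | Path,
    r2_in: str | Path | None = None,
    *,
    out_dir: str | Path,
    emit_removed: bool = False,
    prefix: str | None = None,
) -> tuple[FilterCounts, dict[str, Path]]:
    """Split FASTQ(.gz) input into kept and (optionally) removed streams.

    A pair goes to the removed output iff its normalized ID is in ``labels``;
    otherwise it is kept. Mate order and record order are preserved. Output
    compression mirrors the input (gzip sniffed from magic bytes). Labeled
    IDs absent from the FASTQ are counted in ``unmatched_labels``, not fatal.

    Returns the counts and a map of output roles to paths
    (``kept_r1``, ``kept_r2``, ``removed_r1``, ``removed_r2``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix if prefix is not None else (labels.sample or "sample")
    gz = is_gzipped(r1_in)
    ext = ".fastq.gz" if gz else ".fastq"
    mates = ("R1", "R2") if r2_in is not None else ("R1",)

    paths: dict[str, Path] = {}
    handles: dict[str, object] = {}
    for i, mate in enumerate(mates, start=1):
        kp = out_dir / f"{prefix}.kept_{mate}{ext}"
        paths[f"kept_r{i}"] = kp
        handles[f"kept_r{i}"] = open_text(kp, "wt", compress=gz)
        if emit_removed:
            rp = out_dir / f"{prefix}.removed_{mate}{ext}"
            paths[f"removed_r{i}"] = rp
            handles[f"removed_r{i}"] = open_text(rp, "wt", compress=gz)

    seen: set[str] = set()
    n_in = n_kept = n_removed = 0
    try:
        r1_stream = read_fastq(r1_in)
        r2_stream = read_fastq(r2_in) if r2_in is not None else None
        for pid, recs in _paired_records(r1_stream, r2_stream):
            n_in += 1
            if pid in labels.ids:
                seen.add(pid)
                n_removed += 1
                if emit_removed:
                    for i, rec in enumerate(recs, start=1):
                        write_fastq_record(handles[f"removed_r{i}"], *rec)
            else:
                n_kept += 1
                for i, rec in enumerate(recs, start=1):
                    write_fastq_record(handles[f"kept_r{i}"], *rec)
    finally:
        for fh in handles.values():
            fh.close()

    counts = FilterCounts(
        input_pairs=n_in,
        kept_pairs=n_kept,
        removed_pairs=n_removed,
        unmatched_labels=len(labels.ids - seen),
    )
    return counts, paths


def summarize(sets: Iterable[LabelSet], totals: dict[str, int]) -> pd.DataFrame:
    """Per-(sample, tool) labeled counts and fractions of the input pairs.

    Columns: ``sample``, ``tool``, ``labeled``, ``fraction``.
    """
    rows = []
    for s in sets:
        if s.sample not in totals:
            raise UsageError(f"no input pair total for sample {s.sample!r}")
        total = totals[s.sample]
        rows.append(
            {
                "sample": s.sample,
                "tool": s.tool,
                "labeled": len(s.ids),
                "fraction": len(s.ids) / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["sample", "tool", "labeled", "fraction"])
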