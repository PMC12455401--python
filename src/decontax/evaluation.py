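"""Benchmarking decontamination against ground truth.

The convention throughout: the contaminant (host) read pairs are the
positive class. TP = contaminant pairs removed, FN = contaminant pairs that
survive filtering, FP = clean (microbial) pairs wrongly removed, TN = clean
pairs retained. Hence

    recall    = TP / (TP + FN)   — thoroughness of contamination removal,
    precision = TP / (TP + FP)   — retention of clean reads.

Metrics are reported at 5 decimal places; full double precision is kept
internally. Composition bias among removed (FP) and retained (TN) clean
reads is assessed with a 2x2 Pearson chi-squared test of independence
(df = 1, no continuity correction — intended-use counts are >= 1e4, where
the correction is negligible; small-table users should be aware of this).

Cross-method set algebra supports combination analyses: intersecting FN
sets shows what every method misses; uniting FP sets shows the cost of
chaining methods.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, UndefinedMetricError, UsageError

__all__ = [
    "ConfusionCounts",
    "MethodResult",
    "confusion",
    "recall",
    "precision",
    "chi2_2x2",
    "fn_intersections",
    "fp_union",
    "intersections_table",
]

REPORT_DIGITS = 5


@dataclass(frozen=True)
class ConfusionCounts:
    """Read-pair confusion counts; contaminant pairs are the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion(removed: set[str], truth_contaminant: set[str], universe: set[str]) -> ConfusionCounts:
    """Confusion counts of a removed-ID set against a truth manifest.

    ``universe`` is every read-pair ID in the dataset; ``truth_contaminant``
    the subset that truly originates from the contaminant taxon.
    """
    if not removed <= universe:
        raise UsageError(f"{len(removed - universe)} removed IDs are not in the ID universe")
    if not truth_contaminant <= universe:
        raise UsageError("truth-contaminant IDs must be a subset of the ID universe")
    tp = len(removed & truth_contaminant)
    fp = len(removed - truth_contaminant)
    fn = len(truth_contaminant - removed)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN): fraction of contaminant pairs actually removed."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no truth-contaminant pairs")
    return c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP): fraction of removed pairs that were truly contaminant."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: nothing was removed")
    return c.tp / (c.tp + c.fp)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared test of independence on the 2x2 table [[a,b],[c,d]].

    df = 1, no continuity correction; returns (statistic, upper-tail p).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.min() < 0:
        raise ValueError("table counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("2x2 table has a zero row or column total")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MethodResult:
    """Per-method removed/FN/FP ID sets with derived metrics."""

    name: str
    removed: set[str]
    fn_ids: set[str]
    fp_ids: set[str]
    counts: ConfusionCounts

    @classmethod
    def from_sets(
        cls, name: str, removed: set[str], truth_contaminant: set[str], universe: set[str]
    ) -> "MethodResult":
        counts = confusion(removed, truth_contaminant, universe)
        return cls(
            name=name,
            removed=set(removed),
            fn_ids=truth_contaminant - removed,
            fp_ids=removed - truth_contaminant,
            counts=counts,
        )

    @property
    def recall(self) -> float:
        return recall(self.counts)

    @property
    def precision(self) -> float:
        return precision(self.counts)


def fn_intersections(methods: Sequence[MethodResult]) -> dict[tuple[str, ...], int]:
    """|intersection of FN sets| for every non-empty subset of methods.

    2^k - 1 entries for k methods; keys are tuples of method names in input
    order. Singleton entries are each method's own FN count.
    """
    if not methods:
        raise UsageError("fn_intersections needs at least one method")
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(methods) + 1):
        for combo in itertools.combinations(methods, r):
            inter = set(combo[0].fn_ids)
            for m in combo[1:]:
                inter &= m.fn_ids
            out[tuple(m.name for m in combo)] = len(inter)
    return out


def fp_union(methods: Sequence[MethodResult]) -> tuple[int, dict[str, int]]:
    """|union of FP sets| plus each method's incremental FP over the first.

    The first method is the base; the increment for method m is
    ``|FP_m \\ FP_base|`` — the extra clean pairs lost by chaining m onto it.
    """
    if not methods:
        raise UsageError("fp_union needs at least one method")
    base = methods[0].fp_ids
    union: set[str] = set()
    increments: dict[str, int] = {}
    for m in methods:
        union |= m.fp_ids
        increments[m.name] = len(m.fp_ids - base)
    return len(union), increments


def intersections_table(methods: Sequence[MethodResult]) -> pd.DataFrame:
    """FN-intersection sizes as a tidy table suitable for upset-style plots.

    One row per non-empty method subset: boolean membership columns, the
    subset degree, and the FN-intersection size.
    """
    sizes = fn_intersections(methods)
    names = [m.name for m in methods]
    rows = []
    for combo, size in sizes.items():
        row: dict[str, object] = {n: (n in combo) for n in names}
        row["degree"] = len(combo)
        row["fn_intersection"] = size
        rows.append(row)
    return pd.DataFrame(rows, columns=[*names, "degree", "fn_intersection"])


def metrics_row(result: MethodResult) -> Mapping[str, object]:
    """One reporting row: counts plus recall/precision rounded to 5 decimals."""
    c = result.counts
    return {
        "method": result.name,
        "tp": c.tp,
        "fp": c.fp,
        "tn": c.tn,
        "fn": c.fn,
        "recall": round(result.recall, REPORT_DIGITS),
        "precision": round(result.precision, REPORT_DIGITS),
    }
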