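"""NCBI-taxdump-dialect taxonomy: parsing, name resolution, subtree expansion.

The filter target is given as a scientific name (e.g. ``Homo sapiens``).
Labeling a non-leaf target means labeling its whole subtree, so the core
query here is "give me the set of taxon IDs at or below taxon X".

The parser accepts both the classic ``\\t|\\t``-padded dmp dialect and bare
``|`` delimiters, and ignores trailing fields beyond the rank column, since
real nodes.dmp files vary in how many columns they carry.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from .errors import FormatError, TaxonLookupError, TaxonomyStructureError

__all__ = [
    "TaxonomyTree",
    "parse_taxdump",
    "load_taxdump",
    "write_taxdump",
    "resolve_name",
    "subtree",
    "lca",
]


def _split_dmp(line: str) -> list[str]:
    # fields are pipe-delimited; strip the tab padding and any trailing pipe
    parts = [f.strip(" \t") for f in line.rstrip("\n").split("|")]
    if parts and parts[-1] == "":
        parts.pop()
    return parts


@dataclass
class TaxonomyTree:
    """Parent-pointer taxonomy with names, ranks, and a child index.

    ``nodes`` maps taxon ID -> (parent ID, rank); ``names`` maps taxon ID ->
    scientific name. The root is its own parent (taxdump convention) and is
    detected at parse time, never hard-coded.
    """

    nodes: dict[int, tuple[int, str]]
    names: dict[int, str]
    root: int
    children: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.children:
            self.children = {tid: [] for tid in self.nodes}
            for tid, (parent, _rank) in self.nodes.items():
                if tid != self.root:
                    self.children[parent].append(tid)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxon: int) -> bool:
        return taxon in self.nodes

    def parent(self, taxon: int) -> int:
        return self.nodes[taxon][0]

    def rank(self, taxon: int) -> str:
        return self.nodes[taxon][1]

    def depth(self, taxon: int) -> int:
        """Number of parent hops from ``taxon`` to the root."""
        hops = 0
        while taxon != self.root:
            taxon = self.parent(taxon)
            hops += 1
        return hops

    def ancestors(self, taxon: int) -> list[int]:
        """Path from ``taxon`` (inclusive) up to the root (inclusive)."""
        path = [taxon]
        while taxon != self.root:
            taxon = self.parent(taxon)
            path.append(taxon)
        return path


def parse_taxdump(
    nodes_source: Iterable[str] | IO[str],
    names_source: Iterable[str] | IO[str],
) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from nodes.dmp / names.dmp line streams.

    Only ``scientific name`` class entries populate the name table. The tree
    is validated: exactly one self-parent root, every parent present, and
    every node reaches the root (no cycles).
    """
    nodes: dict[int, tuple[int, str]] = {}
    root: int | None = None
    for line in nodes_source:
        if not line.strip():
            continue
        parts = _split_dmp(line)
        if len(parts) < 3:
            raise FormatError(f"nodes.dmp line has {len(parts)} fields, need >= 3: {line!r}")
        try:
            tid, parent = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FormatError(f"non-integer taxon/parent ID in nodes.dmp line: {line!r}") from exc
        rank = parts[2]
        if tid in nodes:
            raise TaxonomyStructureError(f"duplicate taxon ID {tid} in nodes.dmp")
        nodes[tid] = (parent, rank)
        if tid == parent:
            if root is not None:
                raise TaxonomyStructureError(f"multiple self-parent roots: {root} and {tid}")
            root = tid
    if not nodes:
        raise FormatError("empty nodes.dmp stream")
    if root is None:
        raise TaxonomyStructureError("no self-parent root node found")

    for tid, (parent, _rank) in nodes.items():
        if parent not in nodes:
            raise TaxonomyStructureError(f"taxon {tid} has missing parent {parent}")

    # cycle check: every node must reach the root by parent-following
    reaches_root: set[int] = {root}
    for tid in nodes:
        path = []
        cur = tid
        while cur not in reaches_root:
            if cur in path:
                raise TaxonomyStructureError(f"cycle detected at taxon ID {cur}")
            path.append(cur)
            cur = nodes[cur][0]
        reaches_root.update(path)

    names: dict[int, str] = {}
    for line in names_source:
        if not line.strip():
            continue
        parts = _split_dmp(line)
        if len(parts) < 2:
            raise FormatError(f"names.dmp line has {len(parts)} fields, need >= 2: {line!r}")
        name_class = parts[3] if len(parts) >= 4 else "scientific name"
        if name_class != "scientific name":
            continue
        try:
            tid = int(parts[0])
        except ValueError as exc:
            raise FormatError(f"non-integer taxon ID in names.dmp line: {line!r}") from exc
        if tid in nodes:
            names[tid] = parts[1]

    return TaxonomyTree(nodes=nodes, names=names, root=root)


def load_taxdump(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    with open(nodes_path) as nh, open(names_path) as mh:
        return parse_taxdump(nh, mh)


def write_taxdump(tree: TaxonomyTree, nodes_path: str | Path, names_path: str | Path) -> None:
    """Serialize a tree back to the classic tab-pipe-padded dmp dialect."""
    with open(nodes_path, "w") as nh:
        for tid in sorted(tree.nodes):
            parent, rank = tree.nodes[tid]
            nh.write(f"{tid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w") as mh:
        for tid in sorted(tree.names):
            mh.write(f"{tid}\t|\t{tree.names[tid]}\t|\t\t|\tscientific name\t|\n")


def resolve_name(tree: TaxonomyTree, name: str) -> int:
    """Resolve a scientific name to its taxon ID.

    Exact (case-sensitive) match is preferred; a case-insensitive match is
    the fallback. Ambiguity (two nodes sharing the query name) and misses
    raise :class:`TaxonLookupError`, the latter listing the nearest names.
    """
    exact = [tid for tid, nm in tree.names.items() if nm == name]
    if len(exact) == 1:
        return exact[0]
    if len(exact) > 1:
        raise TaxonLookupError(f"name {name!r} is ambiguous: taxa {sorted(exact)}")
    folded = [tid for tid, nm in tree.names.items() if nm.lower() == name.lower()]
    if len(folded) == 1:
        return folded[0]
    if len(folded) > 1:
        raise TaxonLookupError(f"name {name!r} is ambiguous (case-insensitive): taxa {sorted(folded)}")
    near = difflib.get_close_matches(name, list(tree.names.values()), n=3)
    hint = f"; nearest: {near}" if near else ""
    raise TaxonLookupError(f"no taxon named {name!r}{hint}")


def subtree(tree: TaxonomyTree, taxon: int) -> set[int]:
    """Taxon IDs of ``taxon`` and all its descendants (ancestors excluded)."""
    if taxon not in tree.nodes:
        raise TaxonLookupError(f"unknown taxon ID {taxon}")
    out: set[int] = set()
    stack = [taxon]
    while stack:
        cur = stack.pop()
        out.add(cur)
        stack.extend(tree.children[cur])
    return out


def lca(tree: TaxonomyTree, taxa: Iterable[int]) -> int:
    """Lowest common ancestor of a non-empty collection of taxon IDs."""
    it: Iterator[int] = iter(taxa)
    try:
        first = next(it)
    except StopIteration:
        raise TaxonLookupError("lca of an empty taxon collection") from None
    common = tree.ancestors(first)
    common_set = set(common)
    for t in it:
        anc = [a for a in tree.ancestors(t) if a in common_set]
        common = anc
        common_set = set(anc)
    return common[0]
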