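"""Self-contained synthetic fixtures: taxonomy, genomes, reads, Kraken2-format output.

Everything downstream of real sequencing is emulated here so the whole
pipeline is testable without downloads:

* a small taxonomy containing one target "host" species and several microbes,
* random genomes, optionally sharing verbatim segments between two taxa so
  genuinely ambiguous k-mers exist (a segment of length k+m-1 shares exactly
  m k-mers),
* error-bearing paired-end reads with a truth manifest mapping every pair ID
  to its source taxon and a contaminant flag (source == host),
* Kraken2 standard-format per-read output produced by a miniature LCA
  emulator: each canonical k-mer maps to the lowest common ancestor of all
  taxa whose genomes contain it, mirroring how Kraken2 resolves k-mers
  shared between genomes.

The read model is substitution-only (no indels) — enough to exercise k-mer
mismatch behavior, not a platform error profile. All outputs are pure
functions of (spec, params, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._seqio import revcomp, write_fastq_record
from .errors import SpecError
from .taxonomy import TaxonomyTree, lca, write_taxdump

__all__ = [
    "TaxonSpec",
    "CommunitySpec",
    "ReadSimParams",
    "Community",
    "default_community_spec",
    "generate_community",
    "simulate_pairs",
    "emulate_kraken_output",
    "write_fastq",
    "write_manifest",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class TaxonSpec:
    taxon_id: int
    name: str
    parent: int
    rank: str = "no rank"


@dataclass
class CommunitySpec:
    """Declarative description of a synthetic host + microbes community."""

    taxa: Sequence[TaxonSpec]
    host: int
    genome_lengths: dict[int, int]
    abundances: dict[int, float]
    shared_segments: Sequence[tuple[int, int, int]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = {t.taxon_id for t in self.taxa}
        if self.host not in ids:
            raise SpecError(f"host taxon {self.host} is not in the taxa list")
        if abs(sum(self.abundances.values()) - 1.0) > 1e-9:
            raise SpecError("abundances must sum to 1")
        for tid in self.abundances:
            if tid not in self.genome_lengths:
                raise SpecError(f"abundance given for taxon {tid} without a genome length")
        for a, b, length in self.shared_segments:
            if length > min(self.genome_lengths[a], self.genome_lengths[b]):
                raise SpecError(
                    f"shared segment of {length} bp exceeds a genome ({a} or {b})"
                )


@dataclass(frozen=True)
class ReadSimParams:
    """Paired-end read simulation parameters (Illumina-like, substitution-only)."""

    n_pairs: int
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise SpecError("read length must not exceed the mean insert size")
        if not 0.0 <= self.error_rate < 1.0:
            raise SpecError("error rate must be in [0, 1)")


def default_community_spec(
    host_abundance: float = 0.32,
    shared_segment: int = 0,
    k: int = 27,
) -> CommunitySpec:
    """A 1-host + 3-microbe community echoing a host-heavy metagenome.

    The default host abundance of 0.32 mirrors a dataset of ~10M host among
    ~31M total read pairs. ``shared_segment > 0`` copies a segment of that
    length from the host genome into the first microbe, creating k-mers
    whose LCA sits above the host (``k`` only validates the segment length).
    """
    taxa = [
        TaxonSpec(1, "root", 1, "no rank"),
        TaxonSpec(131567, "cellular organisms", 1, "no rank"),
        TaxonSpec(2, "Bacteria", 131567, "superkingdom"),
        TaxonSpec(2759, "Eukaryota", 131567, "superkingdom"),
        TaxonSpec(9606, "Homo sapiens", 2759, "species"),
        TaxonSpec(562, "Escherichia coli", 2, "species"),
        TaxonSpec(1613, "Limosilactobacillus fermentum", 2, "species"),
        TaxonSpec(1280, "Staphylococcus aureus", 2, "species"),
    ]
    microbes = [562, 1613, 1280]
    rest = (1.0 - host_abundance) / len(microbes)
    shared: tuple[tuple[int, int, int], ...] = ()
    if shared_segment:
        if shared_segment < k:
            raise SpecError(f"shared segment ({shared_segment} bp) shorter than k={k}")
        shared = ((9606, 562, shared_segment),)
    return CommunitySpec(
        taxa=taxa,
        host=9606,
        genome_lengths={9606: 20_000, 562: 12_000, 1613: 12_000, 1280: 12_000},
        abundances={9606: host_abundance, **{m: rest for m in microbes}},
        shared_segments=shared,
    )


@dataclass
class Community:
    """Materialized community: taxonomy, genomes, and provenance."""

    spec: CommunitySpec
    tree: TaxonomyTree
    genomes: dict[int, str]
    provenance: dict[str, object]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Serialize taxdump files, one FASTA per taxon, and the provenance manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        nodes_path = out_dir / "nodes.dmp"
        names_path = out_dir / "names.dmp"
        write_taxdump(self.tree, nodes_path, names_path)
        paths: dict[str, Path] = {"nodes": nodes_path, "names": names_path}
        for tid in sorted(self.genomes):
            p = out_dir / f"taxon_{tid}.fasta"
            with open(p, "w") as fh:
                fh.write(f">taxon_{tid} {self.tree.names.get(tid, '')}\n")
                seq = self.genomes[tid]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
            paths[f"fasta_{tid}"] = p
        prov_path = out_dir / "provenance.tsv"
        with open(prov_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["key", "value"])
            for key, value in sorted(self.provenance.items()):
                w.writerow([key, value])
        paths["provenance"] = prov_path
        return paths


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _build_tree(taxa: Sequence[TaxonSpec]) -> TaxonomyTree:
    nodes = {t.taxon_id: (t.parent, t.rank) for t in taxa}
    names = {t.taxon_id: t.name for t in taxa}
    roots = [t.taxon_id for t in taxa if t.taxon_id == t.parent]
    if len(roots) != 1:
        raise SpecError(f"community taxa must contain exactly one self-parent root, got {roots}")
    return TaxonomyTree(nodes=nodes, names=names, root=roots[0])


def generate_community(spec: CommunitySpec, seed: int) -> Community:
    """Draw random genomes per the spec and copy shared segments verbatim."""
    rng = np.random.default_rng(seed)
    tree = _build_tree(spec.taxa)
    genomes = {
        tid: _random_genome(rng, length) for tid, length in sorted(spec.genome_lengths.items())
    }
    segments = []
    for a, b, length in spec.shared_segments:
        src_start = int(rng.integers(0, len(genomes[a]) - length + 1))
        dst_start = int(rng.integers(0, len(genomes[b]) - length + 1))
        segment = genomes[a][src_start : src_start + length]
        gb = genomes[b]
        genomes[b] = gb[:dst_start] + segment + gb[dst_start + length :]
        segments.append(f"{a}:{src_start}->{b}:{dst_start}:{length}")
    provenance: dict[str, object] = {
        "seed": seed,
        "host": spec.host,
        "n_taxa": len(spec.taxa),
        "shared_segments": ";".join(segments) or "none",
    }
    return Community(spec=spec, tree=tree, genomes=genomes, provenance=provenance)


@dataclass
class SimulatedReads:
    """Paired reads plus the per-pair truth manifest."""

    r1: list[tuple[str, str, str]]  # (id, sequence, quality)
    r2: list[tuple[str, str, str]]
    manifest: list[tuple[str, int, bool]]  # (pair id, source taxon, is_contaminant)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_pairs(community: Community, params: ReadSimParams) -> SimulatedReads:
    """Draw read pairs from the community genomes per the spec abundances.

    Fragments are sampled uniformly with a normal insert-size distribution
    (clipped to [read length, genome length]); R1 is the forward strand of
    the fragment start, R2 the reverse complement strand of the fragment
    end. Substitution errors are applied i.i.d. per base. Pair IDs are
    ``simN`` with the mate encoded only in file membership.
    """
    spec = community.spec
    rng = np.random.default_rng(params.seed)
    taxa = sorted(spec.abundances)
    probs = np.array([spec.abundances[t] for t in taxa])
    for tid in taxa:
        if spec.abundances[tid] > 0 and len(community.genomes[tid]) < params.insert_mean:
            raise SpecError(
                f"genome of taxon {tid} ({len(community.genomes[tid])} bp) is shorter "
                f"than the mean insert size ({params.insert_mean} bp)"
            )
    qual = "I" * params.read_length
    r1: list[tuple[str, str, str]] = []
    r2: list[tuple[str, str, str]] = []
    manifest: list[tuple[str, int, bool]] = []
    sources = rng.choice(len(taxa), size=params.n_pairs, p=probs)
    for i in range(params.n_pairs):
        tid = taxa[sources[i]]
        genome = community.genomes[tid]
        insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
        insert = max(params.read_length, min(insert, len(genome)))
        start = int(rng.integers(0, len(genome) - insert + 1))
        fragment = genome[start : start + insert]
        fwd = fragment[: params.read_length]
        rev = revcomp(fragment)[: params.read_length]
        pid = f"sim{i}"
        r1.append((pid, _apply_errors(rng, fwd, params.error_rate), qual))
        r2.append((pid, _apply_errors(rng, rev, params.error_rate), qual))
        manifest.append((pid, tid, tid == spec.host))
    return SimulatedReads(r1=r1, r2=r2, manifest=manifest)


def write_fastq(records: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for title, seq, qual in records:
            write_fastq_record(fh, title, seq, qual)


def write_manifest(manifest: Sequence[tuple[str, int, bool]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "source_taxon", "is_contaminant"])
        for pid, tid, contaminant in manifest:
            w.writerow([pid, tid, int(contaminant)])


def read_manifest(path: str | Path) -> list[tuple[str, int, bool]]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append((row["id"], int(row["source_taxon"]), row["is_contaminant"] == "1"))
    return out


def _kmer_lca_map(community: Community, k: int) -> dict[str, int]:
    """Canonical k-mer -> LCA of all taxa whose genomes contain it."""
    from .kmers import _iter_canonical  # local import avoids a cycle at module load

    owners: dict[str, set[int]] = {}
    for tid, genome in sorted(community.genomes.items()):
        for km in _iter_canonical(genome, k):
            owners.setdefault(km, set()).add(tid)
    return {km: lca(community.tree, taxa) for km, taxa in owners.items()}


def _mate_tokens(seq: str, k: int, assign: dict[str, int]) -> list[str]:
    """Run-length-encoded (assignment, count) tokens for one read, in read order."""
    from .kmers import canonical

    seq = seq.upper()
    calls: list[str] = []
    n_windows = len(seq) - k + 1
    for i in range(max(n_windows, 0)):
        window = seq[i : i + k]
        if any(b not in "ACGT" for b in window):
            calls.append("A")
        else:
            calls.append(str(assign.get(canonical(window), 0)))
    tokens: list[str] = []
    for call in calls:
        if tokens and tokens[-1].split(":")[0] == call:
            head, _, count = tokens[-1].partition(":")
            tokens[-1] = f"{head}:{int(count) + 1}"
        else:
            tokens.append(f"{call}:1")
    return tokens


def emulate_kraken_output(
    community: Community,
    r1: Sequence[tuple[str, str, str]],
    r2: Optional[Sequence[tuple[str, str, str]]] = None,
    k: int = 31,
) -> list[str]:
    """Kraken2 standard-format lines for simulated reads, via the k-mer->LCA map.

    Every valid window is looked up as a canonical k-mer; hits report the
    LCA taxon, misses report 0, windows spanning non-ACGT bases report
    ``A``. The consensus column carries the plurality assigned taxon (the
    cutoff model never reads it). Mates are joined by ``|:|``.
    """
    assign = _kmer_lca_map(community, k)
    lines: list[str] = []
    mates2 = r2 if r2 is not None else [None] * len(r1)
    if len(r1) != len(mates2):
        raise SpecError("r1 and r2 read lists differ in length")
    for rec1, rec2 in zip(r1, mates2):
        reads = [rec1] if rec2 is None else [rec1, rec2]
        token_lists = [_mate_tokens(seq, k, assign) for _id, seq, _q in reads]
        votes: dict[int, int] = {}
        for tokens in token_lists:
            for token in tokens:
                head, _, count = token.partition(":")
                if head not in ("A", "0"):
                    votes[int(head)] = votes.get(int(head), 0) + int(count)
        consensus = max(votes, key=lambda t: (votes[t], -t)) if votes else 0
        flag = "C" if votes else "U"
        lengths = "|".join(str(len(seq)) for _id, seq, _q in reads)
        kmer_col = " |:| ".join(" ".join(tokens) for tokens in token_lists)
        lines.append(f"{flag}\t{rec1[0]}\t{consensus}\t{lengths}\t{kmer_col}")
    return lines
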