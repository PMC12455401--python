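import pytest

from decontax import (
    ReadSimParams,
    TaxonomyTree,
    default_community_spec,
    emulate_kraken_output,
    generate_community,
    simulate_pairs,
)

N_PAIRS = 300
SEED = 11
KRAKEN_K = 31


@pytest.fixture(scope="session")
def fixture_tree() -> TaxonomyTree:
    """Hand-built taxonomy: host lineage plus a 7-node binary clade under taxon 10."""
    nodes = {
        1: (1, "no rank"),
        131567: (1, "no rank"),
        2759: (131567, "superkingdom"),
        2: (131567, "superkingdom"),
        9606: (2759, "species"),
        10: (2, "genus"),
        11: (10, "species"),
        12: (10, "species"),
        13: (11, "strain"),
        14: (11, "strain"),
        15: (12, "strain"),
        16: (12, "strain"),
    }
    names = {
        1: "root",
        131567: "cellular organisms",
        2759: "Eukaryota",
        2: "Bacteria",
        9606: "Homo sapiens",
        10: "Example genus",
        11: "Example species A",
        12: "Example species B",
    }
    return TaxonomyTree(nodes=nodes, names=names, root=1)


@pytest.fixture(scope="session")
def community():
    """Disjoint-genome host + microbes community (no shared segments)."""
    return generate_community(default_community_spec(), seed=SEED)


@pytest.fixture(scope="session")
def sim_reads(community):
    """Error-free paired reads from the disjoint community, with truth manifest."""
    return simulate_pairs(community, ReadSimParams(n_pairs=N_PAIRS, seed=SEED))


@pytest.fixture(scope="session")
def kraken_lines(community, sim_reads):
    return emulate_kraken_output(community, sim_reads.r1, sim_reads.r2, k=KRAKEN_K)


@pytest.fixture(scope="session")
def truth_ids(sim_reads):
    universe = {pid for pid, _t, _c in sim_reads.manifest}
    contaminants = {pid for pid, _t, c in sim_reads.manifest if c}
    return universe, contaminants
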