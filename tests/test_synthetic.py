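import pytest

from decontax import (
    CommunitySpec,
    ModelCutoffs,
    ReadSimParams,
    SpecError,
    TaxonSpec,
    build_index,
    default_community_spec,
    emulate_kraken_output,
    generate_community,
    parse_kraken_line,
    simulate_pairs,
    tally,
)
from decontax._seqio import revcomp
from decontax.taxonomy import load_taxdump


def _kmer_set(seq, k):
    out = set()
    for strand in (seq, revcomp(seq)):
        out.update(strand[i : i + k] for i in range(len(strand) - k + 1))
    return out


class TestGenerateCommunity:
    def test_disjoint_genomes_share_no_27mers(self, community):
        genomes = list(community.genomes.values())
        sets = [_kmer_set(g, 27) for g in genomes]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]

    def test_shared_segment_yields_exact_kmer_count(self):
        # segment of length k + m - 1 shares exactly m k-mers
        k, m = 27, 40
        spec = default_community_spec(shared_segment=k + m - 1, k=k)
        com = generate_community(spec, seed=5)
        host, microbe = com.genomes[9606], com.genomes[562]
        shared = _kmer_set(host, k) & _kmer_set(microbe, k)
        # count distinct canonical sites: m windows, each present on both strands
        forward_only = {min(km, revcomp(km)) for km in shared}
        assert len(forward_only) == m

    def test_same_seed_reproduces_outputs(self, tmp_path):
        spec = default_community_spec(shared_segment=60)
        a = generate_community(spec, seed=9)
        b = generate_community(spec, seed=9)
        assert a.genomes == b.genomes
        d1, d2 = tmp_path / "a", tmp_path / "b"
        a.write(d1)
        b.write(d2)
        for name in ("nodes.dmp", "names.dmp", "taxon_9606.fasta", "provenance.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_segment_longer_than_genome_rejected(self):
        taxa = [TaxonSpec(1, "root", 1), TaxonSpec(2, "host", 1), TaxonSpec(3, "microbe", 1)]
        with pytest.raises(SpecError):
            CommunitySpec(
                taxa=taxa, host=2,
                genome_lengths={2: 500, 3: 400},
                abundances={2: 0.5, 3: 0.5},
                shared_segments=[(2, 3, 450)],
            )

    def test_abundances_must_sum_to_one(self):
        taxa = [TaxonSpec(1, "root", 1), TaxonSpec(2, "host", 1)]
        with pytest.raises(SpecError):
            CommunitySpec(taxa=taxa, host=2, genome_lengths={2: 500}, abundances={2: 0.7})

    def test_written_taxdump_is_readable(self, community, tmp_path):
        paths = community.write(tmp_path)
        tree = load_taxdump(paths["nodes"], paths["names"])
        assert tree.nodes == community.tree.nodes
        assert tree.names == community.tree.names


class TestSimulatePairs:
    def test_zero_pairs(self, community):
        reads = simulate_pairs(community, ReadSimParams(n_pairs=0, seed=1))
        assert reads.r1 == [] and reads.r2 == [] and reads.manifest == []

    def test_manifest_matches_realized_draw(self, community):
        spec = default_community_spec(host_abundance=0.5)
        com = generate_community(spec, seed=2)
        reads = simulate_pairs(com, ReadSimParams(n_pairs=1000, seed=2))
        contaminants = [pid for pid, tid, c in reads.manifest if c]
        hosts = [pid for pid, tid, c in reads.manifest if tid == 9606]
        assert contaminants == hosts
        assert 0 < len(contaminants) < 1000

    def test_error_free_reads_are_exact_genome_substrings(self, community, sim_reads):
        genomes = community.genomes
        by_id = {pid: tid for pid, tid, _c in sim_reads.manifest}
        for (pid, seq, _q), (_pid2, seq2, _q2) in zip(sim_reads.r1, sim_reads.r2):
            genome = genomes[by_id[pid]]
            assert seq in genome
            assert revcomp(seq2) in genome

    def test_substitutions_land_at_requested_rate(self):
        import numpy as np

        from decontax.synthetic import _apply_errors

        rng = np.random.default_rng(4)
        seq = "ACGT" * 25_000
        noisy = _apply_errors(rng, seq, 0.05)
        diffs = sum(a != b for a, b in zip(seq, noisy))
        # each hit position is replaced by a different base, so diff rate ~= error rate
        assert 0.04 < diffs / len(seq) < 0.06

    def test_read_length_exceeding_insert_rejected(self):
        with pytest.raises(SpecError):
            ReadSimParams(n_pairs=1, read_length=500, insert_mean=350)

    def test_pair_ids_are_simn_without_mate_suffix(self, sim_reads):
        assert sim_reads.r1[0][0] == "sim0"
        assert all(r1[0] == r2[0] for r1, r2 in zip(sim_reads.r1, sim_reads.r2))


class TestEmulateKrakenOutput:
    def test_host_reads_assign_to_host_taxon(self, community, sim_reads, kraken_lines):
        host_ids = {pid for pid, tid, c in sim_reads.manifest if c}
        for line in kraken_lines:
            rec = parse_kraken_line(line)
            if rec.read_id in host_ids:
                assignments = {a for mate in rec.kmer_runs for a, _c in mate}
                assert assignments == {9606}

    def test_random_read_absent_from_genomes_is_all_zero(self, community):
        # poly-A read: astronomically unlikely to occur in a random genome
        fake = [("alien", "A" * 150, "I" * 150)]
        (line,) = emulate_kraken_output(community, fake, k=31)
        rec = parse_kraken_line(line)
        assert not rec.classified
        assert rec.kmer_runs == (((0, 120),),)

    def test_ambiguous_bases_emit_a_tokens(self, community):
        read_seq = community.genomes[9606][:60] + "N" + community.genomes[9606][61:150]
        (line,) = emulate_kraken_output(community, [("amb", read_seq, "I" * 150)], k=31)
        rec = parse_kraken_line(line)
        assert any(a == -1 for mate in rec.kmer_runs for a, _c in mate)

    def test_shared_segment_kmers_map_to_lca(self):
        spec = default_community_spec(shared_segment=200)
        com = generate_community(spec, seed=6)
        # a read straight from the shared segment (recover it from provenance)
        seg_info = str(com.provenance["shared_segments"])
        src = seg_info.split("->")[0]  # "9606:start"
        start = int(src.split(":")[1])
        read_seq = com.genomes[9606][start : start + 150]
        (line,) = emulate_kraken_output(com, [("shared", read_seq, "I" * 150)], k=31)
        rec = parse_kraken_line(line)
        assignments = {a for mate in rec.kmer_runs for a, _c in mate}
        # LCA of Homo sapiens (Eukaryota) and E. coli (Bacteria) = cellular organisms
        assert assignments == {131567}
        # such k-mers count as "other", so the cutoff model does not label the read
        t = tally(rec, {9606})
        assert t.t == 0 and t.o > 0

    def test_determinism_of_emulated_lines(self, community, sim_reads):
        a = emulate_kraken_output(community, sim_reads.r1, sim_reads.r2, k=31)
        b = emulate_kraken_output(community, sim_reads.r1, sim_reads.r2, k=31)
        assert a == b


def test_shared_segment_separates_the_two_classifiers():
    """Reads from a host-microbe shared segment fool the exact k-mer classifier
    but not the LCA-aware cutoff model — the motivation for combining both."""
    spec = default_community_spec(shared_segment=300)
    com = generate_community(spec, seed=8)
    reads = simulate_pairs(com, ReadSimParams(n_pairs=400, seed=8))
    truth = {pid for pid, _t, c in reads.manifest if c}

    lines = emulate_kraken_output(com, reads.r1, reads.r2, k=31)
    from decontax import label_kraken

    kraken_labels = label_kraken(
        (parse_kraken_line(l) for l in lines), com.tree, "Homo sapiens", ModelCutoffs()
    )
    assert not kraken_labels.ids - truth  # no microbial read labeled

    import io

    host_fasta = io.StringIO(f">host\n{com.genomes[9606]}\n")
    index = build_index(host_fasta, k=27)
    from decontax.kmers import classify_read

    microbe_hits = [
        pid
        for (pid, s1, _q1), (_p, s2, _q2) in zip(reads.r1, reads.r2)
        if pid not in truth and (classify_read(index, s1) or classify_read(index, s2))
    ]
    assert microbe_hits  # the exact-membership classifier picks up shared-segment reads
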