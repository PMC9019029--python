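"""Synthetic-data generator: tree shape, Jukes-Cantor calibration, reads."""

import dendropy
import numpy as np
import pytest

from betapipe.simdata import (
    DepthParams,
    ReadSet,
    evolve_genomes,
    make_diploid,
    make_scenario,
    metadata_table,
    read_fastq,
    reverse_complement,
    simulate_genotypes,
    simulate_reads,
    simulate_tree,
    spike_organelle,
    write_fastq,
)


def _mismatch_fraction(a: str, b: str) -> float:
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((xa != xb).mean())


def _patristic(tree, a, b):
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    return pdm.patristic_distance(tx[a], tx[b])


class TestSimulateTree:
    def test_minimal_scenario_has_four_leaves_and_nested_cultivars(self):
        t = simulate_tree(1, seed=0)
        labels = {lf.taxon.label for lf in t.leaf_node_iter()}
        assert labels == {"outgroup", "atl01", "cul01", "med01"}
        # cultivar is sister to mediterranean, not to atlantic
        d_bc = _patristic(t, "cul01", "med01")
        d_ba = _patristic(t, "cul01", "atl01")
        assert d_bc < d_ba

    def test_deterministic_given_seed(self):
        a = simulate_tree(5, seed=1).as_string(schema="newick")
        b = simulate_tree(5, seed=1).as_string(schema="newick")
        assert a == b

    def test_cultivar_group_closer_to_sister_group_for_all_leaf_pairs(self):
        t = simulate_tree(3, seed=2)
        for i in range(1, 4):
            for j in range(1, 4):
                b = f"cul{i:02d}"
                assert _patristic(t, b, f"med{j:02d}") < _patristic(
                    t, b, f"atl{j:02d}"
                )

    def test_rejects_nonpositive_branch_setting(self):
        with pytest.raises(ValueError, match="within"):
            simulate_tree(2, DepthParams(within=0.0))


class TestEvolveGenomes:
    def test_zero_branch_lengths_give_identical_leaves(self):
        nwk = "(a:0.0,(b:0.0,c:0.0):0.0);"
        t = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = evolve_genomes(t, 5000, seed=0)
        assert leaves["a"] == leaves["b"] == leaves["c"]

    def test_jukes_cantor_closed_form(self):
        # two leaves at total path length 0.04: expected mismatch
        # fraction (3/4)(1 - e^{-4*0.04/3}), within 3 binomial sd
        nwk = "(a:0.015,b:0.025);"
        t = dendropy.Tree.get(data=nwk, schema="newick")
        L = 1_000_000
        leaves = evolve_genomes(t, L, seed=3)
        p = 0.75 * (1 - np.exp(-4 * 0.04 / 3))
        obs = _mismatch_fraction(leaves["a"], leaves["b"])
        assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / L)

    def test_deterministic(self):
        t = simulate_tree(2, seed=4)
        assert evolve_genomes(t, 20000, seed=5) == evolve_genomes(t, 20000, seed=5)

    def test_rejects_negative_branch(self):
        t = dendropy.Tree.get(data="(a:-0.1,b:0.1);", schema="newick")
        with pytest.raises(ValueError, match="non-negative"):
            evolve_genomes(t, 1000, seed=0)


class TestMakeDiploid:
    def test_zero_heterozygosity_identical(self):
        g = "ACGT" * 1000
        h1, h2 = make_diploid(g, 0.0, seed=0)
        assert h1 == g and h2 == g

    def test_heterozygous_site_count_binomial(self):
        rng = np.random.default_rng(0)
        g = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1_000_000)])
        h1, h2 = make_diploid(g, 0.005, seed=1)
        diff = _mismatch_fraction(h1, h2) * 1e6
        assert abs(diff - 5000) < 3 * np.sqrt(1e6 * 0.005 * 0.995)

    def test_two_individuals_diverge_at_twice_rate(self):
        rng = np.random.default_rng(1)
        g = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500_000)])
        h = 0.005
        _, a2 = make_diploid(g, h, seed=2)
        _, b2 = make_diploid(g, h, seed=3)
        # exactly one flipped: 2h(1-h); both flipped to different bases: (2/3)h^2
        exp = (2 * h * (1 - h) + (2 / 3) * h * h) * 500_000
        diff = _mismatch_fraction(a2, b2) * 500_000
        assert abs(diff - exp) < 4 * np.sqrt(exp)

    def test_rejects_out_of_range_rate(self):
        with pytest.raises(ValueError, match="heterozygosity"):
            make_diploid("ACGT", 0.5)


class TestSimulateReads:
    def test_exact_pair_count_from_coverage_formula(self):
        g = "ACGT" * 25_000  # L = 100 kb
        rs = simulate_reads((g, g), coverage=5, read_length=125, seed=0)
        assert rs.n_fragments == round(5 * 100_000 / 250)

    def test_error_free_mates_are_substrings(self):
        rng = np.random.default_rng(2)
        g = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
        h1, h2 = make_diploid(g, 0.01, seed=1)
        rs = simulate_reads((h1, h2), coverage=0.06, error_rate=0.0, seed=3)
        assert rs.n_fragments == 1
        m1, m2 = rs.seqs
        assert m1 in h1 or m1 in h2
        rc = reverse_complement(m2)
        assert rc in h1 or rc in h2

    def test_error_rate_calibration(self):
        # on an all-A genome mate 1 should read A and mate 2 (revcomp) T;
        # any other letter is a simulated sequencing error
        g = "A" * 200_000
        rs = simulate_reads((g, g), coverage=2, error_rate=0.005, seed=4)
        errs = sum(
            sum(c != expect for c in s)
            for i, (s, expect) in enumerate(
                zip(rs.seqs, ["A", "T"] * rs.n_fragments)
            )
        )
        total = rs.total_bases
        assert abs(errs / total - 0.005) < 3 * np.sqrt(0.005 * 0.995 / total)

    def test_deterministic_given_seed(self):
        g = "ACGT" * 2000
        a = simulate_reads((g, g), coverage=2, seed=5, error_rate=0.01)
        b = simulate_reads((g, g), coverage=2, seed=5, error_rate=0.01)
        assert a.seqs == b.seqs and a.names == b.names

    def test_rejects_zero_pairs(self):
        with pytest.raises(ValueError, match="zero read pairs"):
            simulate_reads(("ACGT" * 200, "ACGT" * 200), coverage=1e-6)

    def test_rejects_short_insert(self):
        g = "ACGT" * 500
        with pytest.raises(ValueError, match="insert_mean"):
            simulate_reads((g, g), coverage=1, read_length=125, insert_mean=200)


class TestSpikeOrganelle:
    def test_zero_coverage_is_identity(self):
        g = "ACGT" * 2000
        rs = simulate_reads((g, g), coverage=2, seed=0)
        out = spike_organelle(rs, "ACGT" * 500, 0.0, seed=1)
        assert out.seqs == rs.seqs

    def test_appended_pair_count(self):
        g = "ACGT" * 2000
        rs = simulate_reads((g, g), coverage=2, seed=0)
        org = "ACGT" * 37_500  # 150 kb
        out = spike_organelle(rs, org, 100.0, seed=1)
        assert out.n_fragments - rs.n_fragments == round(100 * 150_000 / 250)

    def test_spiked_reads_match_organelle_exactly_without_errors(self):
        rng = np.random.default_rng(3)
        g = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20_000)])
        org = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
        rs = simulate_reads((g, g), coverage=1, seed=0, error_rate=0.0)
        out = spike_organelle(rs, org, 5.0, seed=1, error_rate=0.0)
        spiked = [
            s for name, s in zip(out.names, out.seqs) if name.startswith("organelle")
        ]
        assert spiked
        for i, s in enumerate(spiked):
            probe = s if i % 2 == 0 else reverse_complement(s)
            assert probe in org


class TestSimulateGenotypes:
    def test_identical_accessions_have_no_polymorphic_site(self):
        g = "ACGT" * 500
        haps = {"a": (g, g), "b": (g, g)}
        with pytest.raises(ValueError, match="biallelic"):
            simulate_genotypes(haps, n_markers=10)

    def test_homozygous_difference_codes_zero_and_two(self):
        a = "AAAA"
        b = "AATA"
        haps = {"x": (a, a), "y": (b, b)}
        g = simulate_genotypes(haps, n_markers=1, missing_rate=0.0, seed=0)
        col = set(g.codes[:, 0])
        assert col == {0.0, 2.0}

    def test_missing_fraction_binomial(self):
        rng = np.random.default_rng(4)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50_000)])
        haps = {}
        for i in range(20):
            h1, h2 = make_diploid(base, 0.02, seed=i)
            haps[f"t{i}"] = (h1, h2)
        g = simulate_genotypes(haps, n_markers=1000, missing_rate=0.1, seed=5)
        frac = np.isnan(g.codes).mean()
        n = g.codes.size
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)

    def test_no_monomorphic_marker_before_masking(self):
        rng = np.random.default_rng(5)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30_000)])
        haps = {f"t{i}": make_diploid(base, 0.02, seed=10 + i) for i in range(6)}
        g = simulate_genotypes(haps, n_markers=500, missing_rate=0.0, seed=6)
        col_min = g.codes.min(axis=0)
        col_max = g.codes.max(axis=0)
        assert (col_min != col_max).all()


class TestScenario:
    def test_beet_mini_structure(self):
        truth = make_scenario("beet-mini", seed=0, genome_length=30_000)
        assert len(truth.taxa) == 13
        assert truth.group_of["outgroup"] == "outgroup"
        groups = {g for g in truth.group_of.values()}
        assert groups == {"atlantic", "cultivar", "mediterranean", "outgroup"}
        leaves = {lf.taxon.label for lf in truth.tree.leaf_node_iter()}
        assert leaves == set(truth.taxa)

    def test_duplicate_scenario_pairs(self):
        truth = make_scenario("beet-mini-dup", seed=0, genome_length=30_000)
        assert len(truth.duplicate_pairs) == 6
        for a, b in truth.duplicate_pairs:
            assert truth.accession_of[a] == truth.accession_of[b]
            # duplicates share haplotype 1, differ in haplotype 2
            assert truth.haplotypes[a][0] == truth.haplotypes[b][0]
            assert truth.haplotypes[a][1] != truth.haplotypes[b][1]
        md = metadata_table(truth)
        assert len(md) == len(truth.taxa)

    def test_scenario_deterministic(self):
        a = make_scenario("beet-mini", seed=3, genome_length=20_000)
        b = make_scenario("beet-mini", seed=3, genome_length=20_000)
        assert a.haplotypes == b.haplotypes

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("nope")


def test_fastq_round_trip(tmp_path):
    g = "ACGT" * 1000
    rs = simulate_reads((g, g), coverage=1, seed=0, error_rate=0.01)
    path = tmp_path / "reads.fastq.gz"
    write_fastq(rs, str(path))
    back = read_fastq(str(path))
    assert back.seqs == rs.seqs
    assert back.names == rs.names
    assert all(np.array_equal(a, b) for a, b in zip(back.quals, rs.quals))


def test_fasta_round_trip(tmp_path):
    from betapipe.simdata import read_fasta, write_fasta

    seqs = {"acc1/hap1": "ACGT" * 50, "acc1/hap2": "TTTT" * 50}
    path = tmp_path / "h.fasta.gz"
    write_fasta(seqs, str(path))
    assert read_fasta(str(path)) == seqs
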