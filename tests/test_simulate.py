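import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from enamelphylo.alphabet import N_STATES
from enamelphylo.simulate import (
    SimulationConfig,
    SurvivalParams,
    backtranslate_and_emit,
    evolve_alignment,
    simulate_ancient_peptides,
    simulate_dataset,
    simulate_yule_tree,
)
from enamelphylo.trees import tree_to_newick


class TestYuleTree:
    def test_smallest_case_three_leaves(self):
        tree = simulate_yule_tree(3, 1.0, seed=7)
        leaves = [lf for lf in tree.leaf_node_iter()]
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        assert len(leaves) == 3
        assert len(internal) == 2  # root plus one further split

    def test_deterministic_under_seed(self):
        a = simulate_yule_tree(8, 1.0, seed=42)
        b = simulate_yule_tree(8, 1.0, seed=42)
        assert tree_to_newick(a) == tree_to_newick(b)

    @pytest.mark.parametrize("seed", range(5))
    def test_leaf_count_and_positive_branches(self, seed):
        tree = simulate_yule_tree(50, 1.0, seed=seed)
        assert sum(1 for _ in tree.leaf_node_iter()) == 50
        total = sum(e.length for e in tree.preorder_edge_iter() if e.length)
        assert total > 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(2, 1.0, seed=0)

    def test_height_rescaling(self):
        tree = simulate_yule_tree(10, 1.0, seed=3, height=0.25)
        leaf = next(tree.leaf_node_iter())
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length
            node = node.parent_node
        assert depth == pytest.approx(0.25)


class TestEvolveAlignment:
    def test_zero_branch_lengths_give_identical_sequences(self):
        tree = simulate_yule_tree(4, 1.0, seed=0)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = 0.0
        msa, hist = evolve_alignment(tree, 50, 0.5, seed=1)
        for t in msa.taxa:
            assert msa.row(t) == hist.ancestral_sequence

    def test_negative_branch_length_rejected(self):
        tree = simulate_yule_tree(4, 1.0, seed=0)
        next(tree.leaf_node_iter()).edge.length = -0.1
        with pytest.raises(ValueError, match="non-negative"):
            evolve_alignment(tree, 10, 0.5, seed=1)

    def test_homogeneous_limit_site_counts(self):
        """With rates forced to 1, per-site mismatch counts are homogeneous."""
        tree = simulate_yule_tree(12, 1.0, seed=2, height=0.5)
        msa, hist = evolve_alignment(tree, 2000, None, seed=3)
        assert np.all(hist.site_rates == 1.0)
        anc = np.array(list(hist.ancestral_sequence))
        diffs = (msa.seqs != anc[None, :]).sum(axis=0)
        # dispersion index of a (near-)binomial count stays near 1;
        # gamma-rate data at alpha=0.5 is strongly overdispersed instead
        assert diffs.var() / diffs.mean() < 2.0
        msa_g, hist_g = evolve_alignment(tree, 2000, 0.3, seed=3)
        anc_g = np.array(list(hist_g.ancestral_sequence))
        diffs_g = (msa_g.seqs != anc_g[None, :]).sum(axis=0)
        assert diffs_g.var() / diffs_g.mean() > diffs.var() / diffs.mean() + 1.0

    def test_pairwise_divergence_matches_gamma_closed_form(self):
        """2-taxon p-distance vs numerical integration over the rate density."""
        alpha, t_total, n = 0.5, 0.5, 10_000
        import dendropy

        tree = dendropy.Tree.get(data="(A:0.25,B:0.25);", schema="newick")
        msa, _ = evolve_alignment(tree, n, alpha, seed=9)
        k = N_STATES
        beta = k / (k - 1)

        def p_diff(r):
            return (k - 1) / k * (1.0 - math.exp(-beta * t_total * r))

        expected, _ = integrate.quad(
            lambda r: p_diff(r) * gamma_dist.pdf(r, a=alpha, scale=1 / alpha),
            0, np.inf,
        )
        observed = np.mean(np.array(list(msa.row("A"))) != np.array(list(msa.row("B"))))
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    @pytest.mark.parametrize("alphas", [(0.3, 1.0), (1.0, 3.0)])
    def test_site_count_variance_grows_as_alpha_drops(self, alphas):
        low, high = alphas
        tree = simulate_yule_tree(10, 1.0, seed=4, height=0.5)
        var = {}
        for a in (low, high):
            msa, hist = evolve_alignment(tree, 2000, a, seed=5)
            anc = np.array(list(hist.ancestral_sequence))
            var[a] = (msa.seqs != anc[None, :]).sum(axis=0).var()
        assert var[low] > var[high]

    def test_determinism(self):
        tree = simulate_yule_tree(6, 1.0, seed=1)
        m1, h1 = evolve_alignment(tree, 100, 0.5, seed=8)
        m2, h2 = evolve_alignment(tree, 100, 0.5, seed=8)
        assert np.array_equal(m1.seqs, m2.seqs)
        assert np.array_equal(h1.site_rates, h2.site_rates)


class TestBacktranslate:
    def test_single_taxon_yields_no_vcfs(self, tmp_path):
        import dendropy

        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        msa, _ = evolve_alignment(tree, 20, None, seed=0)
        single = msa.take_columns(range(20))
        single.taxa = [single.taxa[0]]
        single.seqs = single.seqs[:1]
        em = backtranslate_and_emit(single, tmp_path, seed=1)
        assert em.vcfs == {}

    def test_one_residue_difference_yields_one_to_three_snvs(self, tmp_path):
        from enamelphylo.msa import ConcatenatedMSA

        msa = ConcatenatedMSA.from_rows({"A": "MKL", "B": "MRL"}, protein="p")
        em = backtranslate_and_emit(msa, tmp_path, seed=2)
        records = [
            line for line in em.vcfs["B"].read_text().splitlines()
            if line and not line.startswith("#")
        ]
        assert 1 <= len(records) <= 3

    def test_round_trip_through_proteome_prediction(self, tmp_path):
        from enamelphylo.predict import predict_proteome

        tree = simulate_yule_tree(5, 1.0, seed=2, height=0.4)
        msa, _ = evolve_alignment(
            tree, {"AMELX": 30, "ENAM": 50, "MMP20": 25}, 0.7, seed=5
        )
        em = backtranslate_and_emit(msa, tmp_path, seed=9)
        vcfs: dict = dict(em.vcfs)
        vcfs[em.reference_individual] = None
        result = predict_proteome(em.reference_fasta, em.gff, vcfs)
        assert result.errors == []
        for gene, (start, end) in msa.partitions.items():
            rows = result.rows_for_gene(gene)
            for i, taxon in enumerate(msa.taxa):
                assert rows[taxon] == "".join(msa.seqs[i, start:end])

    def test_gapped_alignment_rejected(self, tmp_path):
        from enamelphylo.msa import ConcatenatedMSA

        msa = ConcatenatedMSA.from_rows({"A": "M-L"})
        with pytest.raises(ValueError, match="gap-free"):
            backtranslate_and_emit(msa, tmp_path)


class TestAncientPeptides:
    def test_age_zero_tiles_full_protein(self):
        row = "MKWVTFISLLLLFSSAYS"
        ps = simulate_ancient_peptides(
            row, "ALB", 0.0, SurvivalParams(cleavage_rate=0.0), seed=0
        )
        recovered = sorted(
            (p.start, p.start + len(p.sequence)) for p in ps.peptides
        )
        covered = set()
        for s, e in recovered:
            covered.update(range(s, e))
        assert covered == set(range(len(row)))

    def test_zero_survival_probability_gives_empty_set(self):
        params = SurvivalParams(intercept_mean=-np.inf, intercept_sd=0.0)
        ps = simulate_ancient_peptides("MKWVTF", "ALB", 1.0, params, seed=1)
        assert ps.peptides == []

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            simulate_ancient_peptides("MKW", "ALB", -1.0, seed=0)

    def test_mean_coverage_strictly_decreasing_in_age(self):
        row = "MKWVTFISLLLLFSSAYSRGVFRRDTHKSEIAHRFKDLGEEHFKGLVLIAFSQYLQQCPF"
        means = []
        for age in (0.1, 1.5, 10.0):
            fractions = []
            for rep in range(100):
                ps = simulate_ancient_peptides(
                    row, "ALB", age, seed=rep + 17
                )
                covered = set()
                for p in ps.peptides:
                    covered.update(range(p.start, p.start + len(p.sequence)))
                fractions.append(len(covered) / len(row))
            means.append(np.mean(fractions))
        assert means[0] > means[1] > means[2]


def test_simulation_config_invariants():
    with pytest.raises(ValueError):
        SimulationConfig(n_taxa=2)
    with pytest.raises(ValueError):
        SimulationConfig(gamma_shape=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_sites_per_protein={"AMELX": 0})


def test_dataset_bitwise_reproducible():
    cfg = SimulationConfig(n_taxa=6, n_sites_per_protein={"ENAM": 40}, seed=5)
    d1 = simulate_dataset(cfg)
    d2 = simulate_dataset(cfg)
    assert tree_to_newick(d1.tree) == tree_to_newick(d2.tree)
    assert np.array_equal(d1.msa.seqs, d2.msa.seqs)
    assert np.array_equal(d1.history.site_rates, d2.history.site_rates)
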