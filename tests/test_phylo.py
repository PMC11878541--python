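import itertools
import math

import numpy as np
import pytest

from enamelphylo.models import GammaRateModel, SubstitutionModel
from enamelphylo.msa import ConcatenatedMSA
from enamelphylo.phylo import (
    DistanceMatrix,
    MissingDistanceError,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    nj_builder,
    pairwise_distance,
    pruning_loglik,
    site_log_likelihoods,
)
from enamelphylo.simulate import evolve_alignment, simulate_yule_tree
from enamelphylo.treecmp import rf_distance
from enamelphylo.trees import tree_from_newick

from conftest import additive_matrix, make_msa


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        assert pairwise_distance("ACDEF", "ACDEF") == 0.0

    def test_poisson_closed_form(self):
        a = "A" * 20
        b = "C" + "A" * 19
        assert pairwise_distance(a, b, "poisson") == pytest.approx(-math.log(0.95))

    def test_gamma_closed_form(self):
        a = "A" * 20
        b = "C" + "A" * 19
        assert pairwise_distance(a, b, "gamma", alpha=1.0) == pytest.approx(
            1 / 0.95 - 1
        )

    def test_missing_symbols_excluded_from_comparison(self):
        d, n, sat = pairwise_distance("AC-X?", "ACDEF", return_details=True)
        assert n == 2 and d == 0.0 and not sat

    def test_no_comparable_sites_raises(self):
        with pytest.raises(MissingDistanceError):
            pairwise_distance("--", "AC")

    def test_saturation_capped_and_flagged(self):
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = "CDEFGHIKLMNPQRSTVWYA"  # all 20 sites differ
        d, n, sat = pairwise_distance(a, b, "poisson", return_details=True)
        assert sat
        assert d == pytest.approx(-math.log(1 - 0.95 * 19 / 20))

    def test_corrections_monotone_in_p(self):
        ds = {c: [] for c in ("p", "poisson", "gamma")}
        for k in range(0, 18):
            a = "A" * 20
            b = "C" * k + "A" * (20 - k)
            for c in ds:
                ds[c].append(pairwise_distance(a, b, c, alpha=0.5))
        for c, vals in ds.items():
            assert all(x < y for x, y in zip(vals, vals[1:])), c

    def test_gamma_converges_to_poisson_for_large_alpha(self):
        a = "A" * 20
        b = "CCC" + "A" * 17
        g = pairwise_distance(a, b, "gamma", alpha=1e4)
        p = pairwise_distance(a, b, "poisson")
        assert abs(g - p) < 1e-4


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        )
        tree = neighbor_joining(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.3)

    def test_four_point_split_recovered(self):
        # additive matrix from ((A:1,B:2):1,(C:3,D:4))
        names = ["A", "B", "C", "D"]
        mat = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(names, mat))
        ref = tree_from_newick("((A,B),(C,D));")
        assert rf_distance(tree, ref) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_consistency_on_additive_matrices(self, seed):
        n = 4 + seed % 9  # 4..12 leaves
        true = simulate_yule_tree(n, 1.0, seed=seed)
        names, mat = additive_matrix(true)
        tree = neighbor_joining(DistanceMatrix(names, mat))
        assert rf_distance(tree, true) == 0

    def test_matches_scikit_bio_on_random_matrix(self):
        """Independent NJ implementation recovers the same topology."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(0)
        true = simulate_yule_tree(8, 1.0, seed=33)
        names, mat = additive_matrix(true)
        noisy = mat + rng.uniform(0, 0.01, mat.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        mine = neighbor_joining(DistanceMatrix(names, noisy))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=names))
        theirs_dp = tree_from_newick(str(theirs))
        assert rf_distance(mine, theirs_dp) == 0

    def test_missing_entries_error_names_pairs(self):
        mat = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(MissingDistanceError, match="A/C"):
            neighbor_joining(DistanceMatrix(["A", "B", "C"], mat))

    def test_deterministic_output(self):
        rng = np.random.default_rng(4)
        true = simulate_yule_tree(9, 1.0, seed=4)
        names, mat = additive_matrix(true)
        t1 = neighbor_joining(DistanceMatrix(names, mat.copy()))
        t2 = neighbor_joining(DistanceMatrix(names, mat.copy()))
        from enamelphylo.trees import tree_to_newick

        assert tree_to_newick(t1) == tree_to_newick(t2)


def brute_force_loglik(tree, msa, model=None, gamma_model=None):
    """Exhaustive sum over all internal-node state assignments (tiny trees)."""
    if model is None:
        model = SubstitutionModel()
    from enamelphylo.alphabet import AA_INDEX, N_STATES

    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    leaves = [nd for nd in nodes if nd.is_leaf()]
    rates = [1.0] if gamma_model is None else gamma_model.rates
    weights = [1.0] if gamma_model is None else gamma_model.weights
    total = 0.0
    for site in range(msa.width):
        obs = {
            id(lf): AA_INDEX.get(msa.row(lf.taxon.label)[site], -1) for lf in leaves
        }
        site_l = 0.0
        for rate, w in zip(rates, weights):
            pmat = {
                id(nd): model.transition_matrices(nd.edge.length * rate)
                for nd in nodes
                if nd.parent_node is not None
            }
            acc = 0.0
            for assign in itertools.product(range(N_STATES), repeat=len(internal)):
                states = {id(nd): s for nd, s in zip(internal, assign)}
                states.update({k: v for k, v in obs.items()})
                prob = model.freqs[states[id(tree.seed_node)]]
                for nd in nodes:
                    if nd.parent_node is None:
                        continue
                    s_child = states[id(nd)]
                    s_par = states[id(nd.parent_node)]
                    if s_child < 0:  # ambiguous leaf: marginalize
                        prob *= 1.0
                    else:
                        prob *= pmat[id(nd)][s_par, s_child]
                acc += prob
            site_l += w * acc
        total += math.log(site_l)
    return total


class TestPruningLikelihood:
    def test_two_taxa_same_residue_zero_length(self):
        msa = make_msa({"A": "A", "B": "A"})
        tree = tree_from_newick("(A:0.0,B:0.0);")
        assert pruning_loglik(tree, msa) == pytest.approx(math.log(1 / 20))

    def test_two_taxa_symmetric_closed_form(self):
        msa = make_msa({"A": "A", "B": "A"})
        tree = tree_from_newick("(A:0.05,B:0.05);")
        expected = math.log(0.05 * (0.05 + 0.95 * math.exp(-(20 / 19) * 0.1)))
        assert pruning_loglik(tree, msa) == pytest.approx(expected)

    def test_different_residues_approach_stationarity(self):
        msa = make_msa({"A": "A", "B": "C"})
        tree = tree_from_newick("(A:50.0,B:50.0);")
        assert pruning_loglik(tree, msa) == pytest.approx(
            math.log(0.05 * 0.05), abs=1e-6
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_enumeration(self, seed):
        tree = simulate_yule_tree(4, 1.0, seed=seed, height=0.4)
        msa, _ = evolve_alignment(tree, 3, 0.7, seed=seed + 50)
        mine = pruning_loglik(tree, msa)
        oracle = brute_force_loglik(tree, msa)
        assert mine == pytest.approx(oracle, abs=1e-8)

    def test_matches_brute_force_with_gamma_and_missing_data(self):
        tree = simulate_yule_tree(4, 1.0, seed=9, height=0.4)
        msa, _ = evolve_alignment(tree, 2, 0.7, seed=60)
        msa.seqs[0, 0] = "-"
        msa.seqs[2, 1] = "X"
        gm = GammaRateModel(alpha=0.5, k=4)
        assert pruning_loglik(tree, msa, gamma_model=gm) == pytest.approx(
            brute_force_loglik(tree, msa, gamma_model=gm), abs=1e-8
        )

    def test_site_likelihoods_shape_and_missing_contribution(self):
        tree = tree_from_newick("(A:0.1,B:0.1);")
        msa = make_msa({"A": "-?", "B": "X?"})
        logl = site_log_likelihoods(tree, msa, rates=[0.5, 1.0])
        # all-missing sites: sum over states of freqs = 1 -> log 1 = 0
        assert logl.shape == (2, 2)
        assert np.allclose(logl, 0.0)


class TestNNIHillClimb:
    def _setup(self):
        from enamelphylo.simulate import balanced_tree

        true = balanced_tree(8, 0.08)
        msa, _ = evolve_alignment(true, 800, None, seed=3)
        scrambled = tree_from_newick(
            "(((T1:0.08,T5:0.08):0.08,(T3:0.08,T4:0.08):0.08):0.08,"
            "((T2:0.08,T6:0.08):0.08,(T7:0.08,T8:0.08):0.08):0.08);"
        )
        return true, msa, scrambled

    def test_recovers_true_topology_from_scrambled_start(self):
        from enamelphylo.phylo import nni_hill_climb

        true, msa, scrambled = self._setup()
        out, ll = nni_hill_climb(scrambled, msa)
        assert rf_distance(out, true) == 0
        assert ll > pruning_loglik(scrambled, msa)

    def test_likelihood_never_decreases(self):
        from enamelphylo.phylo import nni_hill_climb

        true, msa, _ = self._setup()
        out, ll = nni_hill_climb(true, msa)
        assert ll >= pruning_loglik(true, msa) - 1e-9
        assert rf_distance(out, true) == 0

    def test_large_taxon_sets_refused(self):
        from enamelphylo.phylo import nni_hill_climb

        tree = simulate_yule_tree(31, 1.0, seed=0)
        msa, _ = evolve_alignment(tree, 10, None, seed=1)
        with pytest.raises(ValueError, match="limited"):
            nni_hill_climb(tree, msa)


class TestBootstrap:
    def _clean_msa(self):
        tree = simulate_yule_tree(8, 1.0, seed=21, height=0.4)
        msa, _ = evolve_alignment(tree, 2000, None, seed=22)
        return tree, msa

    def test_single_replicate_supports_are_binary(self):
        _, msa = self._clean_msa()
        res = bootstrap_support(msa, 1, seed=0)
        assert set(res.supports.values()) <= {0.0, 1.0}

    def test_true_bipartitions_strongly_supported_on_long_alignment(self):
        # balanced tree with no short internal branches: every split should
        # be recovered in essentially all replicates of a 2000-site alignment
        newick = (
            "(((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.1,"
            "((E:0.1,F:0.1):0.1,(G:0.1,H:0.1):0.1):0.1);"
        )
        tree = tree_from_newick(newick)
        msa, _ = evolve_alignment(tree, 2000, None, seed=22)
        res = bootstrap_support(msa, 50, seed=1)
        assert rf_distance(res.tree, tree) == 0
        assert all(v >= 0.95 for v in res.supports.values())

    def test_same_seed_reproducible(self):
        _, msa = self._clean_msa()
        r1 = bootstrap_support(msa, 10, seed=5)
        r2 = bootstrap_support(msa, 10, seed=5)
        assert r1.supports == r2.supports
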