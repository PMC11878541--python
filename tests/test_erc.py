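import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, kstest, norm

from enamelphylo.erc import (
    BranchRateTable,
    RelativeRates,
    erc_correlations,
    erc_permutation_test,
    fit_branch_lengths_ols,
    fit_branch_lengths_single,
    master_branch_ids,
    relative_rates,
    simulate_branch_rate_table,
)
from enamelphylo.phylo import DistanceMatrix
from enamelphylo.simulate import simulate_yule_tree
from enamelphylo.trees import tree_from_newick

from conftest import additive_matrix


class TestBranchLengthFit:
    def test_three_taxon_star_closed_form(self):
        tree = tree_from_newick("(A:1,B:1,C:1);")
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        )
        fitted = fit_branch_lengths_single(tree, dm)
        by_leaf = {min(k): v for k, v in fitted.items()}
        assert by_leaf["A"] == pytest.approx(0.1)
        assert by_leaf["B"] == pytest.approx(0.2)
        assert by_leaf["C"] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_matrix_recovered_exactly(self, seed):
        tree = simulate_yule_tree(6, 1.0, seed=seed)
        names, mat = additive_matrix(tree)
        table = fit_branch_lengths_ols(
            tree, {"g": DistanceMatrix(names, mat)}
        )
        # total fitted length equals total (derooted) tree length
        from enamelphylo.trees import derooted

        total_true = sum(
            e.length for e in derooted(tree).preorder_edge_iter() if e.length
        )
        assert table.lengths["g"].sum() == pytest.approx(total_true, abs=1e-9)
        assert table.lengths["g"].notna().all()

    def test_pruned_gene_marks_merged_branches_missing(self):
        tree = simulate_yule_tree(7, 1.0, seed=2)
        names, mat = additive_matrix(tree)
        full = DistanceMatrix(names, mat)
        keep = names[:-1]
        idx = [names.index(t) for t in keep]
        pruned = DistanceMatrix(keep, mat[np.ix_(idx, idx)])
        table = fit_branch_lengths_ols(tree, {"full": full, "part": pruned})
        assert table.lengths["full"].notna().all()
        assert table.lengths["part"].isna().sum() > 0
        # where defined, the pruned fit still matches the true lengths
        both = table.lengths.dropna()
        assert np.allclose(both["full"], both["part"], atol=1e-8)

    def test_underdetermined_system_rejected(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        dm = DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
        with pytest.raises(ValueError):
            fit_branch_lengths_single(tree, dm)


class TestRelativeRates:
    def _table(self, vec_a, vec_b):
        ids = [f"b{i}" for i in range(len(vec_a))]
        return BranchRateTable(pd.DataFrame({"g1": vec_a, "g2": vec_b}, index=ids))

    def test_identical_genes_all_ones(self):
        table = self._table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = relative_rates(table)
        assert np.allclose(out.rates.to_numpy(), 1.0)

    def test_uniform_twofold_gene(self):
        table = self._table([2.0, 4.0], [1.0, 2.0])
        out = relative_rates(table)
        assert np.allclose(out.rates["g1"], 4 / 3)
        assert np.allclose(out.rates["g2"], 2 / 3)

    def test_zero_mean_branch_excluded_and_reported(self):
        table = self._table([0.0, 1.0], [0.0, 1.0])
        out = relative_rates(table)
        assert out.excluded_branches == ["b0"]
        assert list(out.rates.index) == ["b1"]


class TestCorrelations:
    def _rates(self, x, y):
        ids = [f"b{i}" for i in range(len(x))]
        return RelativeRates(pd.DataFrame({"g1": x, "g2": y}, index=ids))

    def test_fisher_z_closed_form(self):
        # construct two vectors with an exact known correlation via regression
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        z = math.atanh(0.5) * math.sqrt(27)
        assert z == pytest.approx(2.8543, abs=1e-4)
        res = erc_correlations(self._rates(x, x + rng.normal(size=30)))
        (r,) = res.results
        assert r.z == pytest.approx(math.atanh(r.r) * math.sqrt(r.n - 3))

    def test_zero_correlation_gives_zero_z(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 1.0])  # orthogonal to x around means
        res = erc_correlations(self._rates(x, y))
        (r,) = res.results
        assert r.r == pytest.approx(0.0, abs=1e-12)
        assert r.z == pytest.approx(0.0, abs=1e-12)

    def test_identical_vectors_capped_and_flagged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = erc_correlations(self._rates(x, x.copy()))
        (r,) = res.results
        assert r.capped
        assert math.isfinite(r.z)

    def test_too_few_shared_branches_not_computable(self):
        x = np.array([1.0, 2.0, 3.0])
        res = erc_correlations(self._rates(x, x))
        assert res.results == []
        assert "shared branches" in res.not_computable[0][2]

    def test_fisher_z_standard_normal_under_independence(self):
        """z from independent bivariate-normal samples is ~N(0,1) (KS < 0.1)."""
        rng = np.random.default_rng(7)
        zs = []
        for _ in range(1000):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            r = np.corrcoef(x, y)[0, 1]
            zs.append(math.atanh(r) * math.sqrt(47))
        stat = kstest(zs, norm.cdf).statistic
        assert stat < 0.1


class TestPermutationTest:
    def _pool(self, seed, shared_sigma=0.0, shared=()):
        topo = simulate_yule_tree(27, 1.0, seed=99, height=1.0)
        table = simulate_branch_rate_table(
            topo, 20, seed=seed, shared_sigma=shared_sigma, shared_genes=shared
        )
        return relative_rates(table)

    def test_minimum_attainable_p(self):
        shared = ("g000", "g001", "g002", "g003")
        rates = self._pool(1, shared_sigma=1.0, shared=shared)
        res = erc_permutation_test(list(shared), rates, n_perm=200, seed=0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_shared_multiplier_genes_detected(self):
        shared = ("g000", "g001", "g002", "g003")
        rates = self._pool(2, shared_sigma=0.5, shared=shared)
        res = erc_permutation_test(list(shared), rates, n_perm=1000, seed=3)
        assert res.p_value <= 0.01

    def test_pool_must_exceed_focal_set(self):
        rates = self._pool(3)
        with pytest.raises(ValueError, match="pool"):
            erc_permutation_test(list(rates.rates.columns), rates, n_perm=10)

    def test_reproducible_under_seed(self):
        rates = self._pool(4)
        a = erc_permutation_test(["g000", "g001", "g002"], rates, n_perm=100, seed=9)
        b = erc_permutation_test(["g000", "g001", "g002"], rates, n_perm=100, seed=9)
        assert a.p_value == b.p_value


class TestNullBehaviour:
    def test_independent_genes_mean_z_matches_finite_pool_expectation(self):
        """Without covariation, mean pairwise z equals the compositional bias.

        Relative rates are deviations of each gene from the G-gene branch
        mean, so independent genes correlate at exactly -1/(G-1); the
        mean z therefore sits at atanh(-1/(G-1)) * sqrt(n-3) and shrinks
        toward zero as the gene pool grows.
        """
        topo = simulate_yule_tree(27, 1.0, seed=42, height=1.0)  # 51 branches
        observed = {}
        for n_genes in (20, 60):
            zs = []
            for seed in range(5):
                rates = relative_rates(
                    simulate_branch_rate_table(topo, n_genes, seed=seed)
                )
                res = erc_correlations(rates)
                zs.append(np.mean([r.z for r in res.results]))
            observed[n_genes] = np.mean(zs)
            expected = math.atanh(-1 / (n_genes - 1)) * math.sqrt(51 - 3)
            assert observed[n_genes] == pytest.approx(expected, abs=0.15)
        assert abs(observed[60]) < 0.3  # bias vanishes with pool size

    def test_shared_genes_have_higher_mean_z_than_independent(self):
        """Paired simulations; one-sided sign test at p < 0.01."""
        topo = simulate_yule_tree(27, 1.0, seed=43, height=1.0)
        wins = 0
        n_pairs = 12
        shared = ("g000", "g001", "g002", "g003")

        def mean_z_within(rates, genes):
            res = erc_correlations(rates)
            vals = [
                r.z for r in res.results if r.gene_a in genes and r.gene_b in genes
            ]
            return np.mean(vals)

        for seed in range(n_pairs):
            t_null = simulate_branch_rate_table(topo, 20, seed=seed)
            t_cov = simulate_branch_rate_table(
                topo, 20, seed=seed, shared_sigma=0.5, shared_genes=shared
            )
            z_null = mean_z_within(relative_rates(t_null), shared)
            z_cov = mean_z_within(relative_rates(t_cov), shared)
            wins += z_cov > z_null
        assert binomtest(wins, n_pairs, alternative="greater").pvalue < 0.01
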