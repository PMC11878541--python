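"""Evolutionary Rate Covariation on a simulated gene pool.

Twenty genes evolve on a shared 27-taxon topology; four of them share a
per-branch rate multiplier (genuine covariation). Pairwise ERC z-scores
and a mean-statistic permutation test recover the planted signal.
"""

import numpy as np

from enamelphylo.erc import (
    erc_correlations,
    erc_permutation_test,
    relative_rates,
    simulate_branch_rate_table,
)
from enamelphylo.simulate import simulate_yule_tree

topology = simulate_yule_tree(27, birth_rate=1.0, seed=5, height=1.0)
shared = ("g000", "g001", "g002", "g003")
table = simulate_branch_rate_table(
    topology, n_genes=20, seed=1, shared_sigma=0.5, shared_genes=shared
)
rates = relative_rates(table)
erc = erc_correlations(rates)

zmat = erc.z_matrix()
within = [r.z for r in erc.results if r.gene_a in shared and r.gene_b in shared]
between = [r.z for r in erc.results
           if (r.gene_a in shared) != (r.gene_b in shared)]
print(f"{len(erc.results)} gene pairs over {len(rates.rates)} shared branches")
print(f"mean Fisher z within the covarying set:  {np.mean(within):+.2f}")
print(f"mean Fisher z set vs independent genes: {np.mean(between):+.2f}")

res = erc_permutation_test(list(shared), rates, n_perm=10_000, seed=2)
print(f"permutation test (mean statistic, {res.n_perm} permutations): "
      f"observed mean z = {res.observed:.2f}, p = {res.p_value:.4f}")
print("p near the 1/(n_perm+1) floor indicates covariation beyond random gene sets")
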