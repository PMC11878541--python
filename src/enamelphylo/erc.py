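"""Evolutionary Rate Covariation (ERC) on a shared topology.

Per gene, branch lengths are fitted to the gene's corrected distance
matrix on the (per-gene pruned) master topology by ordinary least
squares over the path-incidence system. Branch-specific *relative*
rates divide each branch length by that branch's across-gene mean, so
genome-wide rate variation cancels and what remains is gene-specific
acceleration or deceleration per branch. For a gene pair, ERC is the
Pearson correlation of relative rates over the branches both genes
share; the Fisher transform ``z = atanh(r) * sqrt(n - 3)`` normalizes
for the number of contributing branches. Significance of elevated
covariation within a focal gene set uses a permutation test with the
mean pairwise z as statistic against random same-size gene sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .phylo import DistanceMatrix
from .trees import derooted, leaves_below

R_CAP = 0.999999


def _branch_id(side: frozenset[str], all_leaves: frozenset[str]) -> str:
    min_leaf = min(all_leaves)
    canonical = side if min_leaf not in side else all_leaves - side
    return "|".join(sorted(canonical))


def master_branch_ids(topology: dendropy.Tree) -> dict[str, frozenset[str]]:
    """Canonical id -> leaf-set-below for every edge of the master topology."""
    topology = derooted(topology)
    all_leaves = frozenset(lf.taxon.label for lf in topology.leaf_node_iter())
    ids: dict[str, frozenset[str]] = {}
    for node in topology.postorder_node_iter():
        if node is topology.seed_node:
            continue
        below = leaves_below(node)
        if 0 < len(below) < len(all_leaves):
            ids[_branch_id(below, all_leaves)] = below
    return ids


@dataclass
class BranchRateTable:
    """Branches (rows) x genes (columns); NaN marks missing branches."""

    lengths: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.lengths.columns)

    @property
    def branch_ids(self) -> list[str]:
        return list(self.lengths.index)

    def to_tsv(self, path) -> None:
        self.lengths.to_csv(path, sep="\t")


def fit_branch_lengths_single(
    topology: dendropy.Tree, dm: DistanceMatrix
) -> dict[frozenset[str], float]:
    """OLS branch lengths of one tree against a distance matrix.

    Solves the path-incidence least-squares system (a pair's distance is
    the sum of the branch lengths separating it); negative estimates are
    clamped to zero. Raises if the system is underdetermined.
    """
    topology = derooted(topology)
    leaves = [lf.taxon.label for lf in topology.leaf_node_iter()]
    missing = [t for t in leaves if t not in dm.names]
    if missing:
        raise ValueError(f"distance matrix lacks taxa {missing}")
    name_idx = {t: i for i, t in enumerate(dm.names)}
    edges = []
    for node in topology.postorder_node_iter():
        if node is topology.seed_node:
            continue
        below = leaves_below(node)
        if 0 < len(below) < len(leaves):
            edges.append(below)
    pairs = list(itertools.combinations(sorted(leaves), 2))
    if len(pairs) < len(edges):
        raise ValueError("underdetermined: fewer taxon pairs than branches")
    a = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for pi, (x, y) in enumerate(pairs):
        d[pi] = dm.matrix[name_idx[x], name_idx[y]]
        for ei, below in enumerate(edges):
            if (x in below) != (y in below):
                a[pi, ei] = 1.0
    if not np.isfinite(d).all():
        raise ValueError("distance matrix has missing entries for tree taxa")
    if np.linalg.matrix_rank(a) < len(edges):
        raise ValueError("underdetermined path-incidence system")
    sol, *_ = np.linalg.lstsq(a, d, rcond=None)
    return {below: max(float(v), 0.0) for below, v in zip(edges, sol)}


def fit_branch_lengths_ols(
    topology: dendropy.Tree, per_gene: dict[str, DistanceMatrix]
) -> BranchRateTable:
    """Per-gene OLS branch lengths on the master topology.

    Genes missing taxa are fitted on the pruned topology; a master branch
    whose bipartition is no longer uniquely identifiable after pruning
    (merged or degenerate) stays missing for that gene.
    """
    topology = derooted(topology)
    all_leaves = frozenset(lf.taxon.label for lf in topology.leaf_node_iter())
    master = master_branch_ids(topology)
    table = pd.DataFrame(np.nan, index=sorted(master), columns=sorted(per_gene))
    for gene, dm in per_gene.items():
        gene_taxa = frozenset(dm.names) & all_leaves
        if len(gene_taxa) < 4:
            continue
        if gene_taxa == all_leaves:
            sub = topology
        else:
            sub = topology.extract_tree_with_taxa_labels(sorted(gene_taxa))
        fitted = fit_branch_lengths_single(sub, dm)

        def restrict(side: frozenset[str]) -> frozenset[str] | None:
            r = side & gene_taxa
            if 0 < len(r) < len(gene_taxa):
                min_leaf = min(gene_taxa)
                return r if min_leaf not in r else gene_taxa - r
            return None

        fitted_by_split = {restrict(below): v for below, v in fitted.items()}
        groups: dict[frozenset[str], list[str]] = {}
        for bid, below in master.items():
            r = restrict(below)
            if r is not None:
                groups.setdefault(r, []).append(bid)
        for split, bids in groups.items():
            if len(bids) == 1 and split in fitted_by_split:
                table.loc[bids[0], gene] = fitted_by_split[split]
    return BranchRateTable(table)


@dataclass
class RelativeRates:
    rates: pd.DataFrame
    excluded_branches: list[str] = field(default_factory=list)


def relative_rates(table: BranchRateTable) -> RelativeRates:
    """Branch length divided by that branch's mean over genes present.

    Branches whose across-gene mean is zero (or that no gene covers) are
    excluded and reported.
    """
    if len(table.genes) < 2:
        raise ValueError("relative rates need at least two genes")
    means = table.lengths.mean(axis=1, skipna=True)
    bad = means.index[(means.isna()) | (means <= 0)].tolist()
    kept = table.lengths.drop(index=bad)
    if kept.empty:
        raise ValueError("no shareable branch with positive mean length")
    rates = kept.div(means.drop(bad), axis=0)
    return RelativeRates(rates, bad)


@dataclass
class ERCResult:
    gene_a: str
    gene_b: str
    r: float
    n: int
    z: float
    capped: bool = False


@dataclass
class ERCResultSet:
    results: list[ERCResult]
    not_computable: list[tuple[str, str, str]] = field(default_factory=list)

    def z_matrix(self) -> pd.DataFrame:
        genes = sorted({g for res in self.results for g in (res.gene_a, res.gene_b)})
        m = pd.DataFrame(np.nan, index=genes, columns=genes)
        for res in self.results:
            m.loc[res.gene_a, res.gene_b] = res.z
            m.loc[res.gene_b, res.gene_a] = res.z
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])


def erc_correlations(rates: RelativeRates | pd.DataFrame, min_branches: int = 4) -> ERCResultSet:
    """Pairwise ERC over shared branches with Fisher-transformed z.

    r is the Pearson correlation of two genes' relative rates over the
    branches both cover (at least ``min_branches``); it is capped at
    +/-0.999999 before ``z = atanh(r) * sqrt(n - 3)``.
    """
    df = rates.rates if isinstance(rates, RelativeRates) else rates
    results = []
    skipped = []
    for ga, gb in itertools.combinations(sorted(df.columns), 2):
        both = df[[ga, gb]].dropna()
        n = len(both)
        if n < min_branches:
            skipped.append((ga, gb, f"only {n} shared branches"))
            continue
        x = both[ga].to_numpy()
        y = both[gb].to_numpy()
        if x.std() == 0 or y.std() == 0:
            skipped.append((ga, gb, "zero variance in shared branch rates"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        capped = abs(r) > R_CAP
        r_eff = max(min(r, R_CAP), -R_CAP)
        z = math.atanh(r_eff) * math.sqrt(n - 3)
        results.append(ERCResult(ga, gb, r, n, z, capped))
    return ERCResultSet(results, skipped)


def simulate_branch_rate_table(
    topology: dendropy.Tree,
    n_genes: int,
    seed: int = 0,
    gene_noise_sigma: float = 0.5,
    shared_sigma: float = 0.0,
    shared_genes: tuple[str, ...] = (),
    gene_names: list[str] | None = None,
) -> BranchRateTable:
    """Simulated per-gene branch lengths for ERC calibration and power.

    Each gene's branch lengths are the topology's lengths times
    independent lognormal(0, ``gene_noise_sigma``) noise per branch.
    Genes named in ``shared_genes`` additionally share one common
    per-branch lognormal(0, ``shared_sigma``) multiplier, inducing
    genuine rate covariation among them; with ``shared_sigma=0`` all
    genes evolve independently (the null).
    """
    topo = derooted(topology)
    all_leaves = frozenset(lf.taxon.label for lf in topo.leaf_node_iter())
    base: dict[str, float] = {}
    for node in topo.postorder_node_iter():
        if node is topo.seed_node:
            continue
        below = leaves_below(node)
        if 0 < len(below) < len(all_leaves):
            base[_branch_id(below, all_leaves)] = float(node.edge.length or 0.0)
    branch_ids = sorted(base)
    base_vec = np.array([base[b] for b in branch_ids])
    rng = np.random.default_rng(seed)
    if gene_names is None:
        gene_names = [f"g{i:03d}" for i in range(n_genes)]
    shared_mult = np.exp(rng.normal(0.0, shared_sigma, size=len(branch_ids)))
    data = {}
    for g in gene_names:
        lengths = base_vec * np.exp(
            rng.normal(0.0, gene_noise_sigma, size=len(branch_ids))
        )
        if g in shared_genes:
            lengths = lengths * shared_mult
        data[g] = lengths
    return BranchRateTable(pd.DataFrame(data, index=branch_ids))


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_perm: int
    null_mean: float
    null_sd: float


def erc_permutation_test(
    focal_genes: list[str],
    rates: RelativeRates | pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    min_branches: int = 4,
) -> PermutationResult:
    """Is mean pairwise z within the focal set elevated over random sets?

    The null draws same-size gene subsets uniformly from the full pool;
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``, so the smallest
    attainable p is ``1/(n_perm+1)``.
    """
    df = rates.rates if isinstance(rates, RelativeRates) else rates
    pool = sorted(df.columns)
    focal = sorted(focal_genes)
    if not set(focal) <= set(pool):
        raise ValueError("focal genes must be part of the rate table")
    if len(pool) <= len(focal):
        raise ValueError("gene pool must be larger than the focal set")
    erc = erc_correlations(RelativeRates(df), min_branches=min_branches)
    zmat = erc.z_matrix().reindex(index=pool, columns=pool).to_numpy()
    gene_idx = {g: i for i, g in enumerate(pool)}

    def mean_pairwise(genes: list[str]) -> float:
        idx = [gene_idx[g] for g in genes]
        vals = zmat[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("no computable pair within the gene set")
        return float(vals.mean())

    observed = mean_pairwise(focal)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    pool_arr = np.array(pool)
    for i in range(n_perm):
        subset = pool_arr[rng.choice(len(pool_arr), size=len(focal), replace=False)]
        null[i] = mean_pairwise(list(subset))
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationResult(observed, p, n_perm, float(null.mean()), float(null.std()))
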