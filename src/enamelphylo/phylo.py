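"""Compact phylogenetic engine for protein supermatrices.

Four pieces: corrected pairwise distances over comparable sites,
deterministic neighbor joining, Felsenstein pruning likelihood on a fixed
topology (optionally mixed over discrete-gamma rate categories), and a
nonparametric column bootstrap.

Missing characters ('-', 'X', '?') are excluded from distance comparisons
and contribute a vector of ones to the pruning partials, i.e. they are
treated as fully ambiguous observations rather than as a 21st state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np

from .alphabet import AA_INDEX, N_STATES
from .models import GammaRateModel, SubstitutionModel
from .msa import ConcatenatedMSA

#: observed p-distances at or above this value are treated as saturated and
#: capped before distance correction (95% of the maximal expected 19/20)
P_SATURATION = 0.95 * (N_STATES - 1) / N_STATES


class MissingDistanceError(ValueError):
    """Raised when taxon pairs share no comparable alignment column."""

    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs = pairs
        super().__init__(
            "no comparable sites for taxon pair(s): "
            + ", ".join(f"{a}/{b}" for a, b in pairs)
        )


@dataclass
class DistanceMatrix:
    """Symmetric corrected-distance matrix with per-pair site counts."""

    names: list[str]
    matrix: np.ndarray
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.names)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match taxon count")
        if self.counts is None:
            self.counts = np.zeros((n, n), dtype=np.int64)
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)

    @property
    def missing_pairs(self) -> list[tuple[str, str]]:
        bad = []
        for i, j in itertools.combinations(range(len(self.names)), 2):
            if not np.isfinite(self.matrix[i, j]):
                bad.append((self.names[i], self.names[j]))
        return bad

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.names)}\n")
            for i, name in enumerate(self.names):
                row = " ".join(f"{v:.8f}" for v in self.matrix[i])
                fh.write(f"{name}  {row}\n")


def _correct(p: float, correction: str, alpha: float | None) -> tuple[float, bool]:
    saturated = p >= P_SATURATION
    p_eff = min(p, P_SATURATION)
    if correction == "p":
        return p_eff, saturated
    if correction == "poisson":
        return -math.log(1.0 - p_eff), saturated
    if correction == "gamma":
        if alpha is None or alpha <= 0:
            raise ValueError("gamma correction requires a positive alpha")
        return alpha * ((1.0 - p_eff) ** (-1.0 / alpha) - 1.0), saturated
    raise ValueError(f"unknown correction {correction!r}")


def pairwise_distance(
    row_a: str | Sequence[str],
    row_b: str | Sequence[str],
    correction: str = "poisson",
    alpha: float | None = None,
    return_details: bool = False,
):
    """Corrected distance between two aligned rows.

    Comparable sites are those where neither row has '-', 'X' or '?'.
    ``correction`` is one of ``p`` (raw proportion), ``poisson``
    (d = -ln(1-p)) or ``gamma`` (d = alpha((1-p)^(-1/alpha) - 1)).
    Saturated pairs (p at the 19/20 ceiling) are capped and flagged.
    """
    a = np.array(list(row_a), dtype="<U1")
    b = np.array(list(row_b), dtype="<U1")
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    ia = np.array([AA_INDEX.get(c, -1) for c in a])
    ib = np.array([AA_INDEX.get(c, -1) for c in b])
    valid = (ia >= 0) & (ib >= 0)
    n_comp = int(valid.sum())
    if n_comp == 0:
        raise MissingDistanceError([("row_a", "row_b")])
    p = float((ia[valid] != ib[valid]).mean())
    d, saturated = _correct(p, correction, alpha)
    if return_details:
        return d, n_comp, saturated
    return d


def distance_matrix(
    msa: ConcatenatedMSA, correction: str = "poisson", alpha: float | None = None
) -> DistanceMatrix:
    """All-pairs corrected distances; incomparable pairs become NaN."""
    n = msa.n_taxa
    enc = np.array(
        [[AA_INDEX.get(c, -1) for c in row] for row in msa.seqs], dtype=np.int64
    )
    mat = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    sat = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        valid = (enc[i] >= 0) & (enc[j] >= 0)
        n_comp = int(valid.sum())
        counts[i, j] = counts[j, i] = n_comp
        if n_comp == 0:
            mat[i, j] = mat[j, i] = np.nan
            continue
        p = float((enc[i, valid] != enc[j, valid]).mean())
        d, s = _correct(p, correction, alpha)
        mat[i, j] = mat[j, i] = d
        sat[i, j] = sat[j, i] = s
    return DistanceMatrix(list(msa.taxa), mat, counts, sat)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is joined at each step; exact ties
    are resolved by the lexicographically smallest (cluster-name) pair,
    where a cluster is named by its smallest contained leaf. Negative
    branch-length estimates are clamped to zero. Requires a complete
    matrix on at least three taxa.
    """
    if len(dm.names) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    missing = dm.missing_pairs
    if missing:
        raise MissingDistanceError(missing)

    tns = dendropy.TaxonNamespace(sorted(dm.names))
    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for name in dm.names:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(node)
        keys.append(name)
    d = dm.matrix.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        # only the upper triangle is inspected: q is symmetric up to
        # floating-point summation order
        iu = np.triu_indices(m, 1)
        qmin = q[iu].min()
        best = None
        for i, j in itertools.combinations(range(m), 2):
            if q[i, j] == qmin:
                key = tuple(sorted((keys[i], keys[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best  # type: ignore[misc]
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        new = dendropy.Node()
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        d_new = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], d_new[keep][None, :]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final three clusters joined at a central node (three-point formulas)
    center = dendropy.Node()
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def _encode_for_tree(tree: dendropy.Tree, msa: ConcatenatedMSA) -> tuple[list, np.ndarray]:
    """Leaf order and integer state matrix (-1 = ambiguous) for the tree."""
    leaves = list(tree.leaf_node_iter())
    rows = []
    for lf in leaves:
        name = lf.taxon.label
        if name not in msa.taxa:
            raise ValueError(f"tree leaf {name!r} not present in alignment")
        rows.append([AA_INDEX.get(c, -1) for c in msa.row(name)])
    return leaves, np.asarray(rows, dtype=np.int64)


def site_log_likelihoods(
    tree: dendropy.Tree,
    msa: ConcatenatedMSA,
    model: SubstitutionModel | None = None,
    rates: Sequence[float] = (1.0,),
) -> np.ndarray:
    """Per-site log-likelihoods under one or more rate multipliers.

    Felsenstein pruning with per-node rescaling; identical site patterns
    are collapsed before the tree pass and expanded afterwards. Returns an
    array of shape ``(len(rates), n_sites)``.
    """
    if model is None:
        model = SubstitutionModel()
    rates = np.asarray(rates, dtype=float)
    leaves, states = _encode_for_tree(tree, msa)
    patterns, inverse = np.unique(states.T, axis=0, return_inverse=True)
    n_pat = patterns.shape[0]
    n_rates = len(rates)

    leaf_index = {id(lf): i for i, lf in enumerate(leaves)}
    partials: dict[int, np.ndarray] = {}
    scales: dict[int, np.ndarray] = {}

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            st = patterns[:, leaf_index[id(node)]]
            part = np.zeros((n_pat, N_STATES))
            amb = st < 0
            part[np.arange(n_pat)[~amb], st[~amb]] = 1.0
            part[amb] = 1.0
            partials[id(node)] = np.broadcast_to(part, (n_rates, n_pat, N_STATES)).copy()
            scales[id(node)] = np.zeros((n_rates, n_pat))
            continue
        part = np.ones((n_rates, n_pat, N_STATES))
        scale = np.zeros((n_rates, n_pat))
        for child in node.child_nodes():
            b = child.edge.length
            if b is None:
                raise ValueError("tree has an unset branch length")
            if b < 0:
                raise ValueError("tree has a negative branch length")
            p_mats = model.transition_matrices(b * rates)  # (n_rates, 20, 20)
            msg = np.einsum("rij,rpj->rpi", p_mats, partials.pop(id(child)))
            part *= msg
            scale += scales.pop(id(child))
        mx = part.max(axis=2)
        safe = np.where(mx > 0, mx, 1.0)
        part /= safe[:, :, None]
        with np.errstate(divide="ignore"):
            scale += np.where(mx > 0, np.log(safe), -np.inf)
        partials[id(node)] = part
        scales[id(node)] = scale

    root = tree.seed_node
    site_l = partials[id(root)] @ model.freqs  # (n_rates, n_pat)
    with np.errstate(divide="ignore"):
        logl = np.log(site_l) + scales[id(root)]
    return logl[:, inverse]


def pruning_loglik(
    tree: dendropy.Tree,
    msa: ConcatenatedMSA,
    model: SubstitutionModel | None = None,
    gamma_model: GammaRateModel | None = None,
) -> float:
    """Total log-likelihood of the alignment on a fixed tree.

    With a :class:`GammaRateModel`, per-site likelihoods are averaged over
    the discrete rate categories before taking logs.
    """
    if gamma_model is None:
        logl = site_log_likelihoods(tree, msa, model, rates=[1.0])[0]
        total = float(logl.sum())
    else:
        cat = site_log_likelihoods(tree, msa, model, rates=gamma_model.rates)
        mx = cat.max(axis=0)
        mix = np.log(
            (gamma_model.weights[:, None] * np.exp(cat - mx[None, :])).sum(axis=0)
        ) + mx
        total = float(mix.sum())
    if not np.isfinite(total):
        raise ValueError("non-finite likelihood (conflicting data on zero-length tree?)")
    return total


def nni_hill_climb(
    tree: dendropy.Tree,
    msa: ConcatenatedMSA,
    model: SubstitutionModel | None = None,
    gamma_model: GammaRateModel | None = None,
    max_rounds: int = 10,
    max_taxa: int = 30,
) -> tuple[dendropy.Tree, float]:
    """Greedy nearest-neighbour-interchange search on pruning likelihood.

    Starting from the given tree (typically the NJ estimate), each
    internal edge's two NNI alternatives are scored with branch lengths
    held fixed; improving swaps are kept until a full round yields none.
    Intended as a small-scale refinement only (``max_taxa`` guard).
    """
    n_taxa = sum(1 for _ in tree.leaf_node_iter())
    if n_taxa > max_taxa:
        raise ValueError(f"NNI search is limited to {max_taxa} taxa (got {n_taxa})")
    tree = tree.clone(depth=1)
    best = pruning_loglik(tree, msa, model, gamma_model)

    for _ in range(max_rounds):
        improved = False
        for v in list(tree.preorder_internal_node_iter()):
            u = v.parent_node
            if u is None or v.is_leaf():
                continue
            siblings = [c for c in u.child_nodes() if c is not v]
            if not siblings:
                continue
            sib = siblings[0]
            for b in list(v.child_nodes()):
                # exchange subtree b (below v) with the sibling of v
                v.remove_child(b)
                u.remove_child(sib)
                v.add_child(sib)
                u.add_child(b)
                score = pruning_loglik(tree, msa, model, gamma_model)
                if score > best + 1e-9:
                    best = score
                    improved = True
                    break
                # revert
                v.remove_child(sib)
                u.remove_child(b)
                v.add_child(b)
                u.add_child(sib)
        if not improved:
            break
    return tree, best


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    tree: dendropy.Tree
    supports: dict[frozenset[str], float]
    n_replicates: int
    n_skipped: int


def nj_builder(correction: str = "poisson", alpha: float | None = None) -> Callable:
    """Distance + neighbor-joining tree builder usable with the bootstrap."""

    def build(msa: ConcatenatedMSA) -> dendropy.Tree:
        return neighbor_joining(distance_matrix(msa, correction, alpha))

    return build


def bootstrap_support(
    msa: ConcatenatedMSA,
    n_replicates: int,
    builder: Callable | None = None,
    seed: int = 0,
) -> BootstrapResult:
    """Nonparametric column bootstrap on any msa -> tree builder.

    Columns are resampled with replacement; the support of a bipartition
    of the point-estimate tree is the fraction of successful replicates
    whose tree contains it. Replicates whose resampled columns leave some
    taxon pair with no comparable sites are skipped and counted.
    """
    from .treecmp import bipartitions

    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    if builder is None:
        builder = nj_builder()
    rng = np.random.default_rng(seed)
    main_tree = builder(msa)
    target = bipartitions(main_tree)
    hits = {bp: 0 for bp in target}
    n_skipped = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, msa.width, size=msa.width)
        rep = ConcatenatedMSA(
            list(msa.taxa),
            msa.seqs[:, idx],
            {"resampled": (0, msa.width)},
            msa.col_sources[idx],
        )
        try:
            rep_tree = builder(rep)
        except MissingDistanceError:
            n_skipped += 1
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
    n_ok = n_replicates - n_skipped
    supports = {bp: (hits[bp] / n_ok if n_ok else float("nan")) for bp in target}

    from .trees import leaves_below

    n_total = len(msa.taxa)
    all_leaves = frozenset(t for t in msa.taxa if t in {lf.taxon.label for lf in main_tree.leaf_node_iter()})
    min_leaf = min(all_leaves)
    for node in main_tree.postorder_internal_node_iter():
        if node is main_tree.seed_node:
            continue
        below = leaves_below(node)
        side = below if min_leaf not in below else all_leaves - below
        if 2 <= len(side) <= n_total - 2 and side in supports:
            node.label = f"{supports[side]:.3f}"
    return BootstrapResult(main_tree, supports, n_replicates, n_skipped)
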