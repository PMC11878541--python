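"""Tree comparison: Robinson–Foulds distance and rank-level monophyly.

Trees are compared topology-only on their shared leaf set. A bipartition
is the pair of leaf sets separated by an internal edge of the unrooted
tree; it is stored canonically as the side *not* containing the
lexicographically smallest leaf, and only non-trivial splits (both sides
with at least two leaves) are counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from .trees import leaves_below


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (implicitly unrooted) tree."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(leaves)
    if n < 4:
        return set()
    min_leaf = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.postorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        below = leaves_below(node)
        side = below if min_leaf not in below else leaves - below
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Robinson–Foulds distance: bipartitions unique to either tree.

    Branch lengths and rootings are ignored. Raises on unequal leaf sets,
    listing the symmetric difference.
    """
    leaves_a = frozenset(lf.taxon.label for lf in tree_a.leaf_node_iter())
    leaves_b = frozenset(lf.taxon.label for lf in tree_b.leaf_node_iter())
    if leaves_a != leaves_b:
        diff = sorted(leaves_a.symmetric_difference(leaves_b))
        raise ValueError(f"leaf sets differ; symmetric difference: {diff}")
    bp_a = bipartitions(tree_a)
    bp_b = bipartitions(tree_b)
    return len(bp_a.symmetric_difference(bp_b))


@dataclass
class TaxonomyMap:
    """Species -> rank assignments (genus, family, ...)."""

    table: pd.DataFrame  # index: species; columns: rank names

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df.set_index(df.columns[0]))

    @classmethod
    def from_dict(cls, mapping: dict[str, dict[str, str]]) -> "TaxonomyMap":
        return cls(pd.DataFrame.from_dict(mapping, orient="index"))

    @property
    def ranks(self) -> list[str]:
        return list(self.table.columns)

    def group_of(self, species: str, rank: str) -> str:
        try:
            value = self.table.loc[species, rank]
        except KeyError:
            raise KeyError(f"species {species!r} missing from taxonomy") from None
        if pd.isna(value) or value == "":
            raise ValueError(f"species {species!r} has empty {rank!r} assignment")
        return str(value)


@dataclass
class MonophylyReport:
    rank: str
    groups: dict[str, tuple[bool, int]]  # group -> (monophyletic, n leaves)
    fraction_monophyletic: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"group": g, "monophyletic": flag, "n_leaves": n}
                for g, (flag, n) in sorted(self.groups.items())
            ]
        )


def check_rank_monophyly(
    tree: dendropy.Tree, taxonomy: TaxonomyMap, rank: str
) -> MonophylyReport:
    """Is each taxonomic group at the given rank an exclusive clade?

    On the unrooted tree, a group is monophyletic when some edge induces
    exactly its leaf set. Singleton groups (and groups covering all, or
    all-but-one, leaves) are trivially monophyletic.
    """
    if rank not in taxonomy.ranks:
        raise ValueError(f"rank {rank!r} not in taxonomy columns {taxonomy.ranks}")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    n = len(leaves)
    groups: dict[str, set[str]] = {}
    for leaf in leaves:
        groups.setdefault(taxonomy.group_of(leaf, rank), set()).add(leaf)
    bps = bipartitions(tree)
    all_leaves = frozenset(leaves)
    min_leaf = min(all_leaves)
    result: dict[str, tuple[bool, int]] = {}
    for group, members in groups.items():
        k = len(members)
        if k <= 1 or k >= n - 1:
            result[group] = (True, k)
            continue
        side = frozenset(members)
        canonical = side if min_leaf not in side else all_leaves - side
        result[group] = (canonical in bps, k)
    frac = sum(1 for flag, _ in result.values() if flag) / len(result)
    return MonophylyReport(rank, result, frac)
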