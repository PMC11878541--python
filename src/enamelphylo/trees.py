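"""Thin helpers around dendropy trees (newick I/O, leaf access)."""

from __future__ import annotations

import dendropy


def tree_from_newick(newick: str, rooted: bool | None = None) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def tree_from_file(path, rooted: bool | None = None) -> dendropy.Tree:
    with open(path) as fh:
        return tree_from_newick(fh.read(), rooted=rooted)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def leaves_below(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def derooted(tree: dendropy.Tree) -> dendropy.Tree:
    """Copy of the tree with any basal bifurcation collapsed (seed degree 3).

    The two edges incident to a root of degree two describe the same
    unrooted branch; their lengths are summed onto the surviving edge.
    """
    t = tree.clone(depth=1)
    seed = t.seed_node
    children = seed.child_nodes()
    if len(children) == 2:
        a, b = children
        keep, move = (a, b) if not a.is_leaf() else (b, a)
        if keep.is_leaf():
            raise ValueError("cannot deroot a two-leaf tree")
        merged = (move.edge.length or 0.0) + (keep.edge.length or 0.0)
        seed.remove_child(keep)
        for c in list(keep.child_nodes()):
            keep.remove_child(c)
            seed.add_child(c)
        move.edge.length = merged
    t.is_rooted = False
    return t
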