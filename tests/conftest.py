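import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enamelphylo.msa import ConcatenatedMSA
from enamelphylo.simulate import evolve_alignment, simulate_yule_tree

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim16():
    """16-taxon, 2000-site alignment with strong rate heterogeneity (alpha=0.5)."""
    tree = simulate_yule_tree(16, 1.0, seed=11, height=0.3)
    msa, history = evolve_alignment(tree, 2000, 0.5, seed=12)
    return tree, msa, history


def make_msa(rows: dict[str, str], partitions=None) -> ConcatenatedMSA:
    return ConcatenatedMSA.from_rows(rows, partitions=partitions)


@pytest.fixture
def toy_msa():
    return make_msa


def additive_matrix(tree):
    """Exact leaf-to-leaf path-length matrix of a tree (independent oracle)."""
    depths = {}
    paths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            paths[id(node)] = []
            continue
        paths[id(node)] = paths[id(node.parent_node)] + [node]
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    names = [lf.taxon.label for lf in leaves]
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = paths[id(leaves[i])]
            pj = paths[id(leaves[j])]
            shared = 0
            for a, b in zip(pi, pj):
                if a is b:
                    shared += 1
                else:
                    break
            d = sum(nd.edge.length for nd in pi[shared:]) + sum(
                nd.edge.length for nd in pj[shared:]
            )
            mat[i, j] = mat[j, i] = d
    return names, mat
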