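import numpy as np
import pytest

import phylotraits as pt


@pytest.fixture
def cherry():
    return pt.PhyloTree.from_newick("(A:1,B:1);")


@pytest.fixture
def quartet():
    """Balanced ultrametric 4-tip tree."""
    return pt.PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar6():
    return pt.PhyloTree.from_newick(
        "(((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5);"
    )


@pytest.fixture
def yule64():
    return pt.simulate_yule_tree(64, 1.0, 20240101)


def random_tree_with_polytomies(n_tips: int, rng: np.random.Generator) -> pt.PhyloTree:
    """Yule tree with ~30% of internal edges collapsed into polytomies."""
    tree = pt.simulate_yule_tree(n_tips, 1.0, rng.integers(2**31))
    dt = tree.dendropy_tree
    for edge in list(dt.preorder_edge_iter()):
        head = edge.head_node
        if head.is_leaf() or head.parent_node is None:
            continue
        if rng.random() < 0.3:
            edge.collapse()
    return pt.PhyloTree(dt)
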