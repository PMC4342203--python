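import numpy as np
import pytest
from scipy import stats

import phylotraits as pt
from phylotraits.errors import ValidationError


def _d_sum_reference(tree: pt.PhyloTree, trait: pt.BinaryTrait) -> float:
    """Independent recursive re-implementation over the dendropy tree."""
    vals = {}
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            vals[nd] = float(trait.states[nd.taxon.label])
        else:
            kids = nd.child_nodes()
            vals[nd] = sum(vals[c] for c in kids) / len(kids)
    total = 0.0
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.parent_node is not None:
            total += abs(vals[nd] - vals[nd.parent_node])
    return total


def test_d_sum_constant_trait_is_zero(quartet):
    tr = pt.BinaryTrait("c", {l: 1 for l in quartet.tip_labels})
    assert pt.d_sum(quartet, tr) == 0.0


def test_d_sum_two_tip_hand_value(cherry):
    tr = pt.BinaryTrait("x", {"A": 0, "B": 1})
    assert pt.d_sum(cherry, tr) == pytest.approx(1.0)


def test_d_sum_quartet_hand_value(quartet):
    tr = pt.BinaryTrait("x", {"A": 1, "B": 1, "C": 0, "D": 0})
    assert pt.d_sum(quartet, tr) == pytest.approx(1.0)
    assert pt.d_sum(quartet, tr) == pytest.approx(_d_sum_reference(quartet, tr))


def test_d_sum_matches_reference_on_random_traits(yule64):
    rng = np.random.default_rng(0)
    for _ in range(20):
        k = int(rng.integers(1, 64))
        tr = pt.simulate_trait_random(yule64, k, seed=rng.integers(2**31))
        assert pt.d_sum(yule64, tr) == pytest.approx(
            _d_sum_reference(yule64, tr), rel=1e-12
        )


def test_d_sum_handles_polytomies_natively():
    tree = pt.PhyloTree.from_newick("((A:1,B:1,C:1):1,D:2);")
    tr = pt.BinaryTrait("x", {"A": 1, "B": 0, "C": 0, "D": 0})
    # internal value 1/3; d = |1-1/3|+2*|0-1/3| at tips + two root edges
    assert pt.d_sum(tree, tr) == pytest.approx(
        (2 / 3 + 1 / 3 + 1 / 3) + abs(1 / 3 - 1 / 6) + abs(0 - 1 / 6)
    )


def test_d_sum_invariant_under_state_complementation(yule64):
    tr = pt.simulate_trait_random(yule64, 20, seed=5)
    assert pt.d_sum(yule64, tr) == pytest.approx(pt.d_sum(yule64, tr.complement()))


def test_d_sum_requires_full_scoring(quartet):
    tr = pt.BinaryTrait("x", {"A": 1, "B": 0, "C": 1, "D": None})
    with pytest.raises(ValidationError, match="prune"):
        pt.d_sum(quartet, tr)


# ----------------------------------------------------------------------
# phylo_d


def test_phylo_d_random_trait_centred_on_one(yule64):
    ds = []
    for i in range(20):
        tr = pt.simulate_trait_random(yule64, 16, seed=[1, i])
        ds.append(pt.phylo_d(yule64, tr, n_sim=300, seed=[2, i]).D)
    assert np.mean(ds) == pytest.approx(1.0, abs=0.2)


def test_phylo_d_brownian_trait_centred_on_zero(yule64):
    ds = []
    for i in range(20):
        tr = pt.simulate_trait_brownian_threshold(yule64, 16, seed=[3, i])
        ds.append(pt.phylo_d(yule64, tr, n_sim=300, seed=[4, i]).D)
    assert np.mean(ds) == pytest.approx(0.0, abs=0.2)


def test_phylo_d_single_clade_trait_goes_negative():
    """A trait filling exactly one half of a balanced tree is more
    conserved than Brownian expectation; D is reported unclamped."""
    tree = pt.PhyloTree.from_newick(
        "((((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1):1,"
        "(((I:1,J:1):1,(K:1,L:1):1):1,((M:1,N:1):1,(O:1,P:1):1):1):1);"
    )
    tr = pt.BinaryTrait("clade", {c: (1 if c in "ABCDEFGH" else 0)
                                  for c in "ABCDEFGHIJKLMNOP"})
    r = pt.phylo_d(tree, tr, n_sim=1000, seed=0)
    assert r.D < -1.0
    assert r.p_vs_random < 0.01


def test_phylo_d_invariant_under_branch_scaling(yule64):
    tr = pt.simulate_trait_brownian_threshold(yule64, 16, seed=6)
    r1 = pt.phylo_d(yule64, tr, n_sim=200, seed=7)
    scaled = yule64.clone()
    for e in scaled.dendropy_tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= 13.7
    scaled = pt.PhyloTree(scaled.dendropy_tree)
    r2 = pt.phylo_d(scaled, tr, n_sim=200, seed=7)
    assert r1.D == pytest.approx(r2.D, rel=1e-12)


def test_phylo_d_p_uniform_under_random_null(yule64):
    ps = []
    for i in range(200):
        tr = pt.simulate_trait_random(yule64, 16, seed=[8, i])
        ps.append(pt.phylo_d(yule64, tr, n_sim=150, seed=[9, i]).p_vs_random)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_phylo_d_validation(yule64, cherry):
    const = pt.BinaryTrait("c", {l: 1 for l in yule64.tip_labels})
    with pytest.raises(ValidationError, match="prevalence"):
        pt.phylo_d(yule64, const, seed=0)
    tr = pt.simulate_trait_random(yule64, 16, seed=1)
    with pytest.raises(ValidationError, match="n_sim"):
        pt.phylo_d(yule64, tr, n_sim=50, seed=0)
    # 2-tip tree: both nulls give d = 1 always -> degenerate denominator
    tr2 = pt.BinaryTrait("x", {"A": 0, "B": 1})
    with pytest.raises(ValidationError, match="degenerate"):
        pt.phylo_d(cherry, tr2, n_sim=100, seed=0)


def test_phylo_d_missing_policies(yule64):
    states = {l: (1 if i < 16 else 0) for i, l in enumerate(yule64.tip_labels)}
    states[yule64.tip_labels[-1]] = None
    tr = pt.BinaryTrait("m", states)
    with pytest.raises(ValidationError):
        pt.phylo_d(yule64, tr, seed=0)
    r_prune = pt.phylo_d(yule64, tr, n_sim=150, seed=0, missing_policy="prune")
    r_zero = pt.phylo_d(yule64, tr, n_sim=150, seed=0, missing_policy="as_absent")
    assert r_prune.n_sim == r_zero.n_sim == 150


def test_phylo_d_over_sample_medians(yule64):
    sample = pt.TreeSample([yule64] * 3)
    tr = pt.simulate_trait_random(yule64, 16, seed=10)
    summ = pt.phylo_d_over_sample(sample, tr, n_sim=150, seed=11)
    per_tree = sorted(r.D for r in summ.results)
    assert summ.median_D == pytest.approx(per_tree[1])
    assert summ.n_trees == 3
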