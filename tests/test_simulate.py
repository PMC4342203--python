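import numpy as np
import pytest
from scipy import stats

import phylotraits as pt
from phylotraits.dstat import d_sums_batch
from phylotraits.errors import ValidationError
from phylotraits.simulate import brownian_threshold_states_batch, random_states_batch


# ----------------------------------------------------------------------
# Yule trees


def test_yule_two_tips_is_cherry_with_equal_pendants():
    tree = pt.simulate_yule_tree(2, 1.0, 0)
    idx = tree.index
    assert len(idx.tip_pos) == 2
    lens = idx.blen[idx.tip_pos]
    assert lens[0] == pytest.approx(lens[1])


def test_yule_reproducible_and_distinct_by_seed():
    a = pt.simulate_yule_tree(16, 1.0, 9)
    b = pt.simulate_yule_tree(16, 1.0, 9)
    c = pt.simulate_yule_tree(16, 1.0, 10)
    assert a.as_newick() == b.as_newick()
    assert a.as_newick() != c.as_newick()


def test_yule_contract_128_tips():
    tree = pt.simulate_yule_tree(128, 1.0, 1)
    assert tree.n_tips == 128
    _, ultra = pt.node_ages(tree)
    assert ultra


def test_yule_rejects_degenerate_inputs():
    with pytest.raises(ValidationError):
        pt.simulate_yule_tree(1, 1.0, 0)
    with pytest.raises(ValidationError):
        pt.simulate_yule_tree(5, 0.0, 0)


# ----------------------------------------------------------------------
# Random traits


def test_random_trait_prevalence_and_determinism(yule64):
    tr = pt.simulate_trait_random(yule64, 63, seed=4)
    assert tr.prevalence == 63
    assert sum(v == 0 for v in tr.states.values()) == 1
    again = pt.simulate_trait_random(yule64, 63, seed=4)
    assert tr.states == again.states
    with pytest.raises(ValidationError):
        pt.simulate_trait_random(yule64, 0, seed=1)
    with pytest.raises(ValidationError):
        pt.simulate_trait_random(yule64, 64, seed=1)


def test_random_trait_marginals_follow_binomial_law():
    """Over 10000 replicates on 8 tips, each tip is 1 with freq k/n +- 3 SE."""
    n, k, reps = 8, 3, 10000
    states = random_states_batch(n, k, reps, np.random.default_rng(0))
    freqs = states.mean(axis=0)
    se = np.sqrt((k / n) * (1 - k / n) / reps)
    assert np.all(np.abs(freqs - k / n) < 3 * se + 1e-12)


# ----------------------------------------------------------------------
# Brownian threshold traits


def test_brownian_threshold_prevalence_exact(yule64):
    for k in (1, 16, 63):
        tr = pt.simulate_trait_brownian_threshold(yule64, k, seed=k)
        assert tr.prevalence == k


def test_brownian_cherry_cotransition_beats_distant_pairs(quartet):
    """On ((A,B),(C,D)) with k=2, P(A,B both 1) > P(A,D both 1).

    Oracle: sample tip values directly from the analytic Brownian
    covariance (shared-path lengths) and threshold — no tree recursion.
    """
    reps = 5000
    idx = quartet.index
    states = brownian_threshold_states_batch(idx, 2, reps, np.random.default_rng(1))
    lab = {l: j for j, l in enumerate(idx.tip_labels)}
    p_ab = (states[:, lab["A"]] * states[:, lab["B"]]).mean()
    p_ad = (states[:, lab["A"]] * states[:, lab["D"]]).mean()
    assert p_ab > p_ad

    cov = np.array(
        [[2, 1, 0, 0], [1, 2, 0, 0], [0, 0, 2, 1], [0, 0, 1, 2]], dtype=float
    )  # tips A,B,C,D: total depth 2, cherries share 1
    vals = np.random.default_rng(2).multivariate_normal(np.zeros(4), cov, size=reps)
    order = np.argsort(vals, axis=1)
    s = np.zeros_like(vals)
    np.put_along_axis(s, order[:, -2:], 1.0, axis=1)
    p_ab_oracle = (s[:, 0] * s[:, 1]).mean()
    p_ad_oracle = (s[:, 0] * s[:, 3]).mean()
    se = 2 / np.sqrt(reps)
    assert p_ab == pytest.approx(p_ab_oracle, abs=3 * se)
    assert p_ad == pytest.approx(p_ad_oracle, abs=3 * se)


def test_brownian_on_star_tree_matches_random_assignment():
    """With no shared history the threshold trait is an exchangeable draw."""
    star = pt.PhyloTree.from_newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")
    reps, k = 5000, 3
    states = brownian_threshold_states_batch(star.index, k, reps, np.random.default_rng(3))
    counts = states.sum(axis=0)
    chi2 = ((counts - reps * k / 8) ** 2 / (reps * k / 8)).sum()
    # 7 df; exchangeability implies uniform per-tip inclusion
    assert stats.chi2.sf(chi2, df=7) > 0.01


def test_brownian_three_tip_covariance_matches_analytic():
    tree = pt.PhyloTree.from_newick("((A:1,B:1):1,C:2);")
    from phylotraits.simulate import _brownian_tip_values

    vals = _brownian_tip_values(tree.index, 10000, np.random.default_rng(4))
    lab = {l: j for j, l in enumerate(tree.index.tip_labels)}
    emp = np.cov(vals.T)
    expect = {("A", "A"): 2, ("B", "B"): 2, ("C", "C"): 2, ("A", "B"): 1,
              ("A", "C"): 0, ("B", "C"): 0}
    for (x, y), v in expect.items():
        assert emp[lab[x], lab[y]] == pytest.approx(v, abs=0.12)


def test_brownian_requires_variance():
    flat = pt.PhyloTree.from_newick("((A:0,B:0):0,C:0);")
    with pytest.raises(ValidationError, match="variance"):
        pt.simulate_trait_brownian_threshold(flat, 1, seed=0)


# ----------------------------------------------------------------------
# Mk traits


def test_mk_zero_rates_constant(quartet):
    tr, hist = pt.simulate_trait_mk(quartet, 0.0, 0.0, 1, seed=0)
    assert set(tr.states.values()) == {1}
    assert hist.n_changes == 0


def test_mk_no_loss_rate_means_no_losses(yule64):
    tr, hist = pt.simulate_trait_mk(yule64, 0.5, 0.0, 0, seed=1)
    assert hist.n_losses == 0
    assert hist.n_gains >= 1


def test_mk_realised_changes_bound_fitch_minimum(caterpillar6):
    for rep in range(50):
        tr, hist = pt.simulate_trait_mk(caterpillar6, 0.4, 0.4, 0, seed=rep)
        if tr.prevalence in (0, 6):
            continue
        assert pt.fitch(caterpillar6, tr).min_changes <= hist.n_changes


# ----------------------------------------------------------------------
# Correlated traits


def test_correlated_zero_rates_constant(quartet):
    ta, tb, _ = pt.simulate_correlated_traits(quartet, pt.CorrelatedRates(), seed=0)
    assert set(ta.states.values()) == {0}
    assert set(tb.states.values()) == {0}


def test_correlated_negative_rates_rejected(quartet):
    with pytest.raises(ValidationError):
        pt.simulate_correlated_traits(quartet, pt.CorrelatedRates(a01_b0=-1), seed=0)


def test_correlated_equal_rates_traits_independent(yule64):
    """Under the independence rate matrix, one tip's A and B states are
    independent across replicates (contingency chi-square)."""
    rates = pt.CorrelatedRates.independent(0.5, 0.5, 0.5, 0.5)
    focal = yule64.tip_labels[0]
    tab = np.zeros((2, 2))
    for rep in range(400):
        ta, tb, _ = pt.simulate_correlated_traits(yule64, rates, seed=rep)
        tab[ta.states[focal], tb.states[focal]] += 1
    _, p, _, _ = stats.chi2_contingency(tab + 0.5)
    assert p > 0.001


def test_strong_dependence_couples_the_traits(yule64):
    """When B can only gain while A=1, B=1 tips concentrate where A=1."""
    rates = pt.CorrelatedRates.strong_dependence()
    agree = 0
    tot = 0
    for rep in range(30):
        ta, tb, _ = pt.simulate_correlated_traits(yule64, rates, seed=rep)
        for l in yule64.tip_labels:
            tot += 1
            agree += ta.states[l] == tb.states[l]
    assert agree / tot > 0.6


# ----------------------------------------------------------------------
# Range histories


def test_range_history_no_rates_single_area_root():
    tree = pt.simulate_yule_tree(16, 1.0, 2)
    ranges, log = pt.simulate_range_history(
        tree, d=0.0, e=0.0, seed=0, root_range=("S",)
    )
    assert all(r == frozenset("S") for r in ranges.ranges.values())
    assert set(log.counts()) == {"within_area"}


def test_range_history_no_extinction_is_monotone():
    tree = pt.simulate_yule_tree(24, 1.0, 3)
    for rep in range(10):
        ranges, log = pt.simulate_range_history(
            tree, d=0.3, e=0.0, seed=rep, root_range=("S",)
        )
        idx = tree.index
        assert all(ranges.ranges[i] for i in range(idx.n_nodes))
        # child node range contains its inherited range when e = 0
        for v in range(idx.n_nodes):
            if idx.is_tip[v]:
                continue
            i1, i2 = ranges.splits[v]
            for k, inh in zip(idx.children[v], (i1, i2)):
                assert inh <= ranges.ranges[int(k)]
        assert not log.of_type("extinction")


def test_range_history_event_times_within_branch_intervals():
    tree = pt.simulate_yule_tree(24, 1.0, 4)
    ranges, log = pt.simulate_range_history(tree, d=0.2, e=0.1, seed=9)
    idx = tree.index
    for ev in log:
        assert 0.0 <= ev.time <= log.root_age + 1e-9
        if ev.type in ("dispersal", "extinction"):
            top = idx.ages[idx.parent[ev.node]]
            bot = idx.ages[ev.node]
            assert bot - 1e-9 <= ev.time <= top + 1e-9


def test_range_history_validation():
    tree = pt.simulate_yule_tree(8, 1.0, 5)
    with pytest.raises(ValidationError):
        pt.simulate_range_history(tree, areas=("S",), seed=0)
    with pytest.raises(ValidationError):
        pt.simulate_range_history(tree, seed=0, root_range=())


# ----------------------------------------------------------------------
# Toy alignments


def test_toy_alignment_no_indels_is_gap_free():
    aln, spans = pt.generate_toy_alignment(6, 50, 0, seed=0)
    assert spans == []
    assert pt.find_indels(aln) == []
    assert pt.simple_indel_coding(aln).characters == []


def test_toy_alignment_truth_spans_recovered():
    for rep in range(10):
        aln, spans = pt.generate_toy_alignment(8, 60, 4, seed=rep)
        assert pt.find_indels(aln) == spans


def test_toy_alignment_deterministic():
    a1, _ = pt.generate_toy_alignment(5, 40, 3, seed=11)
    a2, _ = pt.generate_toy_alignment(5, 40, 3, seed=11)
    assert a1.sequences == a2.sequences
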