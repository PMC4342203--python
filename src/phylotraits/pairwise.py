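"""Phylogenetically independent pairwise-comparison tests.

The test asks whether change in a predictor character (e.g. leaf
succulence) is associated with change in a dependent character (e.g.
documented use). It selects pairs of tips that differ in the predictor and
whose connecting paths share no tree edges — so each pair is an independent
evolutionary contrast — then applies a one-tailed sign test to the
dependent states within the informative pairs (those where the dependent
character also differs).

Pair selection is a seeded greedy sweep in postorder: at each internal node
currently unpaired tips from different child subtrees with contrasting
predictor states are matched uniformly at random; once a child subtree
contributes a tip to a pair its stem edge is consumed, so the remaining
tips of that subtree can no longer pair above the node. Many maximal
pairings exist; repeating the selection over many random sets and reporting
the median p propagates that arbitrariness, and running over a posterior
tree sample propagates topological uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .traits import BinaryTrait
from .trees import PhyloTree, TreeSample
from .util import as_rng, child_seeds

__all__ = [
    "Pair",
    "PairSet",
    "PairwiseResult",
    "select_independent_pairs",
    "sign_test",
    "pairwise_over_sets",
    "pairwise_over_trees",
    "PairwiseTreeSummary",
]


@dataclass(frozen=True)
class Pair:
    tip_predictor_1: str  # tip carrying predictor state 1
    tip_predictor_0: str
    path_edges: frozenset[int]  # edges (child-node ids) on the connecting path


@dataclass
class PairSet:
    pairs: list[Pair]
    tree: PhyloTree

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_independence(self) -> None:
        """Hard structural check: no two pair paths share an edge."""
        all_edges: list[int] = []
        for p in self.pairs:
            all_edges.extend(p.path_edges)
        if len(all_edges) != len(set(all_edges)):
            raise AssertionError("pairwise paths share edges; selection is broken")
        tips = [t for p in self.pairs for t in (p.tip_predictor_1, p.tip_predictor_0)]
        if len(tips) != len(set(tips)):
            raise AssertionError("a tip appears in more than one pair")


@dataclass
class PairwiseResult:
    n_pairs: int
    n_informative: int
    n_concordant: int
    p_one_tailed: float | None
    direction: int
    flagged: str | None = None
    n_sets: int = 1
    p_per_set: list[float | None] = field(default_factory=list)
    median_p: float | None = None


def select_independent_pairs(tree: PhyloTree, predictor: BinaryTrait, seed) -> PairSet:
    """Greedy postorder selection of edge-disjoint contrasting pairs."""
    idx = tree.index
    states = idx.states_vector(predictor.states).astype(int)
    if states.min() == states.max():
        raise ValidationError(
            f"predictor {predictor.name!r} is constant: no contrasting pairs exist"
        )
    rng = as_rng(seed)
    tip_state = dict(zip(idx.tip_pos, states))
    label_of = dict(zip(idx.tip_pos, idx.tip_labels))

    avail: dict[int, list[int]] = {}  # node -> unpaired tip positions below it
    pairs: list[Pair] = []
    for v in range(idx.n_nodes):
        if idx.is_tip[v]:
            avail[v] = [v]
            continue
        kids = list(idx.children[v])
        unused = set(range(len(kids)))
        while True:
            candidates = [
                (ci, t1, cj, t0)
                for ci in unused
                for t1 in avail[kids[ci]]
                if tip_state[t1] == 1
                for cj in unused
                if cj != ci
                for t0 in avail[kids[cj]]
                if tip_state[t0] == 0
            ]
            if not candidates:
                break
            ci, t1, cj, t0 = candidates[int(rng.integers(len(candidates)))]
            pairs.append(
                Pair(label_of[t1], label_of[t0], idx.path_edges(t1, t0))
            )
            unused -= {ci, cj}
        avail[v] = [t for ci in unused for t in avail[kids[ci]]]
    ps = PairSet(pairs, tree)
    ps.validate_independence()
    return ps


def sign_test(pairs: PairSet, dependent: BinaryTrait, direction: int = 1) -> PairwiseResult:
    """One-tailed sign test on the dependent states within pairs.

    A pair is informative when the dependent states differ (and are both
    scored); with ``direction=+1`` a concordant pair is one where the tip
    with predictor 1 also carries dependent 1. p is the upper binomial tail
    P(X >= k | n, 1/2). Zero informative pairs gives a flagged result with
    p = None rather than an exception.
    """
    if not len(pairs):
        raise ValidationError("empty pair set")
    if direction not in (1, -1):
        raise ValidationError("direction must be +1 or -1")
    n_inf = n_conc = 0
    for p in pairs.pairs:
        d1 = dependent.states.get(p.tip_predictor_1)
        d0 = dependent.states.get(p.tip_predictor_0)
        if d1 is None or d0 is None or d1 == d0:
            continue
        n_inf += 1
        concordant = d1 == 1  # dependent follows predictor
        if direction == -1:
            concordant = not concordant
        n_conc += int(concordant)
    if n_inf == 0:
        return PairwiseResult(len(pairs), 0, 0, None, direction,
                              flagged="no informative pairs")
    p = float(stats.binom.sf(n_conc - 1, n_inf, 0.5))
    return PairwiseResult(len(pairs), n_inf, n_conc, p, direction)


def pairwise_over_sets(
    tree: PhyloTree,
    predictor: BinaryTrait,
    dependent: BinaryTrait,
    n_sets: int = 100,
    seed=None,
    direction: int = 1,
) -> PairwiseResult:
    """Repeat selection + sign test over many random pair sets.

    Reports the median p across sets (flagged sets excluded) along with the
    full per-set distribution; the last set's counts are carried as the
    representative detail.
    """
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    seeds = child_seeds(seed, n_sets)
    p_list: list[float | None] = []
    last: PairwiseResult | None = None
    for s in seeds:
        ps = select_independent_pairs(tree, predictor, s)
        last = sign_test(ps, dependent, direction)
        p_list.append(last.p_one_tailed)
    valid = [p for p in p_list if p is not None]
    out = PairwiseResult(
        n_pairs=last.n_pairs,
        n_informative=last.n_informative,
        n_concordant=last.n_concordant,
        p_one_tailed=last.p_one_tailed,
        direction=direction,
        flagged=None if valid else "no informative pairs in any set",
        n_sets=n_sets,
        p_per_set=p_list,
        median_p=float(np.median(valid)) if valid else None,
    )
    return out


@dataclass
class PairwiseTreeSummary:
    per_tree_median_p: list[float]
    failures: list[tuple[int, str]]
    median_of_medians: float


def pairwise_over_trees(
    sample: TreeSample,
    predictor: BinaryTrait,
    dependent: BinaryTrait,
    n_sets: int = 100,
    seed=None,
    direction: int = 1,
) -> PairwiseTreeSummary:
    """Median p per tree over a posterior sample, and the overall median."""
    seeds = child_seeds(seed, len(sample))
    medians: list[float] = []
    failures: list[tuple[int, str]] = []
    for i, tree in enumerate(sample):
        try:
            r = pairwise_over_sets(tree, predictor, dependent, n_sets=n_sets,
                                   seed=seeds[i], direction=direction)
            if r.median_p is None:
                failures.append((i, r.flagged or "no informative pairs"))
            else:
                medians.append(r.median_p)
        except ValidationError as exc:
            failures.append((i, str(exc)))
    if not medians:
        raise ValidationError("pairwise test failed on every tree in the sample")
    return PairwiseTreeSummary(
        per_tree_median_p=medians,
        failures=failures,
        median_of_medians=float(np.median(medians)),
    )
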