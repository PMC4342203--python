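"""Fitch parsimony for binary characters, with gain/loss accounting.

The bottom-up pass uses the multifurcation extension of Fitch's method: a
node's state set is the set of states occurring in the maximum number of
child sets, and the added cost is the number of children whose set lacks
that state. On a rooted tree the polarity of each change (gain 0->1 vs loss
1->0) depends on which most-parsimonious reconstruction (MPR) is chosen, so
gains and losses are reported as min/max over all MPRs via a unit-cost
Sankoff dynamic program; an ACCTRAN-style single reconstruction (ties
resolved toward placing changes closer to the root) is available as an
option.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .traits import BinaryTrait
from .trees import PhyloTree, TreeSample

__all__ = ["ParsimonyResult", "fitch", "count_transitions_over_sample", "TransitionDistribution"]

_INF = 10**9


@dataclass
class ParsimonyResult:
    """Per-node Fitch state sets plus change counts over MPRs.

    ``node_sets`` is indexed by postorder node position; state sets are
    frozensets over {0, 1}. ``losses_min + gains_min <= min_changes`` and
    every MPR has exactly ``min_changes`` changes, so
    ``losses_min = min_changes - gains_max`` and vice versa.
    """

    node_sets: list[frozenset[int]]
    min_changes: int
    gains_min: int
    gains_max: int
    losses_min: int
    losses_max: int
    resolution: str | None = None
    resolved_states: dict[int, int] | None = None
    resolved_gains: int | None = None
    resolved_losses: int | None = None


def _tip_states(tree: PhyloTree, trait: BinaryTrait) -> np.ndarray:
    idx = tree.index
    states = idx.states_vector(trait.states)
    if not np.isin(states, (0.0, 1.0)).all():
        raise ValidationError("parsimony needs binary 0/1 tip states")
    return states.astype(int)


def fitch(tree: PhyloTree, trait: BinaryTrait, resolve: str | None = None) -> ParsimonyResult:
    """Fitch parsimony for one binary trait on one rooted tree.

    ``resolve="acctran"`` additionally returns one concrete MPR with
    ambiguous nodes resolved toward early (rootward) changes.
    """
    idx = tree.index
    states = _tip_states(tree, trait)
    tip_state = dict(zip(idx.tip_pos, states))

    # --- multifurcating Fitch bottom-up: sets + minimum change count
    node_sets: list[frozenset[int]] = [frozenset()] * idx.n_nodes
    fitch_cost = 0
    for i in range(idx.n_nodes):
        if idx.is_tip[i]:
            node_sets[i] = frozenset({int(tip_state[i])})
            continue
        kids = idx.children[i]
        k0 = sum(1 for c in kids if 0 in node_sets[c])
        k1 = sum(1 for c in kids if 1 in node_sets[c])
        kmax = max(k0, k1)
        node_sets[i] = frozenset(
            s for s, k in ((0, k0), (1, k1)) if k == kmax
        )
        fitch_cost += len(kids) - kmax

    # --- unit-cost Sankoff DP with gain accounting over MPRs
    cost = np.zeros((idx.n_nodes, 2), dtype=np.int64)
    gmin = np.zeros((idx.n_nodes, 2), dtype=np.int64)
    gmax = np.zeros((idx.n_nodes, 2), dtype=np.int64)
    for i in range(idx.n_nodes):
        if idx.is_tip[i]:
            s = int(tip_state[i])
            cost[i, 1 - s] = _INF
            continue
        for s in (0, 1):
            tot = gm = gM = 0
            for c in idx.children[i]:
                opts = []
                for t in (0, 1):
                    ch = cost[c, t] + (1 if t != s else 0)
                    gain = 1 if (s == 0 and t == 1) else 0
                    opts.append((ch, gmin[c, t] + gain, gmax[c, t] + gain))
                best = min(o[0] for o in opts)
                tot += best
                gm += min(o[1] for o in opts if o[0] == best)
                gM += max(o[2] for o in opts if o[0] == best)
            cost[i, s], gmin[i, s], gmax[i, s] = tot, gm, gM
    root = idx.root
    min_changes = int(cost[root].min())
    assert min_changes == fitch_cost, "Fitch count and Sankoff minimum disagree"
    opt_states = [s for s in (0, 1) if cost[root, s] == min_changes]
    gains_min = int(min(gmin[root, s] for s in opt_states))
    gains_max = int(max(gmax[root, s] for s in opt_states))

    result = ParsimonyResult(
        node_sets=node_sets,
        min_changes=min_changes,
        gains_min=gains_min,
        gains_max=gains_max,
        losses_min=min_changes - gains_max,
        losses_max=min_changes - gains_min,
    )
    if resolve is None:
        return result
    if resolve != "acctran":
        raise ValidationError(f"unknown resolution {resolve!r}")

    # --- one concrete MPR, ties resolved toward change (rootward changes)
    resolved: dict[int, int] = {}
    root_choices = opt_states
    resolved[root] = root_choices[0] if len(root_choices) == 1 else 1
    gains = losses = 0
    for i in range(idx.n_nodes - 2, -1, -1):
        s = resolved[idx.parent[i]]
        opts = {t: cost[i, t] + (1 if t != s else 0) for t in (0, 1)}
        best = min(opts.values())
        choices = [t for t, v in opts.items() if v == best]
        # prefer a change (accelerated transformation) when ambiguous
        t = choices[0] if len(choices) == 1 else (1 - s)
        resolved[i] = t
        if t != s:
            gains += 1 if t == 1 else 0
            losses += 1 if t == 0 else 0
    result.resolution = "acctran"
    result.resolved_states = resolved
    result.resolved_gains = gains
    result.resolved_losses = losses
    return result


@dataclass
class TransitionDistribution:
    """Histogram of per-tree transition counts over a tree sample."""

    counts: list[int]
    failures: list[tuple[int, str]]
    which: str

    def histogram(self) -> dict[int, float]:
        """Fraction of successfully analysed trees supporting each count."""
        c = Counter(self.counts)
        n = len(self.counts)
        return {k: c[k] / n for k in sorted(c)}

    def support_for(self, count: int) -> float:
        return self.histogram().get(count, 0.0)


def count_transitions_over_sample(
    sample: TreeSample, trait: BinaryTrait, which: str = "losses_min"
) -> TransitionDistribution:
    """Per-tree parsimony transition counts and their histogram.

    ``which`` selects the counted quantity: ``min_changes``, ``gains_min``,
    ``gains_max``, ``losses_min`` or ``losses_max``.
    """
    valid = ("min_changes", "gains_min", "gains_max", "losses_min", "losses_max")
    if which not in valid:
        raise ValidationError(f"which must be one of {valid}")
    counts: list[int] = []
    failures: list[tuple[int, str]] = []
    for i, tree in enumerate(sample):
        try:
            counts.append(int(getattr(fitch(tree, trait), which)))
        except ValidationError as exc:
            failures.append((i, str(exc)))
    if not counts:
        raise ValidationError("parsimony failed on every tree in the sample")
    return TransitionDistribution(counts=counts, failures=failures, which=which)
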