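"""Synthetic data with the statistical structure the analyses assume.

Every generator takes an explicit seed and is reproducible; ground truth
(true change counts, joint trait histories, range-event logs, indel spans)
is retained so downstream estimators can be validated against it.

The trait generators mirror the three regimes the signal statistic is
calibrated against: uniformly random scatter at fixed prevalence, a
Brownian-motion threshold model (strong phylogenetic dependence), and
2-state Markov evolution including a correlated-pair variant. The range
simulator is the forward counterpart of a dispersal-extinction-cladogenesis
reconstruction: anagenetic area gains/losses along branches, vicariance or
peripheral-isolation splits at nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .biogeo import DEFAULT_AREAS, Event, EventLog, RangeAssignment
from .errors import ValidationError
from .traits import BinaryTrait
from .trees import PhyloTree, TreeIndex
from .util import as_rng, child_seeds

__all__ = [
    "SimulationConfig",
    "CorrelatedRates",
    "MkHistory",
    "simulate_yule_tree",
    "simulate_trait_random",
    "simulate_trait_brownian_threshold",
    "simulate_trait_mk",
    "simulate_correlated_traits",
    "simulate_range_history",
    "generate_toy_alignment",
    "random_states_batch",
    "brownian_threshold_states_batch",
]


@dataclass
class SimulationConfig:
    """Default study conditions for the synthetic bundle.

    197 tips matches the pruned ingroup the analyses run on; prevalence 81
    is the medicinal-use prevalence scale; Mk and range rates are set so a
    197-tip, depth~5 pure-birth tree carries a handful of changes per
    character and a few dozen range events — the regime the estimators are
    meant for.
    """

    seed: int = 0
    n_tips: int = 197
    birth_rate: float = 1.0
    prevalence: int = 81
    q01: float = 0.15
    q10: float = 0.15
    dispersal_rate: float = 0.08
    extinction_rate: float = 0.04
    clado_prob_vicariance: float = 0.25
    areas: tuple[str, ...] = DEFAULT_AREAS


# ----------------------------------------------------------------------
# Trees


def simulate_yule_tree(n_tips: int, birth_rate: float, seed) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with exponential waiting times.

    The process starts from the root split (two lineages at time 0); after
    the (n_tips)-th lineage appears, the present is set one further
    exponential waiting time later, so pendant branches are never zero.
    """
    if n_tips < 2:
        raise ValidationError("a tree needs at least 2 tips")
    if birth_rate <= 0:
        raise ValidationError("birth_rate must be positive")
    rng = as_rng(seed)
    root = dendropy.Node()
    active: list[tuple[dendropy.Node, float]] = []
    t = 0.0
    for _ in range(2):
        active.append((root.new_child(), t))
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = t - born
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    tree = dendropy.Tree(seed_node=root)
    label_i = 0
    pending = {id(n): b for n, b in active}
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = t - pending[id(leaf)]
        label_i += 1
        leaf.taxon = tree.taxon_namespace.new_taxon(label=f"t{label_i}")
    return PhyloTree(tree)


# ----------------------------------------------------------------------
# Batch trait machinery (shared by the public simulators and the D nulls)


def random_states_batch(n_tips: int, k: int, n_sims: int, rng) -> np.ndarray:
    """(n_sims, n_tips) 0/1 matrix, each row with exactly k ones placed
    uniformly at random."""
    u = as_rng(rng).random((n_sims, n_tips))
    order = np.argsort(u, axis=1)
    states = np.zeros((n_sims, n_tips))
    np.put_along_axis(states, order[:, :k], 1.0, axis=1)
    return states


def _brownian_tip_values(index: TreeIndex, n_sims: int, rng) -> np.ndarray:
    """Brownian motion from root value 0, per-branch variance = length.

    Returns tip values in ``index.tip_labels`` order, shape (n_sims, n_tips).
    """
    g = as_rng(rng)
    vals = np.zeros((index.n_nodes, n_sims))
    sd = np.sqrt(index.blen)
    for i in range(index.n_nodes - 2, -1, -1):  # preorder, root already 0
        vals[i] = vals[index.parent[i]]
        if sd[i] > 0:
            vals[i] += g.normal(0.0, sd[i], size=n_sims)
    return vals[index.tip_pos].T


def brownian_threshold_states_batch(index: TreeIndex, k: int, n_sims: int, rng) -> np.ndarray:
    """Brownian-threshold traits: state 1 to the k largest tip values per
    simulation, ties broken uniformly at random."""
    g = as_rng(rng)
    if np.all(index.blen == 0):
        raise ValidationError("all branch lengths are zero: Brownian motion has no variance")
    vals = _brownian_tip_values(index, n_sims, g)
    tiebreak = g.random(vals.shape)
    order = np.lexsort((tiebreak, vals), axis=1)  # ascending by value
    states = np.zeros_like(vals)
    np.put_along_axis(states, order[:, -k:], 1.0, axis=1)
    return states


def _check_prevalence(k: int, n: int) -> None:
    if not 0 < k < n:
        raise ValidationError(f"prevalence k={k} must satisfy 0 < k < n_tips={n}")


def simulate_trait_random(tree: PhyloTree, k: int, seed) -> BinaryTrait:
    """Exactly k tips in state 1, chosen uniformly (phylogeny ignored)."""
    idx = tree.index
    _check_prevalence(k, len(idx.tip_labels))
    row = random_states_batch(len(idx.tip_labels), k, 1, seed)[0]
    return BinaryTrait("random", dict(zip(idx.tip_labels, (int(v) for v in row))))


def simulate_trait_brownian_threshold(tree: PhyloTree, k: int, seed) -> BinaryTrait:
    """Threshold a Brownian motion so that exactly k tips score 1."""
    idx = tree.index
    _check_prevalence(k, len(idx.tip_labels))
    row = brownian_threshold_states_batch(idx, k, 1, seed)[0]
    return BinaryTrait("brownian_threshold", dict(zip(idx.tip_labels, (int(v) for v in row))))


# ----------------------------------------------------------------------
# Markov traits


@dataclass
class MkHistory:
    """Ground truth for an Mk simulation: realised change counts."""

    n_gains: int  # 0 -> 1
    n_losses: int  # 1 -> 0
    per_branch: dict[int, int]  # postorder node index -> changes on its branch

    @property
    def n_changes(self) -> int:
        return self.n_gains + self.n_losses


def simulate_trait_mk(
    tree: PhyloTree, q01: float, q10: float, root_state: int, seed
) -> tuple[BinaryTrait, MkHistory]:
    """2-state continuous-time Markov chain down the tree (exact jump chain).

    Returns the tip trait and the realised per-branch change counts. With
    both rates 0 the trait is constant at the root state (allowed; the
    history simply records zero changes).
    """
    if q01 < 0 or q10 < 0:
        raise ValidationError("rates must be nonnegative")
    rng = as_rng(seed)
    idx = tree.index
    state = np.empty(idx.n_nodes, dtype=int)
    state[idx.root] = int(root_state)
    per_branch: dict[int, int] = {}
    gains = losses = 0
    rates = (q01, q10)
    for i in range(idx.n_nodes - 2, -1, -1):
        s = state[idx.parent[i]]
        remaining = idx.blen[i]
        n_changes = 0
        while rates[s] > 0:
            wait = rng.exponential(1.0 / rates[s])
            if wait >= remaining:
                break
            remaining -= wait
            if s == 0:
                gains += 1
            else:
                losses += 1
            s = 1 - s
            n_changes += 1
        state[i] = s
        per_branch[i] = n_changes
    trait = BinaryTrait(
        "mk", {lab: int(state[p]) for lab, p in zip(idx.tip_labels, idx.tip_pos)}
    )
    return trait, MkHistory(gains, losses, per_branch)


@dataclass
class CorrelatedRates:
    """Rate matrix for the dependent 2-trait model over joint states
    (A,B) in {00, 01, 10, 11}; the eight single-change rates.

    Naming: ``a01_b0`` is the rate of A 0->1 while B=0, ``b10_a1`` the rate
    of B 1->0 while A=1, etc. Double changes are not permitted.
    """

    a01_b0: float = 0.0
    a01_b1: float = 0.0
    a10_b0: float = 0.0
    a10_b1: float = 0.0
    b01_a0: float = 0.0
    b01_a1: float = 0.0
    b10_a0: float = 0.0
    b10_a1: float = 0.0

    def as_matrix(self) -> np.ndarray:
        """4x4 generator over states (00, 01, 10, 11), rows = from."""
        q = np.zeros((4, 4))
        # state index = 2*A + B
        q[0b00, 0b10] = self.a01_b0
        q[0b01, 0b11] = self.a01_b1
        q[0b10, 0b00] = self.a10_b0
        q[0b11, 0b01] = self.a10_b1
        q[0b00, 0b01] = self.b01_a0
        q[0b10, 0b11] = self.b01_a1
        q[0b01, 0b00] = self.b10_a0
        q[0b11, 0b10] = self.b10_a1
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def validate(self) -> None:
        vals = [self.a01_b0, self.a01_b1, self.a10_b0, self.a10_b1,
                self.b01_a0, self.b01_a1, self.b10_a0, self.b10_a1]
        if any(v < 0 for v in vals):
            raise ValidationError("correlated-model rates must be nonnegative")

    @classmethod
    def independent(cls, qa01: float, qa10: float, qb01: float, qb10: float) -> "CorrelatedRates":
        return cls(a01_b0=qa01, a01_b1=qa01, a10_b0=qa10, a10_b1=qa10,
                   b01_a0=qb01, b01_a1=qb01, b10_a0=qb10, b10_a1=qb10)

    @classmethod
    def strong_dependence(cls, qa: float = 0.3, qb: float = 3.0) -> "CorrelatedRates":
        """B tracks A: B can only gain while A=1 and only lose while A=0."""
        return cls(a01_b0=qa, a01_b1=qa, a10_b0=qa, a10_b1=qa,
                   b01_a0=0.0, b01_a1=qb, b10_a0=qb, b10_a1=0.0)


def simulate_correlated_traits(
    tree: PhyloTree,
    rates: CorrelatedRates,
    seed,
    root_state: tuple[int, int] = (0, 0),
) -> tuple[BinaryTrait, BinaryTrait, dict[int, tuple[int, int]]]:
    """Joint 4-state chain for two binary traits; marginals plus the true
    joint state at every node."""
    rates.validate()
    rng = as_rng(seed)
    q = rates.as_matrix()
    out_rate = -np.diag(q)
    idx = tree.index
    joint = np.empty(idx.n_nodes, dtype=int)
    joint[idx.root] = 2 * root_state[0] + root_state[1]
    for i in range(idx.n_nodes - 2, -1, -1):
        s = joint[idx.parent[i]]
        remaining = idx.blen[i]
        while out_rate[s] > 0:
            wait = rng.exponential(1.0 / out_rate[s])
            if wait >= remaining:
                break
            remaining -= wait
            probs = q[s].clip(min=0.0)
            probs[s] = 0.0
            s = int(rng.choice(4, p=probs / probs.sum()))
        joint[i] = s
    history = {i: (int(joint[i]) >> 1, int(joint[i]) & 1) for i in range(idx.n_nodes)}
    ta = BinaryTrait("trait_a", {lab: joint[p] >> 1 for lab, p in zip(idx.tip_labels, idx.tip_pos)})
    tb = BinaryTrait("trait_b", {lab: joint[p] & 1 for lab, p in zip(idx.tip_labels, idx.tip_pos)})
    ta.states = {k: int(v) for k, v in ta.states.items()}
    tb.states = {k: int(v) for k, v in tb.states.items()}
    return ta, tb, history


# ----------------------------------------------------------------------
# Range histories


def simulate_range_history(
    tree: PhyloTree,
    areas: Sequence[str] = DEFAULT_AREAS,
    d: float = 0.08,
    e: float = 0.04,
    clado_prob_vicariance: float = 0.25,
    seed=None,
    root_range: Sequence[str] | None = None,
) -> tuple[RangeAssignment, EventLog]:
    """Forward dispersal-extinction-cladogenesis history with ground truth.

    Along each branch, each unoccupied area is gained at rate ``d`` and each
    occupied area lost at rate ``e``; a loss that would empty the range is
    proposed and rejected (time still advances). At each split a single-area
    range is copied to both children; otherwise, with probability
    ``clado_prob_vicariance`` the range is divided into two disjoint
    nonempty parts (vicariance), and with the complementary probability one
    child keeps the full range while the other is founded from one of its
    areas chosen uniformly (peripheral isolation).

    The truth log records the *net* realised history: one dispersal per area
    present at a child node but absent from its inherited range and one
    extinction per area lost, each timed at the simulated transition that
    fixed it, plus every cladogenetic event at its node age. Within-branch
    flicker (an area gained and lost again between two nodes) is invisible
    at node resolution; the raw anagenetic event count is kept on the log
    for diagnostics. The returned assignment includes the per-node splits.
    """
    areas = tuple(areas)
    if len(areas) < 2:
        raise ValidationError("need at least 2 areas")
    if d < 0 or e < 0 or not 0 <= clado_prob_vicariance <= 1:
        raise ValidationError("rates must be nonnegative and clado_prob_vicariance in [0,1]")
    rng = as_rng(seed)
    idx = tree.index
    if root_range is None:
        root_range = (areas[int(rng.integers(len(areas)))],)
    root_set = frozenset(root_range)
    if not root_set or not root_set <= set(areas):
        raise ValidationError("root range must be a nonempty subset of the areas")

    ranges: dict[int, frozenset[str]] = {}
    splits: dict[int, tuple[frozenset[str], frozenset[str]]] = {}
    inherited: dict[int, frozenset[str]] = {}
    events: list[Event] = []
    n_raw = 0

    def split_range(p: frozenset[str], node: int, age: float) -> tuple[frozenset, frozenset]:
        nonlocal events
        if len(p) == 1:
            events.append(Event("within_area", age, node, tuple(sorted(p))))
            return p, p
        if rng.random() < clado_prob_vicariance:
            members = sorted(p)
            while True:
                mask = rng.integers(0, 2, size=len(members)).astype(bool)
                if mask.any() and not mask.all():
                    break
            i1 = frozenset(m for m, keep in zip(members, mask) if keep)
            events.append(Event("vicariance", age, node, tuple(sorted(p))))
            return i1, p - i1
        a = sorted(p)[int(rng.integers(len(p)))]
        events.append(Event("peripheral_isolation", age, node, tuple(sorted(p))))
        keeper_first = rng.random() < 0.5
        return (p, frozenset({a})) if keeper_first else (frozenset({a}), p)

    for v in range(idx.n_nodes - 1, -1, -1):
        if v == idx.root:
            ranges[v] = root_set
        else:
            start = inherited[v]
            age_top, age_bot = idx.ages[idx.parent[v]], idx.ages[v]
            r = set(start)
            t = age_top
            last_change: dict[str, float] = {}
            while True:
                unocc = [a for a in areas if a not in r]
                total = d * len(unocc) + e * len(r)
                if total <= 0:
                    break
                t -= rng.exponential(1.0 / total)
                if t <= age_bot:
                    break
                if rng.random() < d * len(unocc) / total:
                    a = unocc[int(rng.integers(len(unocc)))]
                    r.add(a)
                    last_change[a] = t
                    n_raw += 1
                else:
                    occ = sorted(r)
                    a = occ[int(rng.integers(len(occ)))]
                    if len(r) > 1:  # rejection keeps the range nonempty
                        r.remove(a)
                        last_change[a] = t
                        n_raw += 1
            end = frozenset(r)
            for a in sorted(end - start):
                events.append(Event("dispersal", last_change[a], v, (a,)))
            for a in sorted(start - end):
                events.append(Event("extinction", last_change[a], v, (a,)))
            ranges[v] = end
        if not idx.is_tip[v]:
            kids = idx.children[v]
            if len(kids) != 2:
                raise ValidationError("range simulation requires a bifurcating tree")
            i1, i2 = split_range(ranges[v], v, float(idx.ages[v]))
            splits[v] = (i1, i2)
            inherited[int(kids[0])], inherited[int(kids[1])] = i1, i2

    events.sort(key=lambda ev: (-ev.time, ev.node, ev.type, ev.areas))
    log = EventLog(events, root_age=float(idx.depth), n_raw_anagenetic=n_raw)
    return RangeAssignment(ranges, splits=splits), log


# ----------------------------------------------------------------------
# Toy alignments


def generate_toy_alignment(
    n_seqs: int, length: int, indel_events: int, seed
) -> tuple["AlignmentPartition", list[tuple[int, int]]]:
    """Random nucleotide alignment with non-overlapping internal gap runs.

    Each indel event picks a span (never touching the alignment ends, never
    overlapping another span) and a random nonempty proper subset of taxa
    that receive the gap. Returns the alignment and the truth list of spans.
    """
    from .indels import AlignmentPartition

    if n_seqs < 2:
        raise ValidationError("need at least 2 sequences")
    rng = as_rng(seed)
    mat = rng.choice(list("ACGT"), size=(n_seqs, length))
    spans: list[tuple[int, int]] = []
    occupied = np.zeros(length + 2, dtype=bool)  # 1-based with guard cols
    for _ in range(indel_events):
        placed = False
        for _attempt in range(200):
            span_len = int(rng.integers(1, min(6, max(2, length - 2))))
            if span_len > length - 2:
                raise ValidationError("indel span exceeds alignment length")
            s = int(rng.integers(2, length - span_len + 1))
            e = s + span_len - 1
            if not occupied[s - 1 : e + 2].any():
                placed = True
                break
        if not placed:
            break
        occupied[s : e + 1] = True
        n_gapped = int(rng.integers(1, n_seqs))
        rows = rng.choice(n_seqs, size=n_gapped, replace=False)
        mat[rows, s - 1 : e] = "-"
        spans.append((s, e))
    taxa = [f"s{i + 1}" for i in range(n_seqs)]
    seqs = {t: "".join(row) for t, row in zip(taxa, mat)}
    return AlignmentPartition("toy", seqs), sorted(spans)
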