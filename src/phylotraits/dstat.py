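"""Phylogenetic signal in binary traits: the D statistic.

D measures how clumped a presence/absence character is on a phylogeny by
comparing the observed sum of nodal value changes, d_obs, with its
expectation under two simulated extremes at the same prevalence: random
scatter across the tips and a Brownian-motion threshold model. D scales
d_obs between the two null means,

    D = (d_obs - mean_d_brownian) / (mean_d_random - mean_d_brownian),

so D ~ 1 means the trait is distributed essentially at random (no signal)
and D ~ 0 means it is as phylogenetically conserved as Brownian evolution
predicts. Values outside [0, 1] are legitimate (over-dispersed traits give
D > 1, extreme single-clade clumping D < 0) and are reported unclamped.

Nodal values are estimated tips-to-root as the arithmetic mean of child
values (tips carry their 0/1 states), with polytomies handled natively by
the same recursion; d_obs is the sum of |child - parent| over all non-root
nodes. Because D rescales d_obs between null means computed with the same
estimator, the calibration endpoints (1 for random, 0 for Brownian) hold
for any consistent estimator; other implementations may differ numerically
in d_obs itself.

Significance is assessed against the simulated nulls directly:
``p_vs_random`` is the fraction of random-null replicates with d <= d_obs
(departure from randomness toward conservation) and ``p_vs_brownian`` the
fraction of Brownian replicates with d >= d_obs, both with a pseudocount so
a finite simulation never reports p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .simulate import brownian_threshold_states_batch, random_states_batch
from .traits import BinaryTrait
from .trees import PhyloTree, TreeIndex, TreeSample, prune_to_taxa
from .util import as_rng, child_seeds

__all__ = ["DResult", "DSampleSummary", "d_sum", "phylo_d", "phylo_d_over_sample"]


@dataclass
class DResult:
    trait_name: str
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    p_vs_random: float
    p_vs_brownian: float
    n_sim: int
    seed: object = None

    def as_dict(self) -> dict:
        return {
            "trait": self.trait_name,
            "d_obs": self.d_obs,
            "mean_d_random": self.mean_d_random,
            "mean_d_brownian": self.mean_d_brownian,
            "D": self.D,
            "p_vs_random": self.p_vs_random,
            "p_vs_brownian": self.p_vs_brownian,
            "n_sim": self.n_sim,
        }


@dataclass
class DSampleSummary:
    """Per-tree results over a posterior sample plus robust summaries."""

    results: list[DResult]
    failures: list[tuple[int, str]]
    median_D: float
    median_p_vs_random: float
    D_interval: tuple[float, float]  # 2.5 / 97.5 percentiles

    @property
    def n_trees(self) -> int:
        return len(self.results) + len(self.failures)


def d_sums_batch(index: TreeIndex, tip_states: np.ndarray) -> np.ndarray:
    """Sum of nodal value changes for each row of a (n_sims, n_tips) 0/1
    matrix (tips ordered as ``index.tip_labels``)."""
    tip_states = np.atleast_2d(np.asarray(tip_states, dtype=float))
    n_sims = tip_states.shape[0]
    vals = np.empty((index.n_nodes, n_sims))
    vals[index.tip_pos] = tip_states.T
    for i in index.postorder_internal():
        vals[i] = vals[index.children[i]].mean(axis=0)
    # every node except the root (last postorder index) heads one branch
    return np.abs(vals[:-1] - vals[index.parent[:-1]]).sum(axis=0)


def d_sum(tree: PhyloTree, trait: BinaryTrait) -> float:
    """Observed sum of nodal value changes for one trait on one tree."""
    idx = tree.index
    states = idx.states_vector(trait.states)
    if not np.isin(states, (0.0, 1.0)).all():
        raise ValidationError("d_sum needs binary 0/1 tip states")
    return float(d_sums_batch(idx, states[None, :])[0])


def _prepare(tree: PhyloTree, trait: BinaryTrait, missing_policy: str):
    labels = tree.tip_labels
    missing = [l for l in labels if trait.states.get(l) is None]
    if missing:
        if missing_policy == "prune":
            keep = [l for l in labels if l not in set(missing)]
            tree = prune_to_taxa(tree, keep)
        elif missing_policy == "as_absent":
            trait = BinaryTrait(
                trait.name,
                {l: (0 if trait.states.get(l) is None else trait.states[l]) for l in labels},
            )
        else:
            raise ValidationError(
                f"{len(missing)} tips lack a state for {trait.name!r}; "
                "pass missing_policy='prune' or 'as_absent'"
            )
    return tree, trait


def phylo_d(
    tree: PhyloTree,
    trait: BinaryTrait,
    n_sim: int = 1000,
    seed=None,
    missing_policy: str = "error",
) -> DResult:
    """Compute D with simulated nulls at the observed prevalence.

    ``missing_policy`` controls tips without a trait state: ``"error"``
    (default), ``"prune"`` (drop them from the tree), or ``"as_absent"``
    (score them 0).
    """
    if n_sim < 100:
        raise ValidationError("n_sim must be at least 100")
    tree, trait = _prepare(tree, trait, missing_policy)
    idx = tree.index
    states = idx.states_vector(trait.states)
    n = len(states)
    k = int(states.sum())
    if k == 0 or k == n:
        raise ValidationError(
            f"signal undefined at prevalence 0 or n (trait {trait.name!r} is constant)"
        )
    rng = as_rng(seed)
    d_obs = float(d_sums_batch(idx, states[None, :])[0])
    d_rand = d_sums_batch(idx, random_states_batch(n, k, n_sim, rng))
    d_brown = d_sums_batch(idx, brownian_threshold_states_batch(idx, k, n_sim, rng))
    mean_r, mean_b = float(d_rand.mean()), float(d_brown.mean())
    denom = mean_r - mean_b
    if abs(denom) < 1e-9 * max(mean_r, 1e-300):
        raise ValidationError(
            "null means are indistinguishable (degenerate scaling denominator); "
            "the tree is too small or star-like for D"
        )
    return DResult(
        trait_name=trait.name,
        d_obs=d_obs,
        mean_d_random=mean_r,
        mean_d_brownian=mean_b,
        D=(d_obs - mean_b) / denom,
        p_vs_random=(1 + int((d_rand <= d_obs).sum())) / (1 + n_sim),
        p_vs_brownian=(1 + int((d_brown >= d_obs).sum())) / (1 + n_sim),
        n_sim=n_sim,
        seed=seed,
    )


def phylo_d_over_sample(
    sample: TreeSample,
    trait: BinaryTrait,
    n_sim: int = 1000,
    seed=None,
    missing_policy: str = "error",
) -> DSampleSummary:
    """D over a posterior tree sample: per-tree results, median D and p.

    Trees on which the computation fails (constant trait after pruning,
    degenerate denominator) are recorded and excluded from the medians.
    """
    seeds = child_seeds(seed, len(sample))
    results: list[DResult] = []
    failures: list[tuple[int, str]] = []
    for i, tree in enumerate(sample):
        try:
            results.append(phylo_d(tree, trait, n_sim=n_sim, seed=seeds[i],
                                   missing_policy=missing_policy))
        except ValidationError as exc:
            failures.append((i, str(exc)))
    if not results:
        raise ValidationError("phylo_d failed on every tree in the sample")
    ds = np.array([r.D for r in results])
    ps = np.array([r.p_vs_random for r in results])
    return DSampleSummary(
        results=results,
        failures=failures,
        median_D=float(np.median(ds)),
        median_p_vs_random=float(np.median(ps)),
        D_interval=(float(np.percentile(ds, 2.5)), float(np.percentile(ds, 97.5))),
    )
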