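"""Rooted phylogenies and posterior tree samples.

A :class:`PhyloTree` wraps a :class:`dendropy.Tree` (which handles all
Newick/NEXUS parsing, including MrBayes-style translate tables) and adds the
derived quantities the comparative analyses need: node ages on dated trees,
pruning with path-length conservation, and a flattened array view
(:class:`TreeIndex`) used by the vectorised simulation and signal routines.

Conventions: ages are in time units before present (root deepest, tips of an
ultrametric tree at age 0); tip labels are unique with whitespace normalised
to underscores; polytomies are preserved, never silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

from .errors import FormatError, ValidationError
from .util import as_rng, normalize_label

__all__ = [
    "PhyloTree",
    "TreeIndex",
    "TreeSample",
    "read_trees",
    "write_trees",
    "prune_to_taxa",
    "node_ages",
    "subsample_trees",
]


class TreeIndex:
    """Array view of a rooted tree in postorder (root last).

    Attributes
    ----------
    parent : (n_nodes,) int array, -1 for the root.
    blen : (n_nodes,) float array, 0.0 for the root.
    children : list of int arrays, one per node.
    tip_pos : (n_tips,) indices of leaves within the postorder.
    tip_labels : list of str aligned with ``tip_pos``.
    ages : (n_nodes,) float array of node ages (max root-tip depth minus
        root distance).
    """

    def __init__(self, tree: "PhyloTree"):
        nodes = list(tree.dendropy_tree.postorder_node_iter())
        self.nodes = nodes
        self.n_nodes = len(nodes)
        pos = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.blen = np.zeros(self.n_nodes)
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        tip_pos: list[int] = []
        tip_labels: list[str] = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = pos[id(nd.parent_node)]
                children[self.parent[i]].append(i)
                if nd.edge.length is None:
                    raise ValidationError(
                        f"node {nd.taxon.label if nd.taxon else '<internal>'} "
                        "has no branch length"
                    )
                self.blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                tip_pos.append(i)
                tip_labels.append(nd.taxon.label if nd.taxon else "")
        self.children = [np.asarray(c, dtype=np.int64) for c in children]
        self.tip_pos = np.asarray(tip_pos, dtype=np.int64)
        self.tip_labels = tip_labels
        self.tip_index = {lab: j for j, lab in enumerate(tip_labels)}
        self.root = self.n_nodes - 1
        self.is_tip = np.zeros(self.n_nodes, dtype=bool)
        self.is_tip[self.tip_pos] = True
        # root distances via preorder (reverse postorder)
        dist = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 2, -1, -1):
            dist[i] = dist[self.parent[i]] + self.blen[i]
        self.root_distance = dist
        depth = dist[self.tip_pos].max() if len(tip_pos) else 0.0
        self.depth = float(depth)
        self.ages = depth - dist

    # ------------------------------------------------------------------
    def postorder_internal(self) -> Iterator[int]:
        for i in range(self.n_nodes):
            if not self.is_tip[i]:
                yield i

    def states_vector(self, trait_map: dict[str, int]) -> np.ndarray:
        """Tip states in ``tip_pos`` order; raises if a tip is missing."""
        missing = [t for t in self.tip_labels if trait_map.get(t) is None]
        if missing:
            raise ValidationError(
                f"{len(missing)} tips lack a trait state (e.g. {missing[:3]}); "
                "prune the tree or fill the trait first"
            )
        return np.asarray([trait_map[t] for t in self.tip_labels], dtype=float)

    def path_edges(self, a: int, b: int) -> frozenset[int]:
        """Edges (identified by their child node index) on the a--b path."""
        anc_a = []
        x = a
        while x != -1:
            anc_a.append(x)
            x = self.parent[x]
        anc_set = set(anc_a)
        path_b = []
        x = b
        while x not in anc_set:
            path_b.append(x)
            x = self.parent[x]
        mrca = x
        path_a = []
        x = a
        while x != mrca:
            path_a.append(x)
            x = self.parent[x]
        return frozenset(path_a + path_b)

    def patristic_distance(self, label_a: str, label_b: str) -> float:
        a = self.tip_pos[self.tip_index[label_a]]
        b = self.tip_pos[self.tip_index[label_b]]
        return float(self.blen[list(self.path_edges(a, b))].sum())


class PhyloTree:
    """A rooted tree with branch lengths; thin wrapper over dendropy."""

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self.dendropy_tree = tree
        self._index: TreeIndex | None = None
        self._normalize_labels()
        self._validate()

    # ------------------------------------------------------------------
    def _normalize_labels(self) -> None:
        for leaf in self.dendropy_tree.leaf_node_iter():
            if leaf.taxon is not None:
                leaf.taxon.label = normalize_label(leaf.taxon.label)

    def _validate(self) -> None:
        labels = [lf.taxon.label for lf in self.dendropy_tree.leaf_node_iter() if lf.taxon]
        seen: set[str] = set()
        dups = {l for l in labels if l in seen or seen.add(l)}
        if dups:
            raise ValidationError(f"duplicate tip labels: {sorted(dups)}")

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValidationError(f"duplicate tip labels: {exc.message}") from exc
        except (dendropy.utility.error.DataParseError, ValueError) as exc:
            raise FormatError(f"could not parse newick: {exc}") from exc
        return cls(tree)

    def as_newick(self) -> str:
        return (
            self.dendropy_tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
        )

    @property
    def index(self) -> TreeIndex:
        if self._index is None:
            self._index = TreeIndex(self)
        return self._index

    @property
    def tip_labels(self) -> list[str]:
        return list(self.index.tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self.index.tip_pos)

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.dendropy_tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_tips} tips>"


@dataclass
class TreeSample:
    """An ordered list of trees over a shared taxon set (e.g. a posterior)."""

    trees: list[PhyloTree]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValidationError("a TreeSample must contain at least one tree")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def __getitem__(self, i) -> PhyloTree:
        return self.trees[i]

    def shared_taxa(self) -> set[str]:
        taxa = set(self.trees[0].tip_labels)
        for t in self.trees[1:]:
            if set(t.tip_labels) != taxa:
                raise ValidationError("trees in the sample differ in tip-label sets")
        return taxa


# ----------------------------------------------------------------------
# I/O


def read_trees(path: str, format: str = "newick") -> TreeSample:
    """Read all trees from a Newick or NEXUS file, in file order.

    NEXUS translate tables are resolved to full labels; branch lengths are
    preserved to input precision.
    """
    if format not in ("newick", "nexus"):
        raise ValidationError(f"unknown tree format {format!r}")
    try:
        tl = dendropy.TreeList.get(path=path, schema=format)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate tip labels in {path}: {exc.message}") from exc
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise FormatError(f"could not parse {path} as {format}: {exc}") from exc
    if len(tl) == 0:
        raise FormatError(f"no trees found in {path}")
    return TreeSample([PhyloTree(t) for t in tl], source=path)


def write_trees(sample: TreeSample | PhyloTree, path: str, format: str = "newick") -> None:
    """Write trees as Newick lines or a NEXUS TREES block with translate table."""
    trees = [sample] if isinstance(sample, PhyloTree) else list(sample)
    tl = dendropy.TreeList()
    for t in trees:
        tl.append(
            dendropy.Tree.get(data=t.as_newick(), schema="newick",
                              taxon_namespace=tl.taxon_namespace)
        )
    if format == "newick":
        tl.write(path=path, schema="newick", suppress_rooting=True,
                 unquoted_underscores=True)
    elif format == "nexus":
        tl.write(path=path, schema="nexus", translate_tree_taxa=True,
                 unquoted_underscores=True)
    else:
        raise ValidationError(f"unknown tree format {format!r}")


# ----------------------------------------------------------------------
# Manipulation


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Prune to a subset of tips, conserving patristic distances.

    Unbranched internal nodes created by pruning are suppressed with their
    branch lengths summed; the root retains degree >= 2.
    """
    keep = {normalize_label(k) for k in keep}
    have = set(tree.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise ValidationError(f"labels not in tree: {missing}")
    if len(keep) < 2:
        raise ValidationError("cannot prune to fewer than 2 tips")
    sub = tree.dendropy_tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    return PhyloTree(sub)


def node_ages(tree: PhyloTree, tolerance: float = 1e-6) -> tuple[dict, bool]:
    """Node ages (time before present) and an ultrametricity flag.

    Age = (max root-to-tip depth) - (root-to-node distance). The tree is
    flagged non-ultrametric when any tip age exceeds ``tolerance`` times the
    tree depth. Returns ``(ages, is_ultrametric)`` where ``ages`` maps the
    dendropy node object to its age.
    """
    idx = tree.index
    tip_ages = idx.ages[idx.tip_pos]
    is_ultrametric = bool(np.all(np.abs(tip_ages) <= tolerance * max(idx.depth, 1e-300)))
    ages = {idx.nodes[i]: float(idx.ages[i]) for i in range(idx.n_nodes)}
    return ages, is_ultrametric


def subsample_trees(sample: TreeSample, n: int, seed) -> TreeSample:
    """Draw ``n`` trees uniformly without replacement; reproducible per seed."""
    if n <= 0:
        raise ValidationError("n must be positive (empty samples are forbidden)")
    if n > len(sample):
        raise ValidationError(f"cannot draw {n} trees from a sample of {len(sample)}")
    rng = as_rng(seed)
    picks = rng.choice(len(sample), size=n, replace=False)
    return TreeSample([sample[i] for i in picks], source=f"{sample.source}[subsample]")
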