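"""Classification and time-binning of biogeographic events.

Given a dated tree and per-node ancestral range assignments (the kind of
output a dispersal-extinction-cladogenesis reconstruction produces), this
module decomposes the history into node-based cladogenetic events
(vicariance, peripheral isolation, within-area speciation) and branch-based
anagenetic events (dispersal = area gain, extinction = local area loss), and
bins them through time for range-expansion-through-time histograms.

Identifiability note: from node ranges alone the split of a branch's change
into "cladogenetic inheritance" plus "anagenetic gains/losses" is not unique
(a vicariance followed by one dispersal can look exactly like a peripheral
isolation). DEC implementations report the range inherited by each
descendant branch at every split, so :class:`RangeAssignment` carries an
optional ``splits`` map; when present, classification is exact. Without it,
:func:`infer_events` falls back to a minimum-event parsimony resolution with
a deterministic preference order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trees import PhyloTree

__all__ = [
    "DEFAULT_AREAS",
    "DEFAULT_AREA_NAMES",
    "Event",
    "EventLog",
    "RangeAssignment",
    "TimeBinnedEvents",
    "most_probable_ranges",
    "classify_cladogenetic",
    "infer_events",
    "bin_events",
    "read_range_table",
    "write_range_table",
]

#: Single-letter codes for the eight default biogeographic regions
#: (continental Africa plus Arabia, Madagascar and Eurasia).
DEFAULT_AREAS: tuple[str, ...] = ("S", "Z", "C", "E", "H", "A", "M", "U")
DEFAULT_AREA_NAMES: dict[str, str] = {
    "S": "Southern_African",
    "Z": "Zambezian",
    "C": "Congolian",
    "E": "Ethiopian-Somalian",
    "H": "Saharan-Sudanian",
    "A": "Arabia",
    "M": "Madagascar",
    "U": "Eurasia",
}

NODE_EVENT_TYPES = ("vicariance", "peripheral_isolation", "within_area")
BRANCH_EVENT_TYPES = ("dispersal", "extinction")
EVENT_TYPES = BRANCH_EVENT_TYPES + NODE_EVENT_TYPES + ("unclassified",)


@dataclass(frozen=True)
class Event:
    """One classified event: type, age (time before present), node, areas."""

    type: str
    time: float
    node: int
    areas: tuple[str, ...]


@dataclass
class EventLog:
    events: list[Event]
    root_age: float
    #: raw anagenetic event count in a forward simulation (may exceed the
    #: net, observable count when an area flickers within one branch)
    n_raw_anagenetic: int | None = None

    def counts(self) -> Counter:
        return Counter(e.type for e in self.events)

    def of_type(self, *types: str) -> list[Event]:
        return [e for e in self.events if e.type in types]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class RangeAssignment:
    """Per-node area sets, keyed by postorder node index of the tree.

    ``splits`` optionally maps an internal node index to the pair of ranges
    inherited by its two child branches (in the tree's child order), as DEC
    reconstructions report. ``candidates`` optionally holds the per-node
    (range, relative probability) table the assignment was condensed from.
    """

    ranges: dict[int, frozenset[str]]
    splits: dict[int, tuple[frozenset[str], frozenset[str]]] | None = None
    candidates: dict[int, list[tuple[frozenset[str], float]]] | None = None

    def __getitem__(self, node: int) -> frozenset[str]:
        return self.ranges[node]


@dataclass
class TimeBinnedEvents:
    """Counts per event type in right-open time bins descending from the root."""

    edges: np.ndarray  # descending ages, length n_bins + 1
    counts: dict[str, np.ndarray]

    def totals(self) -> dict[str, int]:
        return {t: int(c.sum()) for t, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts)
        df.insert(0, "bin_start_age", self.edges[:-1])
        df.insert(1, "bin_end_age", self.edges[1:])
        return df


# ----------------------------------------------------------------------


def most_probable_ranges(
    prob_table: Mapping[int, Sequence[tuple[Iterable[str], float]]],
    min_probability: float = 0.0,
) -> RangeAssignment:
    """Condense a per-node range-probability table to one range per node.

    Picks the highest-probability candidate; ties broken by smallest range,
    then lexicographically. Nodes whose best candidate falls below
    ``min_probability`` are left unassigned (and will be reported by
    downstream consumers that require a full assignment).
    """
    ranges: dict[int, frozenset[str]] = {}
    candidates: dict[int, list[tuple[frozenset[str], float]]] = {}
    for node, cands in prob_table.items():
        cands = [(frozenset(r), float(p)) for r, p in cands]
        if not cands:
            raise ValidationError(f"node {node} has no candidate ranges")
        candidates[node] = cands
        best = min(cands, key=lambda rp: (-rp[1], len(rp[0]), tuple(sorted(rp[0]))))
        if best[1] >= min_probability:
            ranges[node] = best[0]
    return RangeAssignment(ranges, candidates=candidates)


def classify_cladogenetic(
    parent: Iterable[str], child1: Iterable[str], child2: Iterable[str]
) -> str:
    """Classify one cladogenetic configuration; symmetric in child order.

    within_area: a single-area ancestor copied to both descendants.
    vicariance: the ancestral range split into two disjoint parts.
    peripheral_isolation: one descendant keeps the full ancestral range, the
    other is restricted to a single area of it.
    Anything else is ``unclassified``.
    """
    p, c1, c2 = frozenset(parent), frozenset(child1), frozenset(child2)
    if not p or not c1 or not c2:
        raise ValidationError("cladogenetic ranges must be nonempty")
    if len(p) == 1 and c1 == p and c2 == p:
        return "within_area"
    if not (c1 & c2) and (c1 | c2) == p:
        return "vicariance"
    for keeper, isolate in ((c1, c2), (c2, c1)):
        if keeper == p and len(isolate) == 1 and isolate < p:
            return "peripheral_isolation"
    return "unclassified"


def _resolve_split(
    parent: frozenset[str], c1: frozenset[str], c2: frozenset[str]
) -> tuple[frozenset[str], frozenset[str], str]:
    """Minimum-anagenetic-event resolution of an unannotated split.

    Enumerates every legal cladogenetic scenario for ``parent`` and picks
    the inherited-range pair minimising the implied number of branch events
    ``|c1 ^ i1| + |c2 ^ i2|``. Ties prefer peripheral isolation over
    vicariance (the more common process in range-subdivision histories),
    then the lexicographically smallest scenario, so resolution is
    deterministic.
    """
    if len(parent) == 1:
        return parent, parent, "within_area"
    scenarios: list[tuple[int, int, tuple, frozenset, frozenset, str]] = []
    areas = sorted(parent)
    for a in areas:
        single = frozenset({a})
        scenarios.append((len(c1 ^ parent) + len(c2 ^ single), 0,
                          (a, 0), parent, single, "peripheral_isolation"))
        scenarios.append((len(c1 ^ single) + len(c2 ^ parent), 0,
                          (a, 1), single, parent, "peripheral_isolation"))
    for r in range(1, len(parent)):
        for sub in combinations(areas, r):
            i1 = frozenset(sub)
            i2 = parent - i1
            scenarios.append((len(c1 ^ i1) + len(c2 ^ i2), 1,
                              tuple(sorted(i1)), i1, i2, "vicariance"))
    cost, _, _, i1, i2, kind = min(scenarios, key=lambda s: s[:3])
    return i1, i2, kind


def infer_events(
    tree: PhyloTree,
    ranges: RangeAssignment,
    ultrametric_tolerance: float = 1e-6,
) -> EventLog:
    """Decompose a range reconstruction on a dated tree into an event log.

    At each internal node the cladogenetic event is classified at the node's
    age; along each branch the inherited range (the child side of the split)
    is compared with the child node's range, logging one dispersal per
    gained area and one extinction per lost area at the branch midpoint.
    The log is returned sorted oldest-first.
    """
    idx = tree.index
    tip_ages = idx.ages[idx.tip_pos]
    if np.any(np.abs(tip_ages) > ultrametric_tolerance * max(idx.depth, 1e-300)):
        raise ValidationError("infer_events requires a dated (ultrametric) tree")
    for i in range(idx.n_nodes):
        if i not in ranges.ranges:
            lab = idx.tip_labels[list(idx.tip_pos).index(i)] if idx.is_tip[i] else f"node {i}"
            raise ValidationError(f"no range assigned to {lab}")

    events: list[Event] = []
    inherited: dict[int, frozenset[str]] = {}
    # walk root-down so each child's inherited range is known before its branch
    for v in range(idx.n_nodes - 1, -1, -1):
        if idx.is_tip[v]:
            continue
        p = ranges[v]
        kids = idx.children[v]
        if len(kids) == 2:
            c1, c2 = (ranges[int(k)] for k in kids)
            if ranges.splits and v in ranges.splits:
                i1, i2 = ranges.splits[v]
                kind = classify_cladogenetic(p, i1, i2)
            else:
                i1, i2, kind = _resolve_split(p, c1, c2)
            inherited[int(kids[0])], inherited[int(kids[1])] = i1, i2
            areas = tuple(sorted(p))
        else:
            # polytomies carry no two-way split; children inherit the full
            # range and the node is counted as unclassified
            for k in kids:
                inherited[int(k)] = p
            kind = "unclassified"
            areas = tuple(sorted(p))
        events.append(Event(kind, float(idx.ages[v]), v, areas))

    for c in range(idx.n_nodes - 1):  # every non-root node heads a branch
        inh = inherited[c]
        obs = ranges[c]
        mid = float((idx.ages[idx.parent[c]] + idx.ages[c]) / 2.0)
        for a in sorted(obs - inh):
            events.append(Event("dispersal", mid, c, (a,)))
        for a in sorted(inh - obs):
            events.append(Event("extinction", mid, c, (a,)))

    events.sort(key=lambda e: (-e.time, e.node, e.type, e.areas))
    return EventLog(events, root_age=float(idx.depth))


def bin_events(
    log: EventLog,
    bin_width: float,
    include_types: Sequence[str] = BRANCH_EVENT_TYPES + ("vicariance", "peripheral_isolation"),
) -> TimeBinnedEvents:
    """Bin events into right-open time bins from the root age down to 0.

    Bin *i* covers ages ``(edge[i+1], edge[i]]`` (descending edges); an
    event at exactly the root age lands in the first bin and events at age
    0 in the last. Per-type totals over bins equal the log totals.
    Within-area speciations are excluded from the default four-category
    histogram but remain in the log.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    top = log.root_age
    n_bins = max(1, int(np.ceil(top / bin_width - 1e-12)))
    edges = top - bin_width * np.arange(n_bins + 1)
    edges[-1] = 0.0  # last bin truncated at the present
    counts = {t: np.zeros(n_bins, dtype=int) for t in include_types}
    for e in log:
        if e.type not in counts:
            continue
        # descending right-open: find i with edges[i] >= t > edges[i+1]
        i = int(np.searchsorted(-edges, -e.time, side="left")) - 1
        i = min(max(i, 0), n_bins - 1)
        counts[e.type][i] += 1
    return TimeBinnedEvents(edges=edges, counts=counts)


# ----------------------------------------------------------------------
# Delimited I/O: node id, tip label (blank for internal), areas, probability


def write_range_table(
    ranges: RangeAssignment, tree: PhyloTree, path: str, delimiter: str = "\t"
) -> None:
    idx = tree.index
    tip_of = {int(idx.tip_pos[j]): lab for j, lab in enumerate(idx.tip_labels)}
    with open(path, "w", newline="") as fh:
        fh.write(delimiter.join(["node", "tip_label", "areas"]) + "\n")
        for node in sorted(ranges.ranges):
            areas = "".join(sorted(ranges.ranges[node]))
            fh.write(delimiter.join([str(node), tip_of.get(node, ""), areas]) + "\n")


def read_range_table(path: str, delimiter: str = "\t") -> RangeAssignment:
    """Read a node/areas table; a ``probability`` column triggers condensing
    via :func:`most_probable_ranges`."""
    df = pd.read_csv(path, sep=delimiter)
    if "probability" in df.columns:
        table: dict[int, list[tuple[frozenset[str], float]]] = {}
        for _, row in df.iterrows():
            table.setdefault(int(row["node"]), []).append(
                (frozenset(str(row["areas"])), float(row["probability"]))
            )
        return most_probable_ranges(table)
    ranges = {
        int(row["node"]): frozenset(str(row["areas"])) for _, row in df.iterrows()
    }
    return RangeAssignment(ranges)
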