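import numpy as np
import pytest

import phylotraits as pt
from phylotraits.biogeo import (
    EventLog,
    Event,
    bin_events,
    read_range_table,
    write_range_table,
)
from phylotraits.errors import ValidationError

F = frozenset


# ----------------------------------------------------------------------
# most_probable_ranges


def test_most_probable_argmax():
    ra = pt.most_probable_ranges({0: [(F("A"), 0.7), (F("AB"), 0.3)]})
    assert ra[0] == F("A")


def test_most_probable_tie_prefers_smaller_range():
    ra = pt.most_probable_ranges({0: [(F("AB"), 0.5), (F("A"), 0.5)]})
    assert ra[0] == F("A")


def test_most_probable_empty_candidates_error():
    with pytest.raises(ValidationError):
        pt.most_probable_ranges({0: []})


def test_most_probable_floor_leaves_node_unassigned():
    ra = pt.most_probable_ranges({0: [(F("A"), 0.2)]}, min_probability=0.5)
    assert 0 not in ra.ranges


# ----------------------------------------------------------------------
# classify_cladogenetic


@pytest.mark.parametrize(
    "parent,c1,c2,expected",
    [
        ("AB", "A", "B", "vicariance"),
        ("AB", "AB", "B", "peripheral_isolation"),
        ("A", "A", "A", "within_area"),
        ("ABC", "AB", "C", "vicariance"),
        ("AB", "AB", "AB", "unclassified"),
        ("AB", "A", "C", "unclassified"),
    ],
)
def test_classify_rules(parent, c1, c2, expected):
    assert pt.classify_cladogenetic(F(parent), F(c1), F(c2)) == expected
    assert pt.classify_cladogenetic(F(parent), F(c2), F(c1)) == expected  # symmetry


def test_classify_rejects_empty_ranges():
    with pytest.raises(ValidationError):
        pt.classify_cladogenetic(F("A"), F(""), F("A"))


# ----------------------------------------------------------------------
# infer_events


def test_constant_single_area_history_only_within_area(quartet):
    ranges = pt.RangeAssignment({i: F("S") for i in range(quartet.index.n_nodes)})
    log = pt.infer_events(quartet, ranges)
    assert set(log.counts()) == {"within_area"}
    assert len(log.of_type("within_area")) == 3


def test_single_dispersal_at_branch_midpoint(cherry):
    idx = cherry.index
    a_pos = idx.tip_pos[idx.tip_index["A"]]
    ranges = {i: F("A") for i in range(idx.n_nodes)}
    ranges[int(a_pos)] = F("AB")
    log = pt.infer_events(cherry, pt.RangeAssignment(ranges))
    disp = log.of_type("dispersal")
    assert len(disp) == 1
    assert disp[0].areas == ("B",)
    assert disp[0].time == pytest.approx(0.5)  # midpoint of a length-1 branch
    assert not log.of_type("extinction")


def test_round_trip_exact_counts_with_splits():
    for rep in range(20):
        tree = pt.simulate_yule_tree(32, 1.0, rep)
        ranges, truth = pt.simulate_range_history(tree, d=0.15, e=0.08, seed=rep)
        log = pt.infer_events(tree, ranges)
        assert log.counts() == truth.counts()


def test_round_trip_without_splits_when_no_anagenetic_noise():
    """With d = e = 0 the minimum-event fallback resolves every split
    exactly, even for multi-area roots."""
    for rep in range(10):
        tree = pt.simulate_yule_tree(24, 1.0, rep)
        ranges, truth = pt.simulate_range_history(
            tree, d=0.0, e=0.0, seed=rep, root_range=("S", "Z", "C")
        )
        blind = pt.RangeAssignment(dict(ranges.ranges))  # drop the splits
        log = pt.infer_events(tree, blind)
        assert log.counts() == truth.counts()


def test_zero_extinction_rate_infers_zero_extinctions():
    for rep in range(10):
        tree = pt.simulate_yule_tree(32, 1.0, 100 + rep)
        ranges, _ = pt.simulate_range_history(tree, d=0.2, e=0.0, seed=rep)
        log = pt.infer_events(tree, ranges)
        assert not log.of_type("extinction")


def test_missing_assignment_names_node(quartet):
    ranges = {i: F("S") for i in range(quartet.index.n_nodes)}
    del ranges[0]
    with pytest.raises(ValidationError, match="range"):
        pt.infer_events(quartet, pt.RangeAssignment(ranges))


def test_non_ultrametric_tree_rejected():
    tree = pt.PhyloTree.from_newick("(A:1,B:5);")
    ranges = pt.RangeAssignment({i: F("S") for i in range(3)})
    with pytest.raises(ValidationError, match="ultrametric"):
        pt.infer_events(tree, ranges)


# ----------------------------------------------------------------------
# bin_events


def test_bin_empty_log_all_zero():
    log = EventLog([], root_age=4.0)
    binned = bin_events(log, 1.0)
    assert all(c.sum() == 0 for c in binned.counts.values())


def test_bin_single_event_binning_convention():
    log = EventLog([Event("dispersal", 3.2, 0, ("A",))], root_age=4.0)
    binned = bin_events(log, 1.0)
    assert list(binned.edges) == [4.0, 3.0, 2.0, 1.0, 0.0]
    assert binned.counts["dispersal"].tolist() == [1, 0, 0, 0]  # bin [4,3)


def test_bin_totals_conserved_per_type():
    tree = pt.simulate_yule_tree(48, 1.0, 7)
    ranges, _ = pt.simulate_range_history(tree, d=0.2, e=0.1, seed=8)
    log = pt.infer_events(tree, ranges)
    binned = bin_events(log, 0.37)
    for t, total in binned.totals().items():
        assert total == len(log.of_type(t))


def test_bin_width_validated():
    with pytest.raises(ValidationError):
        bin_events(EventLog([], root_age=1.0), 0.0)


# ----------------------------------------------------------------------
# I/O


def test_range_table_round_trip(tmp_path, quartet):
    ranges, _ = pt.simulate_range_history(quartet, seed=1)
    p = tmp_path / "ranges.tsv"
    write_range_table(ranges, quartet, str(p))
    back = read_range_table(str(p))
    assert back.ranges == ranges.ranges


def test_range_table_with_probabilities(tmp_path):
    p = tmp_path / "probs.tsv"
    p.write_text(
        "node\tareas\tprobability\n0\tA\t0.7\n0\tAB\t0.3\n1\tB\t1.0\n"
    )
    ra = read_range_table(str(p))
    assert ra[0] == F("A")
    assert ra[1] == F("B")
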