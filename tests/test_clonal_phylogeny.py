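import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ith_ihc import (
    Cohort,
    ConflictError,
    LossEvent,
    TreeShape,
    build_tree,
    classify_events,
    classify_shape,
    cohort_tree_summary,
    extract_events,
    pair_relation,
    resolve_conflicts,
    to_newick,
    tumor_tree,
)

from conftest import make_tumor

MARKERS = ("PBRM1", "ARID1A", "SETD2", "BRG1", "BRM")


# ---------------------------------------------------------------- events

def test_extract_events_worked_example(worked_example_tumor):
    events = extract_events(worked_example_tumor, MARKERS)
    assert [(e.markers, set(e.support)) for e in events] == [
        (("ARID1A", "BRM"), {"R1", "R2", "R3"}),
        (("PBRM1", "BRG1"), {"R3"}),
    ]


def test_extract_events_all_retained():
    t = make_tumor("T1", 1, ["F1", "F2"], {})
    assert extract_events(t, MARKERS) == []


@given(st.integers(0, 2 ** 20 - 1))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_extract_events_equals_column_equality_classes(bits):
    """Events are exactly the equality classes of loss columns."""
    foci = ["F1", "F2", "F3", "F4"]
    lost = {
        m: {f for j, f in enumerate(foci) if (bits >> (k * 4 + j)) & 1}
        for k, m in enumerate(MARKERS)
    }
    t = make_tumor("T", 1, foci, lost)
    events = extract_events(t, MARKERS)
    # oracle: group marker columns by identical lost-focus sets
    oracle = {}
    for m in MARKERS:
        if lost[m]:
            oracle.setdefault(frozenset(lost[m]), set()).add(m)
    assert {e.support: set(e.markers) for e in events} == oracle
    # deterministic ordering: descending support size
    sizes = [len(e.support) for e in events]
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------- relations

@pytest.mark.parametrize(
    "s1,s2,expected",
    [
        ({"R1", "R2", "R3"}, {"R3"}, "nested"),
        ({"R1"}, {"R2"}, "disjoint"),
        ({"R1", "R2"}, {"R2", "R3"}, "conflict"),
        ({"R1"}, {"R1"}, "equal"),
    ],
)
def test_pair_relation(s1, s2, expected):
    assert pair_relation(frozenset(s1), frozenset(s2)) == expected
    assert pair_relation(frozenset(s2), frozenset(s1)) == expected


def test_pair_relation_rejects_empty():
    with pytest.raises(ValueError):
        pair_relation(frozenset(), frozenset({"R1"}))


# ---------------------------------------------------------------- conflicts

def _min_laminar_pieces(support, family):
    """Brute-force minimum number of pieces `support` must split into so
    that every piece is nested-or-disjoint w.r.t. every set in `family`."""
    elems = sorted(support)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best = len(elems)
    for part in partitions(elems):
        ok = all(
            pair_relation(frozenset(p), s) != "conflict"
            for p in part
            for s in family
        )
        if ok:
            best = min(best, len(part))
    return best


def test_resolve_conflicts_laminar_input_unchanged(worked_example_tumor):
    events = extract_events(worked_example_tumor, MARKERS)
    resolved, log = resolve_conflicts(events, policy="split", markers=MARKERS)
    assert resolved == events
    assert log == []


def test_resolve_conflicts_splits_overlap():
    ev = [
        LossEvent(("PBRM1",), frozenset({"R1", "R2"})),
        LossEvent(("ARID1A",), frozenset({"R2", "R3"})),
    ]
    resolved, log = resolve_conflicts(ev, policy="split", markers=MARKERS)
    got = {(e.markers, e.support) for e in resolved}
    assert got == {
        (("PBRM1",), frozenset({"R1", "R2"})),
        (("ARID1A",), frozenset({"R2"})),
        (("ARID1A",), frozenset({"R3"})),
    }
    assert len(log) == 1 and log[0]["event"] == "ARID1A"


def test_resolve_conflicts_strict_raises_naming_pair():
    ev = [
        LossEvent(("PBRM1",), frozenset({"R1", "R2"})),
        LossEvent(("ARID1A",), frozenset({"R2", "R3"})),
    ]
    with pytest.raises(ConflictError, match="ARID1A"):
        resolve_conflicts(ev, policy="strict", markers=MARKERS)


@given(st.integers(0, 2 ** 16 - 1))
@settings(max_examples=120, deadline=None, derandomize=True)
def test_resolve_conflicts_split_is_minimal_per_event(bits):
    """Each conflicting event ends in the fewest laminar pieces possible
    given the events already placed (verified by partition enumeration)."""
    foci = ["F1", "F2", "F3", "F4"]
    lost = {
        m: {f for j, f in enumerate(foci) if (bits >> (k * 4 + j)) & 1}
        for k, m in enumerate(MARKERS[:4])
    }
    t = make_tumor("T", 1, foci, lost, markers=MARKERS[:4])
    events = extract_events(t, MARKERS[:4])
    resolved, _ = resolve_conflicts(events, policy="split", markers=MARKERS[:4])
    sups = [e.support for e in resolved]
    # output family is laminar
    assert all(
        pair_relation(a, b) != "conflict"
        for a, b in itertools.combinations(sups, 2)
    )
    # replay insertions: count pieces per original event, compare to optimum
    placed = []
    for ev in events:
        pieces = [
            e.support for e in resolved
            if set(ev.markers) & set(e.markers) and e.support <= ev.support
        ]
        assert frozenset().union(*pieces) == ev.support  # evidence conserved
        assert len(pieces) == _min_laminar_pieces(ev.support, placed)
        placed.extend(pieces)


# ---------------------------------------------------------------- trees

def test_build_tree_worked_example_chain(worked_example_tumor):
    tree, log = tumor_tree(worked_example_tumor, MARKERS)
    assert log == []
    root = tree.root
    assert root.label == "WT"
    assert [c.label for c in root.children] == ["ARID1A+BRM"]
    (am,) = root.children
    assert [c.label for c in am.children] == ["PBRM1+BRG1"]
    assert am.children[0].children == []


def test_build_tree_two_disjoint_trunks():
    t = make_tumor(
        "T1", 4, ["F1", "F2", "F3", "F4"],
        {"PBRM1": {"F1", "F2"}, "BRM": {"F3", "F4"}},
    )
    tree, _ = tumor_tree(t, MARKERS)
    assert len(tree.root.children) == 2
    assert classify_shape(tree) is TreeShape.MULTI_TRUNK


def test_build_tree_empty_events_gives_root_only():
    tree = build_tree([], frozenset({"F1", "F2"}), tumor_id="T")
    assert tree.root.children == []
    assert classify_shape(tree) is TreeShape.NO_LOSS


def test_build_tree_rejects_non_laminar():
    ev = [
        LossEvent(("PBRM1",), frozenset({"R1", "R2"})),
        LossEvent(("ARID1A",), frozenset({"R2", "R3"})),
    ]
    with pytest.raises(ConflictError):
        build_tree(ev, frozenset({"R1", "R2", "R3"}), markers=MARKERS)


# ---------------------------------------------------------------- labels

def test_classify_events_worked_example(worked_example_tumor):
    tree, _ = tumor_tree(worked_example_tumor, MARKERS)
    labels = classify_events(tree, tau=0.75)
    by_event = labels.set_index("event")["label"].to_dict()
    assert by_event == {"ARID1A+BRM": "truncal", "PBRM1+BRG1": "branch"}


def test_classify_events_any_loss_denominator(worked_example_tumor):
    # only 3 of 4 foci carry a loss; under the any-loss denominator the
    # 3-focus trunk covers 3/3 and is truncal for every tau
    tree, _ = tumor_tree(worked_example_tumor, MARKERS)
    labels = classify_events(tree, tau=1.0, denominator="any-loss")
    assert labels.set_index("event")["label"]["ARID1A+BRM"] == "truncal"


def test_classify_events_full_support_truncal_any_tau():
    t = make_tumor("T", 1, ["F1", "F2", "F3", "F4"],
                   {"SETD2": {"F1", "F2", "F3", "F4"}})
    tree, _ = tumor_tree(t, MARKERS)
    for tau in (0.25, 0.75, 1.0):
        assert (classify_events(tree, tau=tau)["label"] == "truncal").all()


def test_classify_events_minority_trunk_flagged():
    t = make_tumor("T", 1, ["F1", "F2", "F3", "F4"], {"SETD2": {"F1"}})
    tree, _ = tumor_tree(t, MARKERS)
    labels = classify_events(tree, tau=0.75)
    row = labels.iloc[0]
    assert row["label"] == "branch" and row["flagged_trunk"]


def test_classify_events_rejects_bad_tau(worked_example_tumor):
    tree, _ = tumor_tree(worked_example_tumor, MARKERS)
    with pytest.raises(ValueError):
        classify_events(tree, tau=0.0)
    with pytest.raises(ValueError):
        classify_events(tree, tau=1.5)


# ---------------------------------------------------------------- shapes

def test_shape_taxonomy():
    foci = ["F1", "F2", "F3", "F4"]
    cases = {
        TreeShape.NO_LOSS: {},
        TreeShape.TRUNK_ONLY: {"PBRM1": set(foci)},
        TreeShape.BRANCHED: {"PBRM1": set(foci), "SETD2": {"F1"}},
        TreeShape.BIFURCATED: {"PBRM1": set(foci), "SETD2": {"F1"}, "BRM": {"F2"}},
        TreeShape.MULTI_TRUNK: {"PBRM1": {"F1"}, "BRM": {"F2"}},
    }
    for expected, lost in cases.items():
        tree, _ = tumor_tree(make_tumor("T", 1, foci, lost), MARKERS)
        assert classify_shape(tree) is expected, expected


def test_worked_example_shape_is_branched(worked_example_tumor):
    tree, _ = tumor_tree(worked_example_tumor, MARKERS)
    assert classify_shape(tree) is TreeShape.BRANCHED


# ---------------------------------------------------------------- newick

def test_newick_worked_example(worked_example_tumor):
    tree, _ = tumor_tree(worked_example_tumor, MARKERS)
    assert to_newick(tree) == "((PBRM1+BRG1)ARID1A+BRM)WT;"


def test_newick_root_only():
    tree = build_tree([], frozenset({"F1"}))
    assert to_newick(tree) == "WT;"


def test_newick_round_trips_topology():
    dendropy = pytest.importorskip("dendropy")
    t = make_tumor(
        "T", 1, ["F1", "F2", "F3", "F4"],
        {"PBRM1": {"F1", "F2", "F3", "F4"}, "SETD2": {"F1"}, "BRM": {"F2", "F3"}},
    )
    tree, _ = tumor_tree(t, MARKERS)
    parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
    # same number of nodes and same multiset of labels
    ours = sorted(n.label for n in tree.nodes())
    theirs = sorted(
        (nd.taxon.label if nd.taxon else nd.label) for nd in parsed
    )
    assert ours == theirs
    # parent/child label pairs agree
    def edges(nd):
        lab = nd.taxon.label if nd.taxon else nd.label
        for c in nd.child_nodes():
            clab = c.taxon.label if c.taxon else c.label
            yield (lab, clab)
            yield from edges(c)
    our_edges = sorted(
        (p.label, c.label)
        for p in tree.nodes()
        for c in p.children
    )
    assert sorted(edges(parsed.seed_node)) == our_edges


# ---------------------------------------------------------------- cohort

def test_cohort_summary_counts(worked_example_tumor, all_retained_cohort):
    cohort = Cohort(tumors=[worked_example_tumor] + list(all_retained_cohort.tumors))
    summary = cohort_tree_summary(cohort)
    shapes = summary["shapes"]
    # shape counts sum to tumor count
    assert shapes.loc["all"].sum() == len(cohort)
    assert shapes.loc["all", "NO_LOSS"] == 8
    assert shapes.loc["all", "BRANCHED"] == 1
    labels = summary["event_labels"]
    assert labels.loc["ARID1A", "truncal"] == 1
    assert labels.loc["PBRM1", "branch"] == 1


def test_cohort_summary_all_retained(all_retained_cohort):
    summary = cohort_tree_summary(all_retained_cohort)
    assert (summary["shapes"].loc["all", "NO_LOSS"]) == len(all_retained_cohort)
    assert (summary["any_loss"]["proportion"] == 0).all()
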