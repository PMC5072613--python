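"""Per-tumor clonal trees from binary loss matrices.

Clonal ordering treats each marker's *support set* (the foci in which it
is lost) as a clone's footprint.  A family of support sets that is
*laminar* — any two sets nested or disjoint — is exactly representable
as a rooted tree: the loss-free founder (WT) at the root, one node per
loss event, parent = smallest support strictly containing the child's.
Events seen in all or most foci are truncal (early); events confined to
a subset of foci are branch (late).

Overlapping-but-non-nested supports are incompatible with a single tree
and indicate convergent (parallel) loss; `resolve_conflicts` either
rejects them (``strict``) or splits the smaller event into parallel
occurrences (``split``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .cohort import Cohort, TumorGrid, stage_to_roman
from .loss_calling import marker_support, tumor_marker_loss, LOST

#: Fraction of foci a root-attached event must cover to be called truncal.
DEFAULT_TAU = 0.75

EQUAL = "equal"
NESTED = "nested"
DISJOINT = "disjoint"
CONFLICT = "conflict"


class TreeShape(enum.Enum):
    """Coarse taxonomy of per-tumor clone-tree shapes."""

    NO_LOSS = "NO_LOSS"          # root only: no marker lost
    TRUNK_ONLY = "TRUNK_ONLY"    # a single event chain of depth 1
    BRANCHED = "BRANCHED"        # a single chain of depth >= 2
    BIFURCATED = "BIFURCATED"    # some non-root node has >= 2 children
    MULTI_TRUNK = "MULTI_TRUNK"  # root has >= 2 children


@dataclass(frozen=True)
class LossEvent:
    """A maximal set of markers lost in exactly the same foci of one tumor."""

    markers: tuple[str, ...]
    support: frozenset[str]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("LossEvent needs at least one marker")
        if not self.support:
            raise ValueError("LossEvent needs non-empty support")

    def label(self) -> str:
        return "+".join(self.markers)


@dataclass
class TreeNode:
    """One clone in a ClonalTree.  The root carries no event."""

    event: Optional[LossEvent]
    support: frozenset[str]
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def label(self) -> str:
        return "WT" if self.event is None else self.event.label()


@dataclass
class ClonalTree:
    """Rooted clone tree of one tumor; root = loss-free founder (WT)."""

    tumor_id: str
    root: TreeNode

    def nodes(self) -> list[TreeNode]:
        """All nodes in preorder."""
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def events(self) -> list[LossEvent]:
        return [n.event for n in self.nodes() if n.event is not None]

    def depth(self) -> int:
        def _d(n: TreeNode) -> int:
            return 1 + max((_d(c) for c in n.children), default=0)

        return _d(self.root) - 1


def _marker_sort_key(markers: Iterable[str], registry: tuple[str, ...]):
    ms = list(markers)
    return tuple(registry.index(m) if m in registry else len(registry) for m in ms)


def _event_order_key(e: LossEvent, registry: tuple[str, ...]):
    # Descending support size, then fixed marker order, then support ids.
    return (-len(e.support), _marker_sort_key(e.markers, registry), tuple(sorted(e.support)))


def extract_events(
    tumor: TumorGrid, markers: tuple[str, ...]
) -> list[LossEvent]:
    """Group markers by identical support over evaluable foci.

    Markers never lost produce no event.  Output order is deterministic:
    descending support size, then fixed marker-registry order.
    """
    groups: dict[frozenset[str], list[str]] = {}
    for m in markers:
        sup = marker_support(tumor, m)
        if sup:
            groups.setdefault(sup, []).append(m)
    events = [
        LossEvent(
            markers=tuple(sorted(ms, key=lambda m: _marker_sort_key([m], markers))),
            support=sup,
        )
        for sup, ms in groups.items()
    ]
    events.sort(key=lambda e: _event_order_key(e, markers))
    return events


def pair_relation(s1: frozenset, s2: frozenset) -> str:
    """Relation of two support sets: equal / nested / disjoint / conflict."""
    if not s1 or not s2:
        raise ValueError("support sets must be non-empty")
    if s1 == s2:
        return EQUAL
    if s1 < s2 or s2 < s1:
        return NESTED
    if not (s1 & s2):
        return DISJOINT
    return CONFLICT


class ConflictError(ValueError):
    """Raised in strict mode when supports overlap without nesting."""


def resolve_conflicts(
    events: list[LossEvent],
    policy: str = "split",
    markers: tuple[str, ...] = (),
) -> tuple[list[LossEvent], list[dict]]:
    """Make an event family laminar.

    ``strict`` raises :class:`ConflictError` on the first conflicting
    pair.  ``split`` processes events in deterministic order (descending
    support size) and, whenever an event's support conflicts with an
    already-accepted set, splits it into its intersection with and
    difference from that set — interpreting the pieces as parallel
    (convergent) occurrences of the same marker loss.  Splitting recurses
    until every piece nests or is disjoint; pieces with identical support
    are merged back into single multi-marker events.

    Returns the laminar event list plus a log of splits, one record per
    split with the event label, the conflicting set and the two pieces.
    """
    if policy not in ("strict", "split"):
        raise ValueError(f"unknown policy {policy!r}")
    ordered = sorted(events, key=lambda e: _event_order_key(e, markers))
    accepted: list[frozenset[str]] = []
    pieces: list[LossEvent] = []
    log: list[dict] = []

    def insert(ev: LossEvent) -> None:
        conflicts = [s for s in accepted if pair_relation(ev.support, s) == CONFLICT]
        if not conflicts:
            if ev.support not in accepted:
                accepted.append(ev.support)
            pieces.append(ev)
            return
        if policy == "strict":
            raise ConflictError(
                f"conflicting supports: {ev.label()}@{sorted(ev.support)} vs "
                f"{sorted(conflicts[0])}"
            )
        # Split against the largest conflicting accepted set first.
        blocker = max(conflicts, key=lambda s: (len(s), tuple(sorted(s))))
        inner = ev.support & blocker
        outer = ev.support - blocker
        log.append(
            {
                "event": ev.label(),
                "support": sorted(ev.support),
                "conflicts_with": sorted(blocker),
                "pieces": [sorted(inner), sorted(outer)],
            }
        )
        insert(LossEvent(ev.markers, frozenset(inner)))
        insert(LossEvent(ev.markers, frozenset(outer)))

    for ev in ordered:
        insert(ev)

    # Merge pieces that ended up with identical support.
    merged: dict[frozenset[str], list[str]] = {}
    for p in pieces:
        merged.setdefault(p.support, []).extend(p.markers)
    out = [
        LossEvent(
            markers=tuple(
                sorted(set(ms), key=lambda m: _marker_sort_key([m], markers))
            ),
            support=sup,
        )
        for sup, ms in merged.items()
    ]
    out.sort(key=lambda e: _event_order_key(e, markers))
    return out, log


def is_laminar(supports: list[frozenset]) -> bool:
    return all(
        pair_relation(a, b) != CONFLICT
        for i, a in enumerate(supports)
        for b in supports[i + 1:]
    )


def build_tree(
    events: list[LossEvent],
    evaluable_foci: frozenset[str],
    tumor_id: str = "",
    markers: tuple[str, ...] = (),
) -> ClonalTree:
    """Assemble the clone tree of a laminar event family.

    Each event's parent is the event with the smallest support strictly
    containing its own (the root if none).  Sibling order is
    deterministic (descending support size, then marker order).
    """
    sups = [e.support for e in events]
    if not is_laminar(sups):
        raise ConflictError("build_tree requires a laminar event family")
    ordered = sorted(events, key=lambda e: _event_order_key(e, markers))
    root = TreeNode(event=None, support=frozenset(evaluable_foci))
    nodes = [TreeNode(event=e, support=e.support) for e in ordered]
    for i, n in enumerate(nodes):
        # candidate parents appear earlier in the size-descending order
        parent = root
        for m in nodes[:i]:
            if n.support < m.support:
                parent = m  # later candidates have smaller support: keep last
        parent.children.append(n)
    return ClonalTree(tumor_id=tumor_id, root=root)


def classify_events(
    tree: ClonalTree,
    tau: float = DEFAULT_TAU,
    denominator: str = "evaluable",
) -> pd.DataFrame:
    """Label each event truncal or branch.

    A root-attached event is truncal iff its support covers at least
    ``tau`` of the denominator foci; everything deeper is branch.  The
    denominator is either all evaluable foci (``evaluable``) or only foci
    carrying at least one loss (``any-loss``).  A root-attached event
    below the threshold is labelled branch and flagged, since a
    trunk-position event with minority support is structurally ambiguous.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau must lie in (0,1], got {tau!r}")
    if denominator not in ("evaluable", "any-loss"):
        raise ValueError(f"unknown denominator {denominator!r}")
    if denominator == "evaluable":
        denom_foci = tree.root.support
    else:
        denom_foci = frozenset().union(
            *(n.support for n in tree.root.children)
        ) if tree.root.children else frozenset()
    rows = []

    def visit(node: TreeNode, at_root: bool) -> None:
        for child in node.children:
            if at_root:
                frac = (len(child.support) / len(denom_foci)) if denom_foci else math.nan
                truncal = bool(denom_foci) and frac >= tau
                flagged = not truncal
            else:
                truncal, flagged = False, False
            rows.append(
                {
                    "event": child.label,
                    "markers": list(child.event.markers),
                    "support": sorted(child.support),
                    "n_support": len(child.support),
                    "n_denominator": len(denom_foci),
                    "label": "truncal" if truncal else "branch",
                    "flagged_trunk": flagged and at_root,
                }
            )
            visit(child, at_root=False)

    visit(tree.root, at_root=True)
    return pd.DataFrame(
        rows,
        columns=[
            "event", "markers", "support", "n_support",
            "n_denominator", "label", "flagged_trunk",
        ],
    )


def classify_shape(tree: ClonalTree) -> TreeShape:
    """Assign the tree-shape taxon of one tumor's clone tree."""
    root = tree.root
    if not root.children:
        return TreeShape.NO_LOSS
    if len(root.children) >= 2:
        return TreeShape.MULTI_TRUNK
    if any(len(n.children) >= 2 for n in tree.nodes() if n is not root):
        return TreeShape.BIFURCATED
    return TreeShape.TRUNK_ONLY if tree.depth() == 1 else TreeShape.BRANCHED


def to_newick(tree: ClonalTree) -> str:
    """Serialize a clone tree as Newick with labelled internal nodes.

    Labels are marker names joined by '+', root labelled WT, no branch
    lengths; e.g. a WT -> AM -> PG chain becomes
    ``((PBRM1+BRG1)ARID1A+BRM)WT;``.
    """

    def render(node: TreeNode) -> str:
        if not node.children:
            return node.label
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){node.label}"

    return render(tree.root) + ";"


def tumor_tree(
    tumor: TumorGrid,
    markers: tuple[str, ...],
    policy: str = "split",
) -> tuple[ClonalTree, list[dict]]:
    """Full per-tumor pipeline: events -> laminar resolution -> tree."""
    events = extract_events(tumor, markers)
    laminar, log = resolve_conflicts(events, policy=policy, markers=markers)
    evaluable = frozenset(tumor.evaluable_foci(markers))
    tree = build_tree(laminar, evaluable, tumor_id=tumor.tumor_id, markers=markers)
    return tree, log


def cohort_tree_summary(
    cohort: Cohort,
    tau: float = DEFAULT_TAU,
    denominator: str = "evaluable",
    policy: str = "split",
) -> dict:
    """Cohort-wide tree statistics.

    Returns a dict with:

    ``shapes``
        DataFrame of TreeShape counts per stage (plus 'all').
    ``any_loss``
        per-stage fraction of tumors with >=1 event.
    ``event_labels``
        per-marker truncal vs branch event counts.
    ``trees``
        mapping tumor_id -> (ClonalTree, shape, Newick string).
    """
    trees: dict[str, tuple[ClonalTree, TreeShape, str]] = {}
    label_rows = []
    shape_rows = []
    for t in cohort:
        tree, _ = tumor_tree(t, cohort.markers, policy=policy)
        shape = classify_shape(tree)
        trees[t.tumor_id] = (tree, shape, to_newick(tree))
        shape_rows.append({"tumor_id": t.tumor_id, "stage": stage_to_roman(t.stage), "shape": shape.value})
        labels = classify_events(tree, tau=tau, denominator=denominator)
        for _, r in labels.iterrows():
            for m in r["markers"]:
                label_rows.append(
                    {"tumor_id": t.tumor_id, "stage": stage_to_roman(t.stage), "marker": m, "label": r["label"]}
                )
    shape_df = pd.DataFrame(shape_rows)
    shape_counts = (
        shape_df.groupby(["stage", "shape"]).size().unstack(fill_value=0)
        if not shape_df.empty
        else pd.DataFrame()
    )
    for s in TreeShape:
        if not shape_counts.empty and s.value not in shape_counts.columns:
            shape_counts[s.value] = 0
    if not shape_counts.empty:
        shape_counts = shape_counts[[s.value for s in TreeShape]]
        shape_counts.loc["all"] = shape_counts.sum()
    label_df = pd.DataFrame(label_rows, columns=["tumor_id", "stage", "marker", "label"])
    event_labels = (
        label_df.groupby(["marker", "label"]).size().unstack(fill_value=0)
        if not label_df.empty
        else pd.DataFrame()
    )
    from .loss_calling import any_loss_fraction

    return {
        "shapes": shape_counts,
        "shape_per_tumor": shape_df,
        "any_loss": any_loss_fraction(cohort, by_stage=True),
        "event_labels": event_labels,
        "trees": trees,
    }
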