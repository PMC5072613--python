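"""Synthetic cohorts with planted clone trees.

The generator emulates a multi-region tissue-microarray study: tumors
sampled as a handful of spatially separated foci, each scored 0/1/2 for
a panel of nuclear markers.  Losses are planted on a per-tumor clone
tree — truncal events span every focus, branch events occupy laminar
minority subsets — so the analysis pipeline can be validated against
known ground truth.

Model assumptions (and what they leave out):

* Each marker is lost by at most one clonal event per tumor; bundled
  markers (e.g. PBRM1+ARID1A) can be lost together as a single event,
  which is what produces co-loss enrichment.
* Branch supports are proper minority subsets of their parent's foci,
  pairwise disjoint among siblings, so every planted tree is laminar and
  every clone is observed in at least one focus.  With no score noise
  and no missing cells the planted tree is therefore exactly
  recoverable — identifiability is a property of the model, not luck.
* Foci are exchangeable: no spatial autocorrelation between neighbouring
  regions, no clone mixing within a focus.
* Stage modulates event rates through per-event multipliers only; no
  growth dynamics are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, DEFAULT_MARKERS, TumorGrid, stage_to_roman
from .clonal_phylogeny import (
    ClonalTree,
    LossEvent,
    TreeNode,
    build_tree,
    classify_events,
    to_newick,
    tumor_tree,
)

#: Default per-tumor event occurrence probabilities (stage multiplier 1).
#: Bundles mirror the observed co-loss structure: PBRM1 travels with
#: ARID1A, BRG1 with BRM.  Values are set so the implied cohort-average
#: tumor-level prevalences approximate 31/51/14/15/38% for
#: PBRM1/ARID1A/SETD2/BRG1/BRM.
DEFAULT_EVENT_PROBS: dict[frozenset[str], float] = {
    frozenset({"PBRM1", "ARID1A"}): 0.28,
    frozenset({"BRG1", "BRM"}): 0.12,
    frozenset({"PBRM1"}): 0.04,
    frozenset({"ARID1A"}): 0.32,
    frozenset({"SETD2"}): 0.14,
    frozenset({"BRG1"}): 0.03,
    frozenset({"BRM"}): 0.295,
}

#: Per-event multipliers for stages I-IV, loosely following the observed
#: stage trends (PBRM1/SETD2 rising, BRM falling, BRG1 fluctuating).
DEFAULT_STAGE_MULTIPLIERS: dict[frozenset[str], tuple[float, float, float, float]] = {
    frozenset({"PBRM1", "ARID1A"}): (0.80, 0.95, 0.75, 1.50),
    frozenset({"BRG1", "BRM"}): (1.10, 1.40, 0.60, 0.90),
    frozenset({"PBRM1"}): (0.80, 0.95, 0.75, 1.50),
    frozenset({"ARID1A"}): (0.80, 1.00, 1.10, 1.10),
    frozenset({"SETD2"}): (0.40, 0.90, 1.10, 1.60),
    frozenset({"BRG1"}): (1.10, 1.40, 0.60, 0.90),
    frozenset({"BRM"}): (1.25, 1.15, 0.70, 0.90),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Defaults reproduce the reference study design: 40 tumors per stage
    across four stages, four foci per tumor with a single two-focus
    tumor, five SWI/SNF-pathway markers.
    """

    n_per_stage: int = 40
    n_stages: int = 4
    n_foci: int = 4
    two_focus_tumor: bool = True
    markers: tuple[str, ...] = DEFAULT_MARKERS
    event_probs: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_PROBS))
    stage_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MULTIPLIERS)
    )
    #: probability an occurring event is truncal (spans all foci)
    p_truncal: float = 0.30
    #: probability a branch event nests under an existing branch clone
    p_nest: float = 0.25
    #: candidate branch-support sizes; capped below ceil(tau*F) so branch
    #: events stay in the minority of foci
    branch_support_sizes: tuple[int, ...] = (1, 2)
    #: probability an expressed (non-lost) cell scores 1 instead of 2
    score_noise: float = 0.10
    #: probability a cell is blanked to non-evaluable
    missing_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        probs = (
            [self.p_truncal, self.p_nest, self.score_noise, self.missing_rate]
            + list(self.event_probs.values())
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0,1]")
        if self.n_foci < 2:
            raise ValueError("need at least two foci per tumor")
        if self.n_per_stage < 1 or self.n_stages < 1:
            raise ValueError("cohort dimensions must be positive")
        for ev in self.event_probs:
            unknown = set(ev) - set(self.markers)
            if unknown:
                raise ValueError(f"event {sorted(ev)} uses unknown markers {sorted(unknown)}")
        if any(s < 1 or s >= self.n_foci for s in self.branch_support_sizes):
            raise ValueError("branch support sizes must lie in [1, n_foci)")


@dataclass
class GroundTruth:
    """Planted truth for one simulated cohort."""

    trees: dict[str, ClonalTree]
    #: tumor_id -> marker -> 'truncal' | 'branch'
    labels: dict[str, dict[str, str]]
    #: tumor_id -> (focus_id, marker) -> True if truly lost
    true_loss: dict[str, dict[tuple[str, str], bool]]
    config: SimConfig

    def newick(self, tumor_id: str) -> str:
        return to_newick(self.trees[tumor_id])


def _ordered(markers_set: frozenset[str], registry: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(sorted(markers_set, key=registry.index))


def _plant_tumor(
    rng: np.random.Generator,
    tumor_id: str,
    stage: int,
    foci: list[str],
    cfg: SimConfig,
) -> tuple[ClonalTree, dict[str, str], dict[tuple[str, str], bool]]:
    """Sample one tumor's clone tree and per-focus truth."""
    all_foci = frozenset(foci)
    # Deterministic candidate order: by first-marker registry position,
    # bundles (larger events) before singletons at ties.
    candidates = sorted(
        cfg.event_probs,
        key=lambda ev: (min(cfg.markers.index(m) for m in ev), -len(ev)),
    )
    used_markers: set[str] = set()
    truncal_sets: list[frozenset[str]] = []
    branch_sets: list[frozenset[str]] = []
    for ev in candidates:
        mult = cfg.stage_multipliers.get(ev, (1.0,) * cfg.n_stages)[stage - 1]
        p = min(cfg.event_probs[ev] * mult, 0.99)
        occurs = rng.random() < p
        if not occurs or (set(ev) & used_markers):
            # draw consumed either way to keep the stream aligned
            continue
        used_markers |= set(ev)
        if rng.random() < cfg.p_truncal:
            truncal_sets.append(ev)
        else:
            branch_sets.append(ev)

    events: list[LossEvent] = []
    # All truncal markers collapse into one trunk event: separate events
    # with identical all-foci support are indistinguishable from a binary
    # loss matrix, so the model plants them as a single clone.
    trunk: Optional[TreeNode] = None
    root = TreeNode(event=None, support=all_foci)
    if truncal_sets:
        trunk_markers = frozenset().union(*truncal_sets)
        ev = LossEvent(_ordered(trunk_markers, cfg.markers), all_foci)
        events.append(ev)
        trunk = TreeNode(event=ev, support=all_foci)
        root.children.append(trunk)

    branch_nodes: list[TreeNode] = []
    max_size = max(
        1, min(max(cfg.branch_support_sizes), math.ceil(0.75 * len(foci)) - 1)
    )
    sizes = [s for s in cfg.branch_support_sizes if s <= max_size] or [1]
    for ev_set in branch_sets:
        parent = trunk if trunk is not None else root
        if branch_nodes and rng.random() < cfg.p_nest:
            parent = branch_nodes[int(rng.integers(len(branch_nodes)))]
        taken = frozenset().union(*(c.support for c in parent.children)) if parent.children else frozenset()
        available = sorted(parent.support - taken)
        feasible = [
            s for s in sizes if s <= len(available) and s < len(parent.support)
        ]
        if not feasible:
            continue  # no room under this clone; event does not occur
        size = int(rng.choice(feasible))
        support = frozenset(rng.choice(available, size=size, replace=False).tolist())
        ev = LossEvent(_ordered(ev_set, cfg.markers), support)
        events.append(ev)
        node = TreeNode(event=ev, support=support)
        parent.children.append(node)
        branch_nodes.append(node)

    tree = build_tree(events, all_foci, tumor_id=tumor_id, markers=cfg.markers)
    labels: dict[str, str] = {}
    for ev in events:
        lab = "truncal" if ev.support == all_foci else "branch"
        for m in ev.markers:
            labels[m] = lab
    true_loss: dict[tuple[str, str], bool] = {}
    support_of = {m: ev.support for ev in events for m in ev.markers}
    for f in foci:
        for m in cfg.markers:
            true_loss[(f, m)] = f in support_of.get(m, frozenset())
    return tree, labels, true_loss


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a full cohort and its planted ground truth.

    Fully reproducible: identical config (including seed) gives a
    byte-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tumors: list[TumorGrid] = []
    trees: dict[str, ClonalTree] = {}
    labels: dict[str, dict[str, str]] = {}
    truth_loss: dict[str, dict[tuple[str, str], bool]] = {}
    for stage in range(1, config.n_stages + 1):
        for i in range(config.n_per_stage):
            tumor_id = f"S{stage_to_roman(stage) if stage <= 4 else stage}-{i + 1:03d}"
            n_foci = config.n_foci
            if config.two_focus_tumor and stage == 1 and i == 0:
                n_foci = 2
            foci = [f"F{j + 1}" for j in range(n_foci)]
            tree, labs, tl = _plant_tumor(rng, tumor_id, min(stage, 4), foci, config)
            grid: dict[tuple[str, str], Optional[int]] = {}
            for f in foci:
                for m in config.markers:
                    if rng.random() < config.missing_rate:
                        grid[(f, m)] = None
                        continue
                    if tl[(f, m)]:
                        grid[(f, m)] = 0
                    else:
                        grid[(f, m)] = 1 if rng.random() < config.score_noise else 2
            tumors.append(
                TumorGrid(tumor_id=tumor_id, stage=min(stage, 4), foci=foci, grid=grid)
            )
            trees[tumor_id] = tree
            labels[tumor_id] = labs
            truth_loss[tumor_id] = tl
    cohort = Cohort(
        tumors=tumors,
        markers=config.markers,
        provenance=f"synthetic cohort, seed={config.seed}",
    )
    return cohort, GroundTruth(trees=trees, labels=labels, true_loss=truth_loss, config=config)


def _canonical(node: TreeNode) -> tuple:
    """Order-free canonical form of a subtree for isomorphism checks."""
    kids = tuple(sorted(_canonical(c) for c in node.children))
    markers = tuple(node.event.markers) if node.event else ("WT",)
    return (markers, tuple(sorted(node.support)), kids)


def recovery_report(
    cohort: Cohort,
    truth: GroundTruth,
    tau: float = 0.75,
    policy: str = "split",
) -> pd.DataFrame:
    """Compare pipeline output against planted truth, per tumor.

    Columns: ``topology_match`` (label-preserving isomorphism of the
    recovered vs planted tree), ``label_accuracy`` (truncal/branch
    agreement over planted lost markers), ``support_jaccard`` (mean
    Jaccard between planted and recovered support per lost marker) and
    ``n_unobservable`` (planted events with no evaluable lost cell —
    sampling misses, not errors).
    """
    truth_ids = set(truth.trees)
    cohort_ids = {t.tumor_id for t in cohort}
    if truth_ids != cohort_ids:
        raise ValueError("cohort and ground truth carry different tumor ids")
    rows = []
    for t in cohort:
        planted = truth.trees[t.tumor_id]
        recovered, _ = tumor_tree(t, cohort.markers, policy=policy)
        topo = _canonical(recovered.root) == _canonical(planted.root)
        rec_labels_df = classify_events(recovered, tau=tau)
        rec_labels: dict[str, str] = {}
        rec_support: dict[str, set[str]] = {}
        for _, r in rec_labels_df.iterrows():
            for m in r["markers"]:
                rec_labels[m] = r["label"]
                rec_support.setdefault(m, set()).update(r["support"])
        planted_labels = truth.labels[t.tumor_id]
        n_unobservable = 0
        agree = []
        jaccards = []
        for ev in planted.events():
            for m in ev.markers:
                if m not in rec_support:
                    n_unobservable += 1
                    continue
                agree.append(rec_labels[m] == planted_labels[m])
                inter = len(rec_support[m] & set(ev.support))
                union = len(rec_support[m] | set(ev.support))
                jaccards.append(inter / union if union else 1.0)
        rows.append(
            {
                "tumor_id": t.tumor_id,
                "topology_match": bool(topo),
                "label_accuracy": float(np.mean(agree)) if agree else math.nan,
                "support_jaccard": float(np.mean(jaccards)) if jaccards else math.nan,
                "n_planted_events": len(planted.events()),
                "n_unobservable": n_unobservable,
            }
        )
    return pd.DataFrame(rows)


def independent_loss_cohort(
    n_tumors: int,
    loss_prob: float,
    markers: tuple[str, ...] = ("M1", "M2"),
    n_foci: int = 4,
    seed: int = 0,
) -> Cohort:
    """Null-model cohort: every (focus, marker) cell lost independently.

    Used to check Fisher-test calibration — no co-loss structure, no
    planted trees.
    """
    rng = np.random.default_rng(seed)
    # per-focus rate giving the requested tumor-level loss probability
    per_focus = 1.0 - (1.0 - loss_prob) ** (1.0 / n_foci)
    tumors = []
    for i in range(n_tumors):
        foci = [f"F{j + 1}" for j in range(n_foci)]
        grid = {
            (f, m): 0 if rng.random() < per_focus else 2
            for f in foci
            for m in markers
        }
        tumors.append(TumorGrid(tumor_id=f"T{i + 1:04d}", stage=1, foci=foci, grid=grid))
    return Cohort(tumors=tumors, markers=markers, provenance="independent-loss null")
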