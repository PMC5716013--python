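"""Minimum-event intron histories on a rooted phylogeny.

Two reconstruction models for one binary presence/absence character
(an ancestral intron slot) whose leaves may also be Not-Determined:

* Dollo, loss-only: the intron is present at the root and can only be lost.
  The minimum number of losses equals the number of maximal subtrees that
  contain at least one Absent leaf and no Present leaf (ND leaves are free
  and join whichever side is cheaper).  Events are placed on the shallowest
  branches achieving that minimum.

* Sankoff, weighted loss+gain: a dynamic program over states {Present,
  Absent} with per-change costs; ND leaves have a zero cost for both states.
  Ties are broken in favour of Present at a node, which also pushes events
  as deep (close to the leaves) as the optimum allows.

Leaves are genes; within-species duplicates are expected to hang as a
cherry/polytomy at the species tip so a shared loss is counted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .io_formats import ABSENT, NOT_DETERMINED, PRESENT, RootedTree, TreeNode

LOSS = "loss"
GAIN = "gain"

_STATE_IDX = {PRESENT: 0, ABSENT: 1}


@dataclass
class EventReconstruction:
    """One slot's optimal event history under a named parsimony model."""

    slot: str
    model: str
    events: list[tuple[str, str]]  # (branch = child-node label, loss|gain)
    ancestral_states: dict[str, str]  # node label -> P|A
    cost_loss: float = 1.0
    cost_gain: float = 1.0

    @property
    def n_losses(self) -> int:
        return sum(1 for _, kind in self.events if kind == LOSS)

    @property
    def n_gains(self) -> int:
        return sum(1 for _, kind in self.events if kind == GAIN)

    @property
    def total_cost(self) -> float:
        return self.n_losses * self.cost_loss + self.n_gains * self.cost_gain


@dataclass
class ModelComparison:
    slot: str
    dollo_events: int
    mixed_min_events: int
    dollo: EventReconstruction = field(repr=False, default=None)
    mixed: EventReconstruction = field(repr=False, default=None)

    @property
    def verdict(self) -> str:
        if self.dollo_events < self.mixed_min_events:
            return "loss_only_preferred"
        if self.dollo_events == self.mixed_min_events:
            return "tie"
        return "mixed_preferred"


def _check_states(states: dict[str, str], tree: RootedTree) -> None:
    leaves = set(tree.leaf_labels())
    missing = leaves - states.keys()
    if missing:
        raise ValidationError(f"no state for leaves: {sorted(missing)[:5]} ...")
    bad = {l: s for l, s in states.items() if l in leaves and s not in (PRESENT, ABSENT, NOT_DETERMINED)}
    if bad:
        raise ValidationError(f"invalid states: {bad}")


def dollo_count(states: dict[str, str], tree: RootedTree, slot: str = "") -> EventReconstruction:
    """Minimum loss-only history with the root fixed to Present.

    Computed by post-order aggregation: a loss is charged on every branch
    whose subtree holds at least one Absent leaf and no Present leaf, while
    its parent still does (or is the root).
    """
    _check_states(states, tree)
    has_p: dict[int, bool] = {}
    has_a: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = states[node.label]
            has_p[id(node)] = s == PRESENT
            has_a[id(node)] = s == ABSENT
        else:
            has_p[id(node)] = any(has_p[id(c)] for c in node.children)
            has_a[id(node)] = any(has_a[id(c)] for c in node.children)

    events: list[tuple[str, str]] = []
    anc: dict[str, str] = {}

    def walk(node: TreeNode, present: bool) -> None:
        if present and has_a[id(node)] and not has_p[id(node)] and node is not tree.root:
            events.append((node.label, LOSS))
            present = False
        anc[node.label] = PRESENT if present else ABSENT
        for child in node.children:
            walk(child, present)

    # Root is fixed Present (the ancestral gene carried the intron).
    walk(tree.root, True)
    events.sort(key=lambda e: e[0])
    return EventReconstruction(
        slot=str(slot), model="dollo", events=events, ancestral_states=anc
    )


def sankoff_min(
    states: dict[str, str],
    tree: RootedTree,
    cost_loss: float = 1.0,
    cost_gain: float = 1.0,
    root_state: str = PRESENT,
    slot: str = "",
) -> EventReconstruction:
    """Sankoff dynamic program over {Present, Absent} with weighted changes.

    ``root_state`` is 'P', 'A' or 'free'.  Returns one optimal labeling;
    ties prefer Present at each node (events pushed leafward).
    """
    if cost_loss <= 0 or cost_gain <= 0:
        raise ValidationError("costs must be positive")
    _check_states(states, tree)
    INF = math.inf
    # trans[s][t]: cost of a parent in state s having a child in state t
    trans = ((0.0, cost_loss), (cost_gain, 0.0))
    cost: dict[int, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = states[node.label]
            if s == PRESENT:
                cost[id(node)] = (0.0, INF)
            elif s == ABSENT:
                cost[id(node)] = (INF, 0.0)
            else:  # ND constrains nothing
                cost[id(node)] = (0.0, 0.0)
        else:
            totals = []
            for s in (0, 1):
                tot = 0.0
                for c in node.children:
                    tot += min(trans[s][t] + cost[id(c)][t] for t in (0, 1))
                totals.append(tot)
            cost[id(node)] = tuple(totals)

    root_cost = cost[id(tree.root)]
    if root_state == "free":
        root_assign = 0 if root_cost[0] <= root_cost[1] else 1
    else:
        root_assign = _STATE_IDX[root_state]
        if root_cost[root_assign] == INF:
            raise ValidationError("root state incompatible with leaf states")

    events: list[tuple[str, str]] = []
    anc: dict[str, str] = {}

    def assign(node: TreeNode, s: int) -> None:
        anc[node.label] = PRESENT if s == 0 else ABSENT
        for c in node.children:
            best = min(trans[s][t] + cost[id(c)][t] for t in (0, 1))
            # tie-break: prefer keeping Present
            t = 0 if trans[s][0] + cost[id(c)][0] == best else 1
            if t != s:
                events.append((c.label, LOSS if t == 1 else GAIN))
            assign(c, t)

    assign(tree.root, root_assign)
    events.sort(key=lambda e: e[0])
    return EventReconstruction(
        slot=str(slot),
        model=f"sankoff(loss={cost_loss:g},gain={cost_gain:g})",
        events=events,
        ancestral_states=anc,
        cost_loss=cost_loss,
        cost_gain=cost_gain,
    )


def compare_models(
    states: dict[str, str], tree: RootedTree, slot: str = ""
) -> ModelComparison:
    """Loss-only versus mixed loss+gain minimum event counts (unit costs)."""
    dollo = dollo_count(states, tree, slot=slot)
    mixed = sankoff_min(states, tree, 1.0, 1.0, root_state=PRESENT, slot=slot)
    return ModelComparison(
        slot=str(slot),
        dollo_events=len(dollo.events),
        mixed_min_events=len(mixed.events),
        dollo=dollo,
        mixed=mixed,
    )


def replay(
    reconstruction: EventReconstruction, tree: RootedTree
) -> dict[str, str]:
    """Replay the event list from a Present root; returns leaf states.

    Used to assert that a reconstruction explains every non-ND leaf.
    """
    flips = {}
    for branch, kind in reconstruction.events:
        flips[branch] = ABSENT if kind == LOSS else PRESENT

    leaf_states: dict[str, str] = {}

    def walk(node: TreeNode, state: str) -> None:
        state = flips.get(node.label, state)
        if node.is_leaf:
            leaf_states[node.label] = state
        for c in node.children:
            walk(c, state)

    walk(tree.root, PRESENT)
    return leaf_states


def branch_report(
    reconstruction: EventReconstruction, tree: RootedTree
) -> pd.DataFrame:
    """One row per event with the sorted leaf set below the event branch."""
    rows = []
    for branch, kind in reconstruction.events:
        clade = sorted(tree.leaf_set(branch))
        rows.append(
            {
                "slot": reconstruction.slot,
                "model": reconstruction.model,
                "branch": branch,
                "type": kind,
                "n_leaves": len(clade),
                "clade": ",".join(clade),
            }
        )
    return pd.DataFrame(rows, columns=["slot", "model", "branch", "type", "n_leaves", "clade"])


def annotate_newick(tree: RootedTree, reconstructions: list[EventReconstruction]) -> str:
    """Newick string with event labels appended to branch (child) labels."""
    tags: dict[str, list[str]] = {}
    for rec in reconstructions:
        for branch, kind in rec.events:
            tags.setdefault(branch, []).append(f"{'-' if kind == LOSS else '+'}{rec.slot}")

    def fmt(node: TreeNode) -> str:
        label = node.label or ""
        if label.startswith("node"):
            label = ""
        if node.label in tags:
            label = f"{label}[{''.join(tags[node.label])}]"
        if node.is_leaf:
            return label
        return "(" + ",".join(fmt(c) for c in node.children) + ")" + label

    return fmt(tree.root) + ";"
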