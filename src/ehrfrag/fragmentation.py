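"""Pathway tracing and the Display Fragmentation Index (DFI).

The DFI scores the navigation burden of assembling task-relevant information
scattered across an interface:

    DFI = E + IS * X_IS + C * X_C + SS * X_SS + ML

where, over a measured pathway through all target elements,

* ``E``  counts the target elements themselves (no multiplier — accessing an
  element costs the same wherever it lives),
* ``IS`` counts intermediate screen transitions,
* ``C``  counts clicks (every screen transition is also one click; selecting
  a data element on a screen is a click without a transition),
* ``SS`` counts scroll actions (a scrolling screen costs 2 per entry, an
  average over the variability of such screens),
* ``ML`` accumulates the menu length at every decision point, reflecting
  the visual-search and choice cost of long menus,
* ``X``  is a per-action multiplier; by default the weight of an action is
  the hierarchy level at which it occurs (deeper levels cost more), with a
  constant-weight mode available.

The measured pathway is a reasonable maximum: by default it returns to the
root between targets ("the longest reasonable pathway"); a ``shortest``
policy instead ascends only to the lowest common ancestor, for tasks where
one need not go up all levels.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .errors import (
    EmptyTargetsError,
    MissingNodeError,
    PathwayInconsistencyError,
)
from .nav_model import NavTree

# step actions
VISIT_SCREEN_TRANSITION = "visit_screen_transition"
CLICK_SAME_LEVEL = "click_same_level"
SCROLL = "scroll"
REACH_ELEMENT = "reach_element"

ACTIONS = (VISIT_SCREEN_TRANSITION, CLICK_SAME_LEVEL, SCROLL, REACH_ELEMENT)

RoutingPolicy = Literal["reasonable_maximum", "shortest"]


@dataclass(frozen=True)
class Step:
    node_id: str
    action: str


@dataclass
class Pathway:
    """An ordered traversal through target elements, starting at the root."""

    start_id: str
    steps: list[Step] = field(default_factory=list)
    target_order: list[str] = field(default_factory=list)

    def node_ids(self) -> list[str]:
        """Distinct nodes touched by the pathway (start first, then step order)."""
        seen: dict[str, None] = {}
        if self.steps:
            seen[self.start_id] = None
        for s in self.steps:
            seen.setdefault(s.node_id, None)
        return list(seen)


@dataclass
class ActionTally:
    """Per-level action counts extracted from a pathway."""

    E: int = 0
    IS_by_level: dict[int, int] = field(default_factory=dict)
    C_by_level: dict[int, int] = field(default_factory=dict)
    SS_by_level: dict[int, int] = field(default_factory=dict)
    ML: int = 0

    @property
    def IS(self) -> int:
        return sum(self.IS_by_level.values())

    @property
    def C(self) -> int:
        return sum(self.C_by_level.values())

    @property
    def SS(self) -> int:
        return sum(self.SS_by_level.values())

    def scaled(self, k: int) -> "ActionTally":
        return ActionTally(
            E=self.E * k,
            IS_by_level={l: c * k for l, c in self.IS_by_level.items()},
            C_by_level={l: c * k for l, c in self.C_by_level.items()},
            SS_by_level={l: c * k for l, c in self.SS_by_level.items()},
            ML=self.ML * k,
        )


@dataclass(frozen=True)
class MultiplierPolicy:
    """Level weighting applied to IS, C and SS counts.

    ``depth_weighted`` (default) weights an action at level l by l, so work
    deep in the hierarchy counts more; ``constant`` applies a flat
    ``constant_value`` to every action.
    """

    mode: Literal["depth_weighted", "constant"] = "depth_weighted"
    constant_value: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("depth_weighted", "constant"):
            raise ValueError(f"unknown multiplier mode {self.mode!r}")
        if self.constant_value <= 0:
            raise ValueError("constant_value must be positive")

    def weight(self, level: int) -> float:
        return float(level) if self.mode == "depth_weighted" else self.constant_value


@dataclass(frozen=True)
class DFIBreakdown:
    """The five DFI terms and their exact sum."""

    E_term: float
    IS_term: float
    C_term: float
    SS_term: float
    ML_term: float

    @property
    def total(self) -> float:
        return self.E_term + self.IS_term + self.C_term + self.SS_term + self.ML_term

    def summary_line(self) -> str:
        def fmt(x: float) -> str:
            return f"{int(x)}" if float(x).is_integer() else f"{x:g}"

        parts = [self.E_term, self.IS_term, self.C_term, self.SS_term, self.ML_term]
        return "DFI = " + " + ".join(fmt(p) for p in parts) + f" = {fmt(self.total)}"

    def to_dict(self) -> dict:
        return {
            "E_term": self.E_term,
            "IS_term": self.IS_term,
            "C_term": self.C_term,
            "SS_term": self.SS_term,
            "ML_term": self.ML_term,
            "total": self.total,
        }


@dataclass(frozen=True)
class SystemComparison:
    """Per-term deltas (b - a) and the ratio of totals b/a."""

    delta_E: float
    delta_IS: float
    delta_C: float
    delta_SS: float
    delta_ML: float
    delta_total: float
    ratio: float | None

    def to_dict(self) -> dict:
        return {
            "delta_E": self.delta_E,
            "delta_IS": self.delta_IS,
            "delta_C": self.delta_C,
            "delta_SS": self.delta_SS,
            "delta_ML": self.delta_ML,
            "delta_total": self.delta_total,
            "ratio": self.ratio,
        }


# ---------------------------------------------------------------------------
# pathway tracing
# ---------------------------------------------------------------------------


def _lca(tree: NavTree, a: str, b: str) -> str:
    anc_a = tree.ancestors(a)
    anc_b = set(tree.ancestors(b))
    for node_id in anc_a:
        if node_id in anc_b:
            return node_id
    raise PathwayInconsistencyError(f"no common ancestor of {a!r} and {b!r}")


def trace_pathway(
    tree: NavTree,
    targets: Iterable[str],
    routing: RoutingPolicy = "reasonable_maximum",
    ordered: bool = False,
) -> Pathway:
    """Trace the measured navigation pathway through all target nodes.

    Targets are visited in tree document order unless ``ordered`` is true, in
    which case the given sequence is honored.  Between consecutive targets
    the route ascends to the root (``reasonable_maximum``, the default) or
    only to the lowest common ancestor (``shortest``), then descends.

    Step emission rules:

    * entering a screen or menu item (either direction) emits one
      ``visit_screen_transition``;
    * selecting a data-element target on its parent screen emits one
      ``click_same_level`` (no screen changes);
    * arriving at a target additionally emits ``reach_element``;
    * every entry of a node flagged ``is_scrolling_screen`` emits two
      ``scroll`` steps (the average cost of a scrolling screen);
    * leaving a data element back to its parent screen emits nothing — the
      element sits on that screen.
    """
    if routing not in ("reasonable_maximum", "shortest"):
        raise ValueError(f"unknown routing policy {routing!r}")
    target_list = list(targets)
    if not target_list:
        raise EmptyTargetsError("no targets given")
    for t in target_list:
        tree.node(t)  # raises MissingNodeError
    if len(set(target_list)) != len(target_list):
        raise ValueError("duplicate target ids")
    if not ordered:
        order = tree.document_order()
        target_list.sort(key=order.__getitem__)

    steps: list[Step] = []

    def emit_scrolls(node_id: str) -> None:
        if tree.node(node_id).is_scrolling_screen:
            steps.append(Step(node_id, SCROLL))
            steps.append(Step(node_id, SCROLL))

    def enter(node_id: str, is_target: bool) -> None:
        node = tree.node(node_id)
        if is_target and node.kind == "data_element":
            steps.append(Step(node_id, CLICK_SAME_LEVEL))
        else:
            steps.append(Step(node_id, VISIT_SCREEN_TRANSITION))
        emit_scrolls(node_id)
        if is_target:
            steps.append(Step(node_id, REACH_ELEMENT))

    position = tree.root_id
    emit_scrolls(position)  # the top screen may itself need scrolling

    for t in target_list:
        anchor = tree.root_id if routing == "reasonable_maximum" else _lca(tree, position, t)
        # ascend: position -> anchor
        node_id = position
        while node_id != anchor:
            node = tree.node(node_id)
            parent_id = node.parent_id
            assert parent_id is not None
            if node.kind != "data_element":
                # re-entering the parent screen is a transition
                steps.append(Step(parent_id, VISIT_SCREEN_TRANSITION))
                emit_scrolls(parent_id)
            node_id = parent_id
        position = anchor
        if t == position:
            steps.append(Step(t, REACH_ELEMENT))
            continue
        # descend: anchor -> t (exclusive of anchor)
        down = list(reversed(tree.ancestors(t)))
        down = down[down.index(anchor) + 1 :]
        for v in down:
            enter(v, is_target=(v == t))
        position = t

    return Pathway(start_id=tree.root_id, steps=steps, target_order=target_list)


# ---------------------------------------------------------------------------
# tallying and the index
# ---------------------------------------------------------------------------


def tally_actions(pathway: Pathway, tree: NavTree) -> ActionTally:
    """Bucket pathway steps by the depth of the node acted on.

    Each ``visit_screen_transition`` counts one intermediate-screen
    transition *and* one click at the entered node's level; each
    ``click_same_level`` counts one click; each ``scroll`` one scroll
    action; each ``reach_element`` one element.  ML accumulates the menu
    length of the node a descent departs from, once per traversal of the
    decision point.
    """
    tally = ActionTally(
        IS_by_level=defaultdict(int),
        C_by_level=defaultdict(int),
        SS_by_level=defaultdict(int),
    )
    if pathway.steps and pathway.start_id not in tree.nodes:
        raise PathwayInconsistencyError(f"start node {pathway.start_id!r} not in tree")
    position = pathway.start_id
    for step in pathway.steps:
        if step.node_id not in tree.nodes:
            raise PathwayInconsistencyError(f"step node {step.node_id!r} not in tree")
        node = tree.node(step.node_id)
        level = node.depth
        if step.action == REACH_ELEMENT:
            tally.E += 1
            # a data element sits on its parent's screen: after viewing it,
            # the user is (still) positioned on that screen
            if node.kind == "data_element" and node.parent_id is not None:
                position = node.parent_id
            continue
        if step.action == SCROLL:
            tally.SS_by_level[level] += 1
            continue
        descent = node.parent_id == position
        if step.action == VISIT_SCREEN_TRANSITION:
            tally.IS_by_level[level] += 1
            tally.C_by_level[level] += 1
        elif step.action == CLICK_SAME_LEVEL:
            tally.C_by_level[level] += 1
        else:
            raise PathwayInconsistencyError(f"unknown action {step.action!r}")
        if descent:
            tally.ML += tree.menu_length(position)
        position = step.node_id
    tally.IS_by_level = dict(tally.IS_by_level)
    tally.C_by_level = dict(tally.C_by_level)
    tally.SS_by_level = dict(tally.SS_by_level)
    if len(pathway.target_order) and tally.E != len(pathway.target_order):
        raise PathwayInconsistencyError(
            f"E={tally.E} != number of targets {len(pathway.target_order)}"
        )
    return tally


def compute_dfi(
    tally: ActionTally, policy: MultiplierPolicy = MultiplierPolicy()
) -> DFIBreakdown:
    """Apply the multiplier policy to a tally and sum the DFI terms."""

    def weighted(by_level: dict[int, int]) -> float:
        return float(sum(policy.weight(l) * c for l, c in by_level.items()))

    return DFIBreakdown(
        E_term=float(tally.E),
        IS_term=weighted(tally.IS_by_level),
        C_term=weighted(tally.C_by_level),
        SS_term=weighted(tally.SS_by_level),
        ML_term=float(tally.ML),
    )


def dfi_for_tree(
    tree: NavTree,
    targets: Iterable[str] | None = None,
    routing: RoutingPolicy = "reasonable_maximum",
    policy: MultiplierPolicy = MultiplierPolicy(),
) -> DFIBreakdown:
    """Convenience: trace, tally and score in one call.

    When ``targets`` is None, the tree's flagged target nodes are used.
    """
    if targets is None:
        targets = [n.id for n in tree.iter_preorder() if n.is_target]
    pathway = trace_pathway(tree, targets, routing=routing)
    return compute_dfi(tally_actions(pathway, tree), policy)


def compare_systems(a: DFIBreakdown, b: DFIBreakdown) -> SystemComparison:
    """Compare two systems' breakdowns: per-term deltas (b - a) and b/a ratio."""
    ratio = (b.total / a.total) if (a.total > 0 and b.total > 0) else None
    return SystemComparison(
        delta_E=b.E_term - a.E_term,
        delta_IS=b.IS_term - a.IS_term,
        delta_C=b.C_term - a.C_term,
        delta_SS=b.SS_term - a.SS_term,
        delta_ML=b.ML_term - a.ML_term,
        delta_total=b.total - a.total,
        ratio=ratio,
    )
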