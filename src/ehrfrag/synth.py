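"""Synthetic navigation trees and task sessions with controllable fragmentation.

Stands in for walkthrough-derived navigation maps and screen-capture event
logs.  Trees are complete (fixed depth and branching) with target data
elements placed uniformly among the leaves and scroll flags drawn per
screen; sessions follow a Markov task-switching process — at every step the
task switches with probability ``p_switch`` to a uniformly random other
label — so switch probability is the fragmentation dial: higher ``p_switch``
splinters tasks into more, shorter instances, driving ACT and PPI down.

Each generator call draws from its own explicitly seeded stream; no global
random state is touched, so fixtures are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapacityError
from .nav_model import NavNode, NavTree, build_tree
from .session_model import Session, TaskSegment


@dataclass(frozen=True)
class TreeSpec:
    """Shape of a synthetic navigation tree.

    ``branching`` may be a single factor or a per-level list of length
    ``depth`` (children per node at each level).
    """

    depth: int = 3
    branching: int | tuple[int, ...] = 3
    n_targets: int = 4
    p_scroll: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if not 0 <= self.p_scroll <= 1:
            raise ValueError("p_scroll must be in [0, 1]")
        if self.n_targets < 1:
            raise ValueError("n_targets must be positive")

    def branching_at(self, level: int) -> int:
        if isinstance(self.branching, int):
            return self.branching
        return self.branching[level]

    @property
    def n_leaves(self) -> int:
        n = 1
        for level in range(self.depth):
            n *= self.branching_at(level)
        return n


@dataclass(frozen=True)
class SessionSpec:
    """Markov task-switching process behind a synthetic session."""

    task_labels: tuple[str, ...] = ("Notes", "Labs", "Meds", "Orders")
    total_steps: int = 40
    step_s: float = 5.0
    p_switch: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.task_labels:
            raise ValueError("need at least one task label")
        if not 0 <= self.p_switch <= 1:
            raise ValueError("p_switch must be in [0, 1]")
        if self.total_steps < 1:
            raise ValueError("total_steps must be positive")
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")


def generate_nav_tree(spec: TreeSpec) -> NavTree:
    """Complete tree of the given shape; leaves are data elements.

    ``n_targets`` leaves are flagged as targets uniformly at random; each
    internal screen is flagged scrolling with probability ``p_scroll``.
    Fully reproducible from ``spec.seed``.
    """
    if spec.n_targets > spec.n_leaves:
        raise CapacityError(
            f"{spec.n_targets} targets requested but only {spec.n_leaves} leaves"
        )
    rng = np.random.default_rng(spec.seed)
    nodes: list[NavNode] = []
    leaves: list[NavNode] = []
    counter = 0

    def make(label: str, kind: str, depth: int, parent_id: str | None) -> NavNode:
        nonlocal counter
        node = NavNode(
            id=f"n{counter}", label=label, kind=kind, depth=depth, parent_id=parent_id
        )
        counter += 1
        nodes.append(node)
        return node

    def grow(parent: NavNode, path: tuple[int, ...]) -> None:
        depth = len(path)
        if depth == spec.depth:
            leaves.append(parent)
            return
        for i in range(spec.branching_at(depth)):
            child_path = path + (i + 1,)
            dotted = ".".join(map(str, child_path))
            kind = "data_element" if depth + 1 == spec.depth else "screen"
            label = f"Item {dotted}" if kind == "data_element" else f"Screen {dotted}"
            child = make(label, kind, depth + 1, parent.id)
            parent.children.append(child.id)
            grow(child, child_path)

    root = make("Home", "screen", 0, None)
    grow(root, ())
    for node in nodes:
        if node.kind == "screen" and rng.random() < spec.p_scroll:
            node.is_scrolling_screen = True
    target_idx = rng.choice(len(leaves), size=spec.n_targets, replace=False)
    for i in sorted(target_idx):
        leaves[i].is_target = True
    return build_tree(nodes, root.id)


def generate_session(spec: SessionSpec, session_id: str | None = None) -> Session:
    """One synthetic session of abutting fixed-length task segments."""
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.task_labels)
    current = int(rng.integers(len(labels)))
    seq = [current]
    for _ in range(spec.total_steps - 1):
        if len(labels) > 1 and rng.random() < spec.p_switch:
            offset = int(rng.integers(1, len(labels)))
            current = (current + offset) % len(labels)
        seq.append(current)
    segments = [
        TaskSegment(
            task_label=labels[lab],
            start_s=i * spec.step_s,
            end_s=(i + 1) * spec.step_s,
        )
        for i, lab in enumerate(seq)
    ]
    sid = session_id if session_id is not None else f"synth-{spec.seed}"
    return Session(session_id=sid, segments=segments)


def generate_sessions(
    spec: SessionSpec, n_sessions: int, seed: int | None = None
) -> list[Session]:
    """A cohort of sessions with per-session seeds derived from one stream."""
    root_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(root_seed)
    out = []
    for i in range(n_sessions):
        sub = int(rng.integers(0, 2**31 - 1))
        sess_spec = SessionSpec(
            task_labels=spec.task_labels,
            total_steps=spec.total_steps,
            step_s=spec.step_s,
            p_switch=spec.p_switch,
            seed=sub,
        )
        out.append(generate_session(sess_spec, session_id=f"synth-{root_seed}-{i}"))
    return out
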