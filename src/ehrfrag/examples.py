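"""Worked-example inputs: two navigation trees and a demo session.

The source spreadsheets behind published sunburst analyses are not
distributed, so these are synthetic stand-ins constructed to exercise the
full measurement chain.  Both trees hang chains of nested target screens off
the root and are scored with the ``shortest`` (lowest-common-ancestor)
routing and the default depth-weighted multiplier, under which a chain of
length L contributes L(L+1)/2 (descent) plus L(L-1)/2 (ascent back to the
root, omitted for the final chain) to both the intermediate-screen and the
click term.

* the *dense* system (chain lengths 9, 5, 3, 2 and seventeen single
  sections) tallies E=36, IS term 136, C term 136, ML 39 -> DFI 347;
* the *lean* system (chain lengths 5, 3, 2 and nine single sections)
  tallies E=19, IS term 47, C term 47, ML 19 -> DFI 132,

about one-third of the dense system.  The numbers are not stored anywhere:
they fall out of trace/tally/compute at run time.
"""

from __future__ import annotations

from .fragmentation import (
    DFIBreakdown,
    MultiplierPolicy,
    SystemComparison,
    compare_systems,
    dfi_for_tree,
)
from .nav_model import NavNode, NavTree, build_tree
from .session_model import Session, TaskSegment

#: routing used by the worked examples (walkthroughs continue downward
#: through nested sections instead of returning to the root each time)
EXAMPLE_ROUTING = "shortest"


def _chain_tree(
    chain_lengths: list[int],
    root_label: str,
    overrides: dict[tuple[int, int], int] | None = None,
) -> NavTree:
    """Root with one chain of nested target screens per entry of chain_lengths.

    ``overrides`` maps (chain index, depth) to a menu_length_override.
    The root's menu length is overridden to 1: its sections are presented as
    a single always-visible rail, not a choice menu.
    """
    overrides = overrides or {}
    nodes: list[NavNode] = []
    counter = 0

    def make(label: str, depth: int, parent: NavNode | None) -> NavNode:
        nonlocal counter
        node = NavNode(
            id=f"n{counter}",
            label=label,
            kind="screen",
            depth=depth,
            parent_id=None if parent is None else parent.id,
            is_target=depth > 0,
        )
        counter += 1
        if parent is not None:
            parent.children.append(node.id)
        nodes.append(node)
        return node

    root = make(root_label, 0, None)
    root.is_target = False
    root.menu_length_override = 1
    for ci, length in enumerate(chain_lengths):
        parent = root
        for depth in range(1, length + 1):
            label = f"Section {ci + 1}" if depth == 1 else f"Section {ci + 1}.{depth}"
            node = make(label, depth, parent)
            if (ci, depth) in overrides:
                node.menu_length_override = overrides[(ci, depth)]
            parent = node
    return build_tree(nodes, root.id)


def dense_navigation_tree() -> NavTree:
    """Heavily fragmented navigation: 36 targets over deep nested chains."""
    chains = [9, 5, 3, 2] + [1] * 17
    # the first chain's top section displays a 4-item picker
    return _chain_tree(chains, "Main Screen", overrides={(0, 1): 4})


def lean_navigation_tree() -> NavTree:
    """Flatter navigation to the same kind of content: 19 targets."""
    chains = [5, 3, 2] + [1] * 9
    return _chain_tree(chains, "Main Screen")


def worked_example_breakdowns() -> tuple[DFIBreakdown, DFIBreakdown, SystemComparison]:
    """Score both example systems and compare them (lean vs dense)."""
    policy = MultiplierPolicy(mode="depth_weighted")
    dense = dfi_for_tree(dense_navigation_tree(), routing=EXAMPLE_ROUTING, policy=policy)
    lean = dfi_for_tree(lean_navigation_tree(), routing=EXAMPLE_ROUTING, policy=policy)
    return dense, lean, compare_systems(dense, lean)


def pogo_example_session() -> Session:
    """A session whose 140-200 s window alternates two elements 3 times each.

    Classic pogo-sticking: the user checks lab values against a note
    repeatedly; juxtaposing the two elements would remove the back-and-forth.
    """
    segments = [
        TaskSegment("Chart Review", 0, 140, screen_id="summary"),
        TaskSegment("Progress Note", 140, 150, screen_id="note"),
        TaskSegment("Lab Values", 150, 160, screen_id="labs"),
        TaskSegment("Progress Note", 160, 170, screen_id="note"),
        TaskSegment("Lab Values", 170, 180, screen_id="labs"),
        TaskSegment("Progress Note", 180, 190, screen_id="note"),
        TaskSegment("Lab Values", 190, 200, screen_id="labs"),
        TaskSegment("Orders", 200, 230, screen_id="orders"),
    ]
    return Session(session_id="demo", segments=segments)
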