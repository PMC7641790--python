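import pytest

from ehrfrag.nav_model import NavNode, NavTree, build_tree
from ehrfrag.session_model import Session, TaskSegment


def make_chain(depth: int, leaf_kind: str = "data_element",
               scrolling: set[int] = frozenset()) -> NavTree:
    """Single-branch tree root -> s1 -> ... -> s_depth (leaf may be an element)."""
    nodes = [NavNode(id="n0", label="root", kind="screen", depth=0)]
    for i in range(1, depth + 1):
        kind = leaf_kind if i == depth else "screen"
        node = NavNode(
            id=f"n{i}", label=f"s{i}", kind=kind, depth=i, parent_id=f"n{i-1}",
            is_target=(i == depth and kind in ("data_element", "screen")),
            is_scrolling_screen=(i in scrolling and kind == "screen"),
        )
        nodes[-1].children.append(node.id)
        nodes.append(node)
    return build_tree(nodes, "n0")


def make_session(triples, session_id="s1"):
    """Build a Session from (label, start, end) or (label, start, end, screen)."""
    segs = []
    for t in triples:
        label, start, end = t[:3]
        screen = t[3] if len(t) > 3 else None
        segs.append(TaskSegment(label, start, end, screen_id=screen))
    return Session(session_id=session_id, segments=segs)


@pytest.fixture
def chain11():
    """The 11-node single-branch tree: 9 screens between root and the element."""
    return make_chain(10)


@pytest.fixture
def binary_tree():
    """Depth-3 complete binary tree with elements at the leaves."""
    from ehrfrag.synth import TreeSpec, generate_nav_tree

    return generate_nav_tree(TreeSpec(depth=3, branching=2, n_targets=2, seed=7))
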