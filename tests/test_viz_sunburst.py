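"""Sunburst geometry and SVG rendering."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_chain

from ehrfrag.errors import PathwayInconsistencyError
from ehrfrag.fragmentation import Pathway, trace_pathway
from ehrfrag.synth import TreeSpec, generate_nav_tree
from ehrfrag.viz_sunburst import (
    CENTER_DISC,
    highlight_pathway,
    layout_sunburst,
    render_sunburst,
)


def by_id(segments):
    return {s.node_id: s for s in segments}


class TestLayout:
    def test_two_children_equal_split(self):
        tree = generate_nav_tree(TreeSpec(depth=1, branching=2, n_targets=1, seed=0))
        segs = by_id(layout_sunburst(tree, weighting="equal_split"))
        kids = tree.root.children
        assert segs[kids[0]].extent_deg == 180
        assert segs[kids[1]].extent_deg == 180

    def test_leaf_weighted_proportions(self):
        """Children with 1 and 3 leaf descendants get 90 and 270 degrees."""
        from ehrfrag.nav_model import NavNode, build_tree

        nodes = [
            NavNode(id="r", label="r", depth=0, children=["a", "b"]),
            NavNode(id="a", label="a", depth=1, parent_id="r", children=["a1"]),
            NavNode(id="a1", label="a1", depth=2, parent_id="a", kind="data_element"),
            NavNode(id="b", label="b", depth=1, parent_id="r",
                    children=["b1", "b2", "b3"]),
            NavNode(id="b1", label="b1", depth=2, parent_id="b", kind="data_element"),
            NavNode(id="b2", label="b2", depth=2, parent_id="b", kind="data_element"),
            NavNode(id="b3", label="b3", depth=2, parent_id="b", kind="data_element"),
        ]
        tree = build_tree(nodes, "r")
        segs = by_id(layout_sunburst(tree, weighting="leaf_weighted"))
        assert segs["a"].extent_deg == 90
        assert segs["b"].extent_deg == 270

    def test_chain_spans_full_circle(self):
        tree = make_chain(5)
        for seg in layout_sunburst(tree):
            assert seg.extent_deg == 360

    def test_ring_is_depth_minus_one(self):
        tree = generate_nav_tree(TreeSpec(depth=3, branching=2, n_targets=1, seed=1))
        for seg in layout_sunburst(tree):
            assert seg.ring == tree.node(seg.node_id).depth - 1
        root_seg = by_id(layout_sunburst(tree))[tree.root_id]
        assert root_seg.ring == CENTER_DISC

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        seed=st.integers(0, 5000),
        weighting=st.sampled_from(["equal_split", "leaf_weighted"]),
    )
    def test_angle_conservation_exact(self, seed, weighting):
        """Children's extents sum exactly to the parent's extent (rationals)."""
        tree = generate_nav_tree(TreeSpec(depth=3, branching=3, n_targets=2, seed=seed))
        segs = by_id(layout_sunburst(tree, weighting=weighting))
        for node in tree.iter_preorder():
            if not node.children:
                continue
            parent_extent = segs[node.id].extent_deg
            child_sum = sum(
                (segs[c].extent_deg for c in node.children), Fraction(0)
            )
            assert child_sum == parent_extent
            # siblings are ordered and disjoint
            kids = [segs[c] for c in node.children]
            for a, b in zip(kids, kids[1:]):
                assert a.end_angle_deg == b.start_angle_deg


class TestHighlight:
    def test_empty_pathway_is_identity(self, chain11):
        segs = layout_sunburst(chain11)
        out = highlight_pathway(segs, Pathway(start_id="n0"))
        assert out == segs

    def test_chain_pathway_highlights_all_eleven(self, chain11):
        segs = layout_sunburst(chain11)
        pw = trace_pathway(chain11, ["n10"])
        out = highlight_pathway(segs, pw)
        assert sum(1 for s in out if s.fill_class == "highlight") == 11

    def test_two_calls_highlight_union(self, binary_tree):
        targets = [n.id for n in binary_tree.iter_preorder() if n.is_target]
        segs = layout_sunburst(binary_tree)
        one = highlight_pathway(segs, trace_pathway(binary_tree, targets[:1]))
        both = highlight_pathway(one, trace_pathway(binary_tree, targets[1:]))
        expected = set(trace_pathway(binary_tree, targets[:1]).node_ids()) | set(
            trace_pathway(binary_tree, targets[1:]).node_ids()
        )
        assert {s.node_id for s in both if s.fill_class == "highlight"} == expected

    def test_pathway_node_without_segment(self, chain11):
        segs = [s for s in layout_sunburst(chain11) if s.node_id != "n5"]
        with pytest.raises(PathwayInconsistencyError):
            highlight_pathway(segs, trace_pathway(chain11, ["n10"]))


class TestRender:
    def test_sector_count_and_center_disc(self):
        tree = generate_nav_tree(TreeSpec(depth=1, branching=3, n_targets=1, seed=0))
        svg = render_sunburst(layout_sunburst(tree))
        assert svg.count("<path ") == 3
        assert svg.count("<circle ") == 1

    def test_byte_identical_rendering(self, binary_tree):
        segs = layout_sunburst(binary_tree)
        assert render_sunburst(segs) == render_sunburst(segs)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 5000))
    def test_sector_count_equals_tree_size_minus_one(self, seed):
        tree = generate_nav_tree(TreeSpec(depth=2, branching=3, n_targets=1, seed=seed))
        svg = render_sunburst(layout_sunburst(tree))
        assert svg.count("<path ") == len(tree) - 1
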