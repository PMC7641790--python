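"""Pathway tracing, action tallying and the Display Fragmentation Index."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_chain
from oracles import nx_action_counts

from ehrfrag.errors import EmptyTargetsError, MissingNodeError
from ehrfrag.fragmentation import (
    CLICK_SAME_LEVEL,
    REACH_ELEMENT,
    SCROLL,
    VISIT_SCREEN_TRANSITION,
    ActionTally,
    MultiplierPolicy,
    Pathway,
    Step,
    compare_systems,
    compute_dfi,
    dfi_for_tree,
    tally_actions,
    trace_pathway,
)
from ehrfrag.nav_model import NavNode, build_tree
from ehrfrag.synth import TreeSpec, generate_nav_tree


def actions(pathway):
    out = {}
    for s in pathway.steps:
        out[s.action] = out.get(s.action, 0) + 1
    return out


class TestTracePathway:
    def test_chain_to_deep_element(self, chain11):
        """Nine screens stand between the top screen and the element."""
        pw = trace_pathway(chain11, ["n10"])
        got = actions(pw)
        assert got[VISIT_SCREEN_TRANSITION] == 9
        assert got[REACH_ELEMENT] == 1
        assert got[CLICK_SAME_LEVEL] == 1
        assert len(pw.node_ids()) == 11

    def test_element_on_top_screen(self):
        tree = make_chain(1)
        pw = trace_pathway(tree, ["n1"])
        assert actions(pw) == {CLICK_SAME_LEVEL: 1, REACH_ELEMENT: 1}

    def test_missing_target(self, chain11):
        with pytest.raises(MissingNodeError):
            trace_pathway(chain11, ["nope"])

    def test_empty_targets(self, chain11):
        with pytest.raises(EmptyTargetsError):
            trace_pathway(chain11, [])

    def test_document_order_default(self, binary_tree):
        targets = [n.id for n in binary_tree.iter_preorder() if n.is_target]
        pw = trace_pathway(binary_tree, list(reversed(targets)))
        assert pw.target_order == targets  # re-sorted to document order
        pw2 = trace_pathway(binary_tree, list(reversed(targets)), ordered=True)
        assert pw2.target_order == list(reversed(targets))


class TestOracleEquivalence:
    """Action counts must match an independent networkx route counter."""

    def small_trees(self):
        trees = [
            make_chain(4),
            make_chain(6, scrolling={2, 4}),
            generate_nav_tree(TreeSpec(depth=2, branching=3, n_targets=1, seed=1)),
            generate_nav_tree(TreeSpec(depth=3, branching=2, n_targets=1,
                                       p_scroll=0.4, seed=2)),
            generate_nav_tree(TreeSpec(depth=2, branching=4, n_targets=1, seed=3)),
        ]
        # a tree with menu-length overrides exercises the ML term
        override = generate_nav_tree(TreeSpec(depth=3, branching=2, n_targets=1, seed=4))
        for i, node in enumerate(override.nodes.values()):
            if node.kind == "screen" and i % 3 == 0:
                node.menu_length_override = 5
        trees.append(override)
        return trees

    @pytest.mark.parametrize("routing", ["reasonable_maximum", "shortest"])
    def test_counts_match_nx_routes(self, routing):
        for tree in self.small_trees():
            assert len(tree) <= 30
            ids = [n.id for n in tree.iter_preorder()
                   if n.kind in ("screen", "data_element")]
            max_k = 4 if len(ids) <= 10 else 2
            for k in range(1, max_k + 1):
                for combo in itertools.combinations(ids, k):
                    pw = trace_pathway(tree, combo, routing=routing)
                    tally = tally_actions(pw, tree)
                    E, IS, C, SS, ML = nx_action_counts(
                        tree, pw.target_order, routing
                    )
                    assert tally.E == E
                    assert tally.IS_by_level == IS
                    assert tally.C_by_level == C
                    assert tally.SS_by_level == SS
                    assert tally.ML == ML


class TestTally:
    def test_empty_pathway_is_all_zero(self, chain11):
        tally = tally_actions(Pathway(start_id="n0"), chain11)
        assert (tally.E, tally.IS, tally.C, tally.SS, tally.ML) == (0, 0, 0, 0, 0)

    def test_scrolling_screen_costs_two(self):
        """A scrolling screen on the route counts 2 scroll actions at its level."""
        tree = make_chain(3, scrolling={2})
        pw = trace_pathway(tree, ["n3"])
        tally = tally_actions(pw, tree)
        assert tally.SS_by_level == {2: 2}

    def test_manual_count_on_binary_tree(self, binary_tree):
        """Step-by-step hand count for two leaf targets in opposite subtrees."""
        leaves = [n for n in binary_tree.iter_preorder() if not n.children]
        a, b = leaves[0], leaves[-1]  # first and last leaf: disjoint subtrees
        pw = trace_pathway(binary_tree, [a.id, b.id], routing="reasonable_maximum")
        tally = tally_actions(pw, binary_tree)
        # leg 1 down: screens at levels 1,2 then the element click at 3;
        # back up: transitions into levels 1,0; leg 2 down: levels 1,2, click at 3
        assert tally.E == 2
        assert tally.IS_by_level == {1: 3, 2: 2, 0: 1}
        assert tally.C_by_level == {1: 3, 2: 2, 0: 1, 3: 2}
        assert tally.ML == 12  # six descents through binary menus of length 2

    def test_ml_uses_override(self):
        tree = make_chain(2)
        tree.node("n0").menu_length_override = 7
        pw = trace_pathway(tree, ["n2"])
        assert tally_actions(pw, tree).ML == 7 + 1


class TestComputeDfi:
    def test_zero_tally(self):
        assert compute_dfi(ActionTally()).total == 0

    def test_closed_form_chain(self):
        """Constant-1 policy, single element at depth d, unit menus:
        total = 1 + (d-1) + d + d."""
        for d in range(1, 11):
            tree = make_chain(d)
            bd = dfi_for_tree(tree, policy=MultiplierPolicy("constant", 1))
            assert bd.total == 1 + (d - 1) + d + d

    def test_depth_weighting(self):
        tree = make_chain(3)
        bd = dfi_for_tree(tree)  # depth_weighted default
        # transitions into levels 1,2 weigh 1+2; element click at level 3
        assert bd.IS_term == 3
        assert bd.C_term == 3 + 3
        assert bd.ML_term == 3
        assert bd.total == 1 + 3 + 6 + 3

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(k=st.integers(1, 9), seed=st.integers(0, 500))
    def test_linearity_in_tally(self, k, seed):
        """Scaling every count by k scales every weighted term by k."""
        tree = generate_nav_tree(TreeSpec(depth=3, branching=2, n_targets=3,
                                          p_scroll=0.3, seed=seed))
        tally = tally_actions(
            trace_pathway(tree, [n.id for n in tree.iter_preorder() if n.is_target]),
            tree,
        )
        for policy in (MultiplierPolicy(), MultiplierPolicy("constant", 2.5)):
            one = compute_dfi(tally, policy)
            many = compute_dfi(tally.scaled(k), policy)
            assert many.total == pytest.approx(k * one.total)
            assert many.IS_term == pytest.approx(k * one.IS_term)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000), extra=st.integers(0, 6))
    def test_monotone_in_targets(self, seed, extra):
        """Adding a target never decreases DFI under the default policy."""
        tree = generate_nav_tree(TreeSpec(depth=3, branching=2, n_targets=2, seed=seed))
        leaves = [n.id for n in tree.iter_preorder() if not n.children]
        base = leaves[:2]
        more = base + leaves[2 : 2 + extra]
        small = dfi_for_tree(tree, base)
        big = dfi_for_tree(tree, more)
        assert big.total >= small.total
        assert big.IS_term >= small.IS_term
        assert big.ML_term >= small.ML_term


class TestCompareSystems:
    def test_identity(self):
        bd = dfi_for_tree(make_chain(4))
        cmp = compare_systems(bd, bd)
        assert cmp.ratio == 1
        assert cmp.delta_total == 0

    def test_zero_total_has_no_ratio(self):
        zero = compute_dfi(ActionTally())
        bd = dfi_for_tree(make_chain(4))
        cmp = compare_systems(zero, bd)
        assert cmp.ratio is None
        assert cmp.delta_total == bd.total
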