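"""Independent reference implementations used only for cross-checking.

These deliberately share no code with the package internals: routes come
from networkx shortest paths on the undirected tree graph, instance counts
from a plain run-length encoding, pogo findings from a quadratic window
scan.
"""

from collections import defaultdict

import networkx as nx

from ehrfrag.nav_model import NavTree


def nx_action_counts(tree: NavTree, targets_in_order, routing):
    """Recount pathway actions by walking networkx shortest paths."""
    g = nx.Graph()
    for node in tree.nodes.values():
        g.add_node(node.id)
        if node.parent_id is not None:
            g.add_edge(node.parent_id, node.id)

    depth = {n.id: n.depth for n in tree.nodes.values()}
    kind = {n.id: n.kind for n in tree.nodes.values()}
    scrolling = {n.id: n.is_scrolling_screen for n in tree.nodes.values()}

    def menu_length(nid):
        n = tree.nodes[nid]
        return n.menu_length_override if n.menu_length_override is not None else len(n.children)

    E = 0
    IS = defaultdict(int)
    C = defaultdict(int)
    SS = defaultdict(int)
    ML = 0

    pos = tree.root_id
    if scrolling[pos]:
        SS[depth[pos]] += 2
    for t in targets_in_order:
        if routing == "reasonable_maximum":
            up = nx.shortest_path(g, pos, tree.root_id)
            down = nx.shortest_path(g, tree.root_id, t)
            route = up + down[1:]
        else:
            route = nx.shortest_path(g, pos, t)
        for u, v in zip(route, route[1:]):
            descending = depth[v] == depth[u] + 1
            if descending:
                ML += menu_length(u)
                if v == t and kind[v] == "data_element":
                    C[depth[v]] += 1  # element selection: click, no transition
                else:
                    IS[depth[v]] += 1
                    C[depth[v]] += 1
                if scrolling[v]:
                    SS[depth[v]] += 2
            else:  # ascending into the parent v
                if kind[u] == "data_element":
                    continue  # the element sits on v's screen already
                IS[depth[v]] += 1
                C[depth[v]] += 1
                if scrolling[v]:
                    SS[depth[v]] += 2
        E += 1
        pos = t
    return E, dict(IS), dict(C), dict(SS), ML


def rle_instances(labels):
    """Run-length encoding of a label sequence -> label -> run count."""
    counts = defaultdict(int)
    prev = object()
    for lab in labels:
        if lab != prev:
            counts[lab] += 1
        prev = lab
    return dict(counts)


def quadratic_pogo_scan(keys, min_repeats):
    """All maximal alternating windows, found by brute force over (i, j)."""

    def alternating(i, j):
        if j - i + 1 < 3:
            return False
        for k in range(i, j - 1):
            if keys[k] != keys[k + 2]:
                return False
        for k in range(i, j):
            if keys[k] == keys[k + 1]:
                return False
        return True

    found = []
    n = len(keys)
    for i in range(n):
        for j in range(i + 2, n):
            if not alternating(i, j):
                continue
            left_ext = i > 0 and alternating(i - 1, j)
            right_ext = j < n - 1 and alternating(i, j + 1)
            if left_ext or right_ext:
                continue
            run_len = j - i + 1
            ca, cb = (run_len + 1) // 2, run_len // 2
            if min(ca, cb) >= min_repeats:
                found.append((keys[i], keys[i + 1], i, j, ca, cb))
    return found
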