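"""Navigation-hierarchy model for menu-based clinical interfaces.

A modified cognitive walkthrough of an EHR yields a tree: the root is the
highest-level screen, each level below it holds the menus, sub-screens and
data elements reachable from its parent.  This module represents that tree
(:class:`NavNode` / :class:`NavTree`) and (de)serializes it to two dialects:

* a path-per-row CSV table (one column per level, ``level_1..level_k``, plus
  annotation columns), mirroring the spreadsheet form sunburst charts are
  built from; and
* a nested JSON form with children inline, for programmatic construction.

Node kinds are ``screen`` (a view of its own), ``menu_item`` (an expandable
entry that does not change the screen) and ``data_element`` (a leaf holding
clinical content).  Targets — nodes relevant to the task under study — may be
screens or data elements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import (
    AnnotationConflictError,
    DuplicateSiblingLabelError,
    EmptyInputError,
    MissingNodeError,
    RaggedPathError,
    TreeInvariantError,
)

NODE_KINDS = ("screen", "menu_item", "data_element")

#: annotation columns of the tabular dialect, in canonical order
ANNOTATION_COLUMNS = ("kind", "is_target", "is_scrolling", "menu_length_override")


@dataclass
class NavNode:
    """One node of the navigation hierarchy.

    ``menu_length_override`` exists because real screens display parallel
    items that are not modeled as tree children; when absent, the menu
    length at this node defaults to its child count.
    """

    id: str
    label: str
    kind: str = "screen"
    depth: int = 0
    parent_id: str | None = None
    children: list[str] = field(default_factory=list)
    is_target: bool = False
    is_scrolling_screen: bool = False
    menu_length_override: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise TreeInvariantError(f"unknown node kind {self.kind!r}")
        if self.is_target and self.kind not in ("data_element", "screen"):
            raise TreeInvariantError(
                f"node {self.id!r}: is_target allowed only for data_element or screen"
            )
        if self.menu_length_override is not None and self.menu_length_override < 1:
            raise TreeInvariantError(
                f"node {self.id!r}: menu_length_override must be a positive integer"
            )


@dataclass
class NavTree:
    """A validated navigation tree (mapping of ids to nodes plus root)."""

    nodes: dict[str, NavNode]
    root_id: str
    max_depth: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    def node(self, node_id: str) -> NavNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise MissingNodeError(f"node id {node_id!r} not in tree") from None

    @property
    def root(self) -> NavNode:
        return self.nodes[self.root_id]

    def parent(self, node_id: str) -> NavNode | None:
        pid = self.node(node_id).parent_id
        return None if pid is None else self.nodes[pid]

    def children(self, node_id: str) -> list[NavNode]:
        return [self.nodes[c] for c in self.node(node_id).children]

    def menu_length(self, node_id: str) -> int:
        """Menu length at a decision point: override if set, else child count."""
        node = self.node(node_id)
        if node.menu_length_override is not None:
            return node.menu_length_override
        return len(node.children)

    def iter_preorder(self, start_id: str | None = None) -> Iterator[NavNode]:
        """Depth-first preorder traversal in sibling order (document order)."""
        stack = [start_id if start_id is not None else self.root_id]
        while stack:
            node = self.node(stack.pop())
            yield node
            stack.extend(reversed(node.children))

    def document_order(self) -> dict[str, int]:
        return {n.id: i for i, n in enumerate(self.iter_preorder())}

    def ancestors(self, node_id: str) -> list[str]:
        """Ids from this node up to the root, inclusive of both ends."""
        out = [node_id]
        node = self.node(node_id)
        while node.parent_id is not None:
            node = self.node(node.parent_id)
            out.append(node.id)
        return out

    def __len__(self) -> int:
        return len(self.nodes)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.root_id not in self.nodes:
            raise TreeInvariantError("root_id not among nodes")
        if self.nodes[self.root_id].parent_id is not None:
            raise TreeInvariantError("root must have no parent")
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise TreeInvariantError(f"expected exactly one root, found {len(roots)}")
        seen: set[str] = set()
        for node in self.iter_preorder():
            if node.id in seen:
                raise TreeInvariantError(f"node {node.id!r} reached twice (cycle?)")
            seen.add(node.id)
            for cid in node.children:
                child = self.node(cid)
                if child.parent_id != node.id:
                    raise TreeInvariantError(
                        f"child {cid!r} does not point back to parent {node.id!r}"
                    )
                if child.depth != node.depth + 1:
                    raise TreeInvariantError(
                        f"depth({cid!r}) != depth({node.id!r}) + 1"
                    )
        if seen != set(self.nodes):
            unreachable = sorted(set(self.nodes) - seen)
            raise TreeInvariantError(f"unreachable nodes: {unreachable}")
        true_max = max(n.depth for n in self.nodes.values())
        if self.max_depth != true_max:
            raise TreeInvariantError(
                f"max_depth {self.max_depth} != observed {true_max}"
            )


def build_tree(nodes: Iterable[NavNode], root_id: str) -> NavTree:
    """Assemble and validate a NavTree, computing max_depth."""
    mapping = {n.id: n for n in nodes}
    max_depth = max(n.depth for n in mapping.values())
    return NavTree(nodes=mapping, root_id=root_id, max_depth=max_depth)


# ---------------------------------------------------------------------------
# tabular (path-per-row) dialect
# ---------------------------------------------------------------------------


def _coerce_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    s = str(value).strip()
    if s in ("", "0", "0.0"):
        return False
    if s in ("1", "1.0"):
        return True
    raise ValueError(f"boolean cell must be 0/1, got {value!r}")


def _coerce_override(value: object) -> int | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return int(float(value))


def _row_path(row: Mapping[str, object], level_cols: Sequence[str]) -> list[str]:
    labels: list[object] = [row.get(c) for c in level_cols]
    cleaned = []
    for v in labels:
        if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
            cleaned.append(None)
        else:
            cleaned.append(str(v))
    # trailing blanks denote a shorter path; internal blanks are ambiguous
    while cleaned and cleaned[-1] is None:
        cleaned.pop()
    if not cleaned:
        raise RaggedPathError("row has no level labels")
    if any(v is None for v in cleaned):
        raise RaggedPathError(f"blank cell inside path {cleaned!r}")
    return cleaned  # type: ignore[return-value]


def parse_nav_table(rows: pd.DataFrame | Iterable[Mapping[str, object]]) -> NavTree:
    """Parse path-per-row records into a NavTree.

    Each row gives an ordered label sequence from the root to some node, one
    column per level (``level_1``, ``level_2``, ...; trailing blanks allowed),
    plus annotation columns applying to the row's final node.  Identical label
    prefixes merge into shared ancestors; sibling order follows first
    appearance.  Nodes only ever seen as prefixes get default annotations
    (kind ``screen``, no flags).
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    if rows.empty:
        raise EmptyInputError("no rows in navigation table")
    level_cols = [c for c in rows.columns if str(c).startswith("level_")]
    level_cols.sort(key=lambda c: int(str(c).split("_", 1)[1]))
    if not level_cols:
        raise EmptyInputError("no level_* columns in navigation table")

    nodes: dict[str, NavNode] = {}
    # key: tuple of labels from root -> node id
    by_path: dict[tuple[str, ...], str] = {}
    annotated: dict[str, tuple] = {}
    counter = 0

    def ensure(path: tuple[str, ...]) -> str:
        nonlocal counter
        if path in by_path:
            return by_path[path]
        parent_id = ensure(path[:-1]) if len(path) > 1 else None
        node_id = f"n{counter}"
        counter += 1
        nodes[node_id] = NavNode(
            id=node_id,
            label=path[-1],
            kind="screen",
            depth=len(path) - 1,
            parent_id=parent_id,
        )
        if parent_id is not None:
            nodes[parent_id].children.append(node_id)
        by_path[path] = node_id
        return node_id

    for _, row in rows.iterrows():
        path = tuple(_row_path(row, level_cols))
        node_id = ensure(path)
        kind = row.get("kind")
        if kind is None or (isinstance(kind, float) and pd.isna(kind)) or str(kind) == "":
            kind = "screen"
        ann = (
            str(kind),
            _coerce_bool(row.get("is_target")),
            _coerce_bool(row.get("is_scrolling")),
            _coerce_override(row.get("menu_length_override")),
        )
        if node_id in annotated and annotated[node_id] != ann:
            raise AnnotationConflictError(
                f"conflicting annotations for path {' / '.join(path)}"
            )
        annotated[node_id] = ann
        node = nodes[node_id]
        node.kind, node.is_target, node.is_scrolling_screen, node.menu_length_override = ann
        # re-run NavNode field checks
        NavNode.__post_init__(node)

    root_id = by_path[min(by_path, key=len)]
    if len(min(by_path, key=len)) != 1:
        raise TreeInvariantError("rows do not share a single root label")
    return build_tree(nodes.values(), root_id)


def serialize_nav_table(tree: NavTree) -> pd.DataFrame:
    """Serialize a NavTree to the path-per-row dialect (one row per node).

    Emitting a row for every node (not only leaves) preserves interior-node
    annotations through a round trip.  Requires unique sibling labels, since
    the dialect merges identical label prefixes on parsing.
    """
    for node in tree.nodes.values():
        labels = [tree.node(c).label for c in node.children]
        if len(labels) != len(set(labels)):
            raise DuplicateSiblingLabelError(
                f"children of {node.label!r} have duplicate labels; "
                "use the JSON dialect for this tree"
            )
    k = tree.max_depth + 1
    level_cols = [f"level_{i + 1}" for i in range(k)]
    records = []
    for node in tree.iter_preorder():
        path_ids = list(reversed(tree.ancestors(node.id)))
        labels = [tree.node(i).label for i in path_ids]
        rec: dict[str, object] = {c: "" for c in level_cols}
        for c, lab in zip(level_cols, labels):
            rec[c] = lab
        rec["kind"] = node.kind
        rec["is_target"] = int(node.is_target)
        rec["is_scrolling"] = int(node.is_scrolling_screen)
        rec["menu_length_override"] = (
            "" if node.menu_length_override is None else node.menu_length_override
        )
        records.append(rec)
    return pd.DataFrame.from_records(
        records, columns=level_cols + list(ANNOTATION_COLUMNS)
    )


def read_nav_csv(path) -> NavTree:
    """Read the CSV dialect (UTF-8, header row) from a file path."""
    return parse_nav_table(pd.read_csv(path, dtype=str, keep_default_na=False))


def write_nav_csv(tree: NavTree, path) -> None:
    serialize_nav_table(tree).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# nested JSON dialect
# ---------------------------------------------------------------------------


def tree_to_nested(tree: NavTree) -> dict:
    """Nested-dict mirror of the tree (children inline), ids preserved."""

    def build(node_id: str) -> dict:
        n = tree.node(node_id)
        d: dict = {"id": n.id, "label": n.label, "kind": n.kind}
        if n.is_target:
            d["is_target"] = True
        if n.is_scrolling_screen:
            d["is_scrolling_screen"] = True
        if n.menu_length_override is not None:
            d["menu_length_override"] = n.menu_length_override
        if n.children:
            d["children"] = [build(c) for c in n.children]
        return d

    return build(tree.root_id)


def tree_from_nested(data: Mapping) -> NavTree:
    """Inverse of :func:`tree_to_nested`; missing ids are auto-assigned."""
    nodes: list[NavNode] = []
    counter = 0

    def build(d: Mapping, depth: int, parent_id: str | None) -> str:
        nonlocal counter
        node_id = str(d.get("id") or f"n{counter}")
        counter += 1
        node = NavNode(
            id=node_id,
            label=str(d["label"]),
            kind=str(d.get("kind", "screen")),
            depth=depth,
            parent_id=parent_id,
            is_target=bool(d.get("is_target", False)),
            is_scrolling_screen=bool(d.get("is_scrolling_screen", False)),
            menu_length_override=d.get("menu_length_override"),
        )
        nodes.append(node)
        for child in d.get("children", []):
            node.children.append(build(child, depth + 1, node_id))
        return node_id

    root_id = build(data, 0, None)
    return build_tree(nodes, root_id)


def write_nav_json(tree: NavTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree_to_nested(tree), fh, indent=2)
        fh.write("\n")


def read_nav_json(path) -> NavTree:
    with open(path, encoding="utf-8") as fh:
        return tree_from_nested(json.load(fh))
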