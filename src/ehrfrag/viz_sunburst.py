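"""Sunburst (radial partition) layout and rendering for navigation trees.

The root screen is the center disc; each deeper hierarchy level is drawn as
the next concentric ring, with siblings as adjacent angular sectors inside
their parent's extent.  More rings means more system levels and screen
transitions — the visual signature of display fragmentation.  Target nodes
are shaded dark; a traced pathway can be highlighted on top.

Angles are kept as exact rationals (``fractions.Fraction`` degrees) so child
extents always sum exactly to their parent's extent, in both weighting
modes.  Re-rooting on a subtree (interactive drill-down in spreadsheet
sunbursts) is exposed as a re-layout on that subtree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Literal, Mapping

from . import _svg
from .errors import PathwayInconsistencyError
from .fragmentation import Pathway
from .nav_model import NavTree

FillClass = Literal["default", "target", "highlight", "irrelevant"]

DEFAULT_FILLS: dict[str, str] = {
    "default": "#d9d9d9",
    "target": "#1a1a1a",
    "highlight": "#2ca02c",
    "irrelevant": "#f5f5f5",
}

#: ring index used for the root's center disc
CENTER_DISC = -1


@dataclass(frozen=True)
class SunburstSegment:
    node_id: str
    ring: int  # depth - 1; the root carries CENTER_DISC (-1)
    start_angle_deg: Fraction
    end_angle_deg: Fraction
    fill_class: str = "default"

    @property
    def extent_deg(self) -> Fraction:
        return self.end_angle_deg - self.start_angle_deg


def layout_sunburst(
    tree: NavTree,
    weighting: Literal["equal_split", "leaf_weighted"] = "leaf_weighted",
    start_id: str | None = None,
) -> list[SunburstSegment]:
    """Compute one segment per node, partitioning [0, 360) exactly.

    ``equal_split`` divides a parent's extent equally among its children;
    ``leaf_weighted`` divides it proportionally to leaf-descendant counts.
    Passing ``start_id`` re-roots the layout on that subtree (drill-down).
    """
    if weighting not in ("equal_split", "leaf_weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    root_id = start_id if start_id is not None else tree.root_id
    root_depth = tree.node(root_id).depth

    leaf_counts: dict[str, int] = {}

    def count_leaves(node_id: str) -> int:
        children = tree.node(node_id).children
        n = 1 if not children else sum(count_leaves(c) for c in children)
        leaf_counts[node_id] = n
        return n

    count_leaves(root_id)

    segments: list[SunburstSegment] = []

    def emit(node_id: str, start: Fraction, end: Fraction) -> None:
        node = tree.node(node_id)
        segments.append(
            SunburstSegment(
                node_id=node_id,
                ring=node.depth - root_depth - 1,
                start_angle_deg=start,
                end_angle_deg=end,
                fill_class="target" if node.is_target else "default",
            )
        )
        children = node.children
        if not children:
            return
        cursor = start
        total_extent = end - start
        if weighting == "equal_split":
            share = total_extent / len(children)
            for c in children:
                emit(c, cursor, cursor + share)
                cursor += share
        else:
            total_leaves = sum(leaf_counts[c] for c in children)
            for c in children:
                share = total_extent * leaf_counts[c] / total_leaves
                emit(c, cursor, cursor + share)
                cursor += share

    emit(root_id, Fraction(0), Fraction(360))
    return segments


def highlight_pathway(
    segments: Iterable[SunburstSegment], pathway: Pathway
) -> list[SunburstSegment]:
    """Mark every segment whose node lies on the pathway as ``highlight``.

    Targets off the pathway keep their ``target`` shading; everything else
    is unchanged.  An empty pathway highlights nothing.
    """
    segments = list(segments)
    if not pathway.steps:
        return segments
    on_path = set(pathway.node_ids())
    have = {s.node_id for s in segments}
    missing = on_path - have
    if missing:
        raise PathwayInconsistencyError(
            f"pathway nodes without segments: {sorted(missing)}"
        )
    return [
        replace(s, fill_class="highlight") if s.node_id in on_path else s
        for s in segments
    ]


def render_sunburst(
    segments: Iterable[SunburstSegment],
    size: float = 600.0,
    palette: Mapping[str, str] | None = None,
) -> str:
    """Render segments as an SVG document: center disc plus annular sectors."""
    segments = list(segments)
    fills = dict(DEFAULT_FILLS)
    if palette:
        fills.update(palette)
    cx = cy = size / 2
    n_rings = max((s.ring for s in segments), default=0) + 1
    r_center = size * 0.08
    ring_width = (size / 2 * 0.95 - r_center) / max(n_rings, 1)
    body: list[str] = []
    for seg in segments:
        fill = fills.get(seg.fill_class, fills["default"])
        if seg.ring == CENTER_DISC:
            body.append(
                _svg.circle(cx, cy, r_center, fill, stroke="#ffffff", stroke_width="1")
            )
            continue
        r_inner = r_center + seg.ring * ring_width
        r_outer = r_inner + ring_width
        body.append(
            _svg.annular_sector(
                cx,
                cy,
                r_inner,
                r_outer,
                float(seg.start_angle_deg),
                float(seg.end_angle_deg),
                fill,
                stroke="#ffffff",
                stroke_width="1",
            )
        )
    return _svg.document(size, size, body)
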