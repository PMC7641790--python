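"""Time belt layout and rendering for task sessions.

One horizontal belt per session: each task segment becomes a color-coded bar
whose width is proportional to its duration, so the belt length shows the
case duration and the banding shows how the work splintered into instances.
Idle gaps render as unfilled space.  Identical task labels map to identical
colors across all rows (label-sorted assignment against a fixed qualitative
palette), and the legend covers every label present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import _svg
from ._svg import QUALITATIVE_PALETTE
from .session_model import Session


@dataclass(frozen=True)
class BeltBar:
    task_label: str
    x_offset: float
    width: float
    color_key: str


@dataclass
class BeltRow:
    session_id: str
    bars: list[BeltBar] = field(default_factory=list)
    total_width: float = 0.0


def assign_colors(labels: Iterable[str]) -> dict[str, str]:
    """Stable label -> color mapping: sorted labels against the fixed palette."""
    return {
        label: QUALITATIVE_PALETTE[i % len(QUALITATIVE_PALETTE)]
        for i, label in enumerate(sorted(set(labels)))
    }


def layout_timebelt(
    sessions: Sequence[Session], scale: float = 1.0
) -> tuple[list[BeltRow], dict[str, str]]:
    """Lay out one BeltRow per session on a shared absolute time scale.

    ``scale`` is drawing units per second; bar offsets and widths are
    ``start_s * scale`` and ``duration_s * scale``.
    """
    if not sessions:
        raise ValueError("need at least one session")
    if scale <= 0:
        raise ValueError("scale must be positive")
    legend = assign_colors(
        label for session in sessions for label in session.task_labels()
    )
    rows = []
    for session in sessions:
        bars = [
            BeltBar(
                task_label=seg.task_label,
                x_offset=seg.start_s * scale,
                width=seg.duration_s * scale,
                color_key=legend[seg.task_label],
            )
            for seg in session.segments
        ]
        span = session.segments[-1].end_s if session.segments else 0.0
        rows.append(
            BeltRow(session_id=session.session_id, bars=bars, total_width=span * scale)
        )
    return rows, legend


def render_timebelt(
    rows: Sequence[BeltRow],
    legend: dict[str, str],
    row_height: float = 26.0,
    row_gap: float = 10.0,
    label_width: float = 90.0,
    margin: float = 12.0,
) -> str:
    """Render belts stacked vertically with a legend underneath."""
    max_width = max((r.total_width for r in rows), default=0.0)
    legend_rows = len(legend)
    width = label_width + max_width + 2 * margin
    height = (
        margin
        + len(rows) * (row_height + row_gap)
        + (legend_rows * (row_height * 0.7 + 4))
        + margin
    )
    body: list[str] = []
    y = margin
    for row in rows:
        body.append(
            _svg.text(margin, y + row_height * 0.65, row.session_id, size=11)
        )
        for bar in row.bars:
            body.append(
                _svg.rect(
                    label_width + bar.x_offset,
                    y,
                    bar.width,
                    row_height,
                    bar.color_key,
                    stroke="#ffffff",
                    stroke_width="0.5",
                    **{"class": "belt-bar"},
                )
            )
        y += row_height + row_gap
    sw = row_height * 0.7
    for label in sorted(legend):
        body.append(
            _svg.rect(label_width, y, sw, sw, legend[label], **{"class": "legend-swatch"})
        )
        body.append(_svg.text(label_width + sw + 6, y + sw * 0.8, label, size=11))
        y += sw + 4
    return _svg.document(width, height, body)
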