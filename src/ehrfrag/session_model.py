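"""Time-stamped task event logs and their segmentation into task instances.

A session is an ordered list of non-overlapping segments, each labeled with
the task being performed (and optionally the screen shown).  Times are
seconds relative to session start; absolute timestamps must be pre-converted.
Total EHR time is the sum of segment durations (idle gaps are not EHR time);
a span-based alternative (last end minus first start) is available.

A *task instance* is a maximal run of consecutive segments sharing a label:
zero-gap adjacency merges, while any gap or interleaved other-task segment
splits.  Instances are what the task-fragmentation measures (ACT, PPI) and
the time-belt bands are built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

from .errors import MalformedSegmentError, OverlapError

#: canonical CSV header for session logs
SESSION_COLUMNS = ("session_id", "task", "start_s", "end_s", "screen_id")


@dataclass(frozen=True)
class TaskSegment:
    task_label: str
    start_s: float
    end_s: float
    screen_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.end_s > self.start_s >= 0):
            raise MalformedSegmentError(
                f"segment {self.task_label!r}: need end > start >= 0, "
                f"got [{self.start_s}, {self.end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Session:
    """One user session: sorted, non-overlapping task segments."""

    session_id: str
    segments: list[TaskSegment] = field(default_factory=list)
    time_basis: Literal["active", "span"] = "active"

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.start_s)
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start_s < prev.end_s:
                raise OverlapError(
                    f"session {self.session_id!r}: segment "
                    f"({cur.task_label!r}, {cur.start_s}, {cur.end_s}) overlaps "
                    f"({prev.task_label!r}, {prev.start_s}, {prev.end_s})"
                )

    @property
    def total_time_s(self) -> float:
        """Total EHR time: active time by default, wall-clock span if configured."""
        if not self.segments:
            return 0.0
        if self.time_basis == "span":
            return self.segments[-1].end_s - self.segments[0].start_s
        return sum(s.duration_s for s in self.segments)

    def task_labels(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.task_label, None)
        return list(seen)


@dataclass(frozen=True)
class Instance:
    """A maximal continuous run of one task."""

    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def parse_session_log(
    rows: pd.DataFrame | Iterable[Mapping[str, object]],
) -> list[Session]:
    """Group tabular records into validated Sessions.

    Expects columns ``session_id, task, start_s, end_s`` and optional
    ``screen_id``.  Sessions are returned in order of first appearance.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    if rows.empty:
        return []
    missing = {"session_id", "task", "start_s", "end_s"} - set(rows.columns)
    if missing:
        raise MalformedSegmentError(f"missing columns: {sorted(missing)}")
    has_screen = "screen_id" in rows.columns
    sessions: list[Session] = []
    for sid in rows["session_id"].drop_duplicates():
        chunk = rows[rows["session_id"] == sid]
        segments = []
        for _, row in chunk.iterrows():
            screen = None
            if has_screen:
                raw = row["screen_id"]
                if raw is not None and not (isinstance(raw, float) and pd.isna(raw)):
                    s = str(raw).strip()
                    screen = s or None
            segments.append(
                TaskSegment(
                    task_label=str(row["task"]),
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                    screen_id=screen,
                )
            )
        sessions.append(Session(session_id=str(sid), segments=segments))
    return sessions


def read_session_csv(path) -> list[Session]:
    return parse_session_log(pd.read_csv(path))


def session_to_frame(session: Session) -> pd.DataFrame:
    records = [
        {
            "session_id": session.session_id,
            "task": s.task_label,
            "start_s": s.start_s,
            "end_s": s.end_s,
            "screen_id": s.screen_id if s.screen_id is not None else "",
        }
        for s in session.segments
    ]
    return pd.DataFrame.from_records(records, columns=list(SESSION_COLUMNS))


def write_session_csv(sessions: Iterable[Session], path) -> None:
    frames = [session_to_frame(s) for s in sessions]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def segment_instances(
    session: Session, max_gap_s: float = 0.0
) -> dict[str, list[Instance]]:
    """Merge consecutive same-label segments into task instances.

    With the default ``max_gap_s = 0`` only exactly abutting segments merge;
    any idle gap (or an interleaved other-task segment) splits an instance.
    Returned mapping preserves first-appearance order of labels.
    """
    instances: dict[str, list[Instance]] = {}
    run_label: str | None = None
    run_start = run_end = 0.0
    for seg in session.segments:
        if (
            run_label == seg.task_label
            and seg.start_s - run_end <= max_gap_s
        ):
            run_end = seg.end_s
            continue
        if run_label is not None:
            instances.setdefault(run_label, []).append(Instance(run_start, run_end))
        run_label, run_start, run_end = seg.task_label, seg.start_s, seg.end_s
    if run_label is not None:
        instances.setdefault(run_label, []).append(Instance(run_start, run_end))
    # keep first-appearance order even when a label's first run closes late
    ordered = {label: instances[label] for label in session.task_labels()}
    return ordered
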