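"""Task-fragmentation measures: average continuous time and proportion per instance.

For a task within a session,

* ACT (average continuous time) is the mean duration of its instances —
  the longer the ACT, the lower the task fragmentation;
* PPI (proportion per instance) is the task's total time divided by
  (number of instances x total EHR time).

PPI normalizes by total EHR time so longer sessions do not inflate the
measure, and it decreases as the same task time splinters into more
instances: a lower PPI denotes more fragmented subtasks.  Equivalently,
PPI = ACT / total EHR time.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import MissingTaskError, UndefinedMetricError
from .session_model import Session, segment_instances


@dataclass(frozen=True)
class TaskStats:
    task_label: str
    total_time_s: float
    n_instances: int
    act_s: float
    ppi: float

    def to_dict(self) -> dict:
        return {
            "task_label": self.task_label,
            "total_time_s": self.total_time_s,
            "n_instances": self.n_instances,
            "act_s": self.act_s,
            "ppi": self.ppi,
        }


def _instances_for(session: Session, task_label: str):
    instances = segment_instances(session).get(task_label)
    if not instances:
        raise MissingTaskError(
            f"task {task_label!r} does not occur in session {session.session_id!r}"
        )
    return instances


def average_continuous_time(session: Session, task_label: str) -> float:
    """Mean instance duration of a task, in seconds."""
    instances = _instances_for(session, task_label)
    return sum(i.duration_s for i in instances) / len(instances)


def proportion_per_instance(session: Session, task_label: str) -> float:
    """Task total time / (number of instances x total EHR time)."""
    instances = _instances_for(session, task_label)
    total = session.total_time_s
    if total <= 0:
        raise UndefinedMetricError(
            f"session {session.session_id!r} has zero total time"
        )
    task_total = sum(i.duration_s for i in instances)
    return task_total / (len(instances) * total)


def task_summary(session: Session) -> list[TaskStats]:
    """One TaskStats per distinct label, ordered by first appearance."""
    total = session.total_time_s
    out = []
    for label, instances in segment_instances(session).items():
        task_total = sum(i.duration_s for i in instances)
        n = len(instances)
        act = task_total / n
        ppi = task_total / (n * total) if total > 0 else float("nan")
        out.append(
            TaskStats(
                task_label=label,
                total_time_s=task_total,
                n_instances=n,
                act_s=act,
                ppi=ppi,
            )
        )
    return out


def summary_frame(session: Session) -> pd.DataFrame:
    """Task summary as a DataFrame (CSV-ready)."""
    return pd.DataFrame.from_records([s.to_dict() for s in task_summary(session)])
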