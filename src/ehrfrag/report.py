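"""Combined fragmentation report: DFI, task metrics, figures, pogo-sticking.

Pogo-sticking is repeated back-and-forth navigation between two elements or
sections — the signature of two related pieces of information living far
apart in the display.  Detected alternations are turned into juxtaposition
suggestions (pairs whose co-display would remove the repeated navigation),
ranked by the total time spent inside the alternation window, i.e. largest
recoverable time first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import _svg
from .errors import EmptyReportError
from .fragmentation import (
    MultiplierPolicy,
    RoutingPolicy,
    compare_systems,
    compute_dfi,
    tally_actions,
    trace_pathway,
)
from .nav_model import NavTree
from .session_model import Session
from .task_metrics import task_summary
from .viz_sunburst import highlight_pathway, layout_sunburst, render_sunburst
from .viz_timebelt import layout_timebelt, render_timebelt


@dataclass(frozen=True)
class PogoFinding:
    """One maximal alternation X,Y,X,... with per-member visit counts."""

    pair: tuple[str, str]
    counts: tuple[int, int]
    window_start_s: float
    window_end_s: float
    time_in_window_s: float

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "counts": list(self.counts),
            "window_start_s": self.window_start_s,
            "window_end_s": self.window_end_s,
            "time_in_window_s": self.time_in_window_s,
        }


def _alternation_keys(session: Session) -> list[str]:
    """Screen ids when every segment has one, else task labels."""
    if session.segments and all(s.screen_id is not None for s in session.segments):
        return [s.screen_id for s in session.segments]  # type: ignore[misc]
    return [s.task_label for s in session.segments]


def detect_pogo_sticking(session: Session, min_repeats: int = 2) -> list[PogoFinding]:
    """Find maximal alternating runs with >= min_repeats visits to each member.

    A run over positions i..j alternates between exactly two keys
    (``s[k] == s[k+2]``, ``s[k] != s[k+1]``) and cannot be extended either
    way.  The covering time window spans the run's first and last segments.
    """
    if min_repeats < 1:
        raise ValueError("min_repeats must be >= 1")
    keys = _alternation_keys(session)
    n = len(keys)
    findings: list[PogoFinding] = []
    i = 0
    while i < n - 1:
        if keys[i] == keys[i + 1]:
            i += 1
            continue
        j = i + 1
        while j + 1 < n and keys[j + 1] == keys[j - 1]:
            j += 1
        run_len = j - i + 1
        if run_len >= 3:
            count_a = (run_len + 1) // 2
            count_b = run_len // 2
            if min(count_a, count_b) >= min_repeats:
                segs = session.segments[i : j + 1]
                findings.append(
                    PogoFinding(
                        pair=(keys[i], keys[i + 1]),
                        counts=(count_a, count_b),
                        window_start_s=segs[0].start_s,
                        window_end_s=segs[-1].end_s,
                        time_in_window_s=sum(s.duration_s for s in segs),
                    )
                )
        # the run's last element may start a new alternation with a new partner
        i = j if run_len >= 3 else i + 1
    return findings


def suggest_juxtapositions(
    findings: Sequence[PogoFinding],
) -> list[dict]:
    """Rank pogo pairs by recoverable time (largest alternation window first)."""
    merged: dict[tuple[str, str], float] = {}
    for f in findings:
        key = tuple(sorted(f.pair))
        merged[key] = merged.get(key, 0.0) + f.time_in_window_s
    ranked = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        {
            "juxtapose": list(pair),
            "recoverable_window_s": seconds,
            "rationale": "co-displaying these two elements removes the "
            "repeated back-and-forth navigation between them",
        }
        for pair, seconds in ranked
    ]


def build_report(
    trees: Sequence[NavTree] = (),
    sessions: Sequence[Session] = (),
    routing: RoutingPolicy = "reasonable_maximum",
    multiplier: MultiplierPolicy = MultiplierPolicy(),
    min_repeats: int = 2,
    sunburst_weighting: str = "leaf_weighted",
) -> dict:
    """Assemble the full comparison bundle as a JSON-serializable dict.

    Every number in the bundle is the value returned by the underlying
    operation — nothing is recomputed by the report layer.
    """
    if len(trees) > 2:
        raise ValueError("at most 2 trees are compared")
    if not trees and not sessions:
        raise EmptyReportError("need at least one tree or one session")

    bundle: dict = {"figures": {}}

    if trees:
        dfi_section: dict = {"systems": []}
        breakdowns = []
        for i, tree in enumerate(trees):
            targets = [n.id for n in tree.iter_preorder() if n.is_target]
            pathway = trace_pathway(tree, targets, routing=routing)
            tally = tally_actions(pathway, tree)
            bd = compute_dfi(tally, multiplier)
            breakdowns.append(bd)
            dfi_section["systems"].append(
                {
                    "index": i,
                    "n_nodes": len(tree),
                    "n_targets": len(targets),
                    "summary": bd.summary_line(),
                    **bd.to_dict(),
                }
            )
            segments = layout_sunburst(tree, weighting=sunburst_weighting)
            segments = highlight_pathway(segments, pathway)
            bundle["figures"][f"sunburst_{i}"] = render_sunburst(segments)
        if len(breakdowns) == 2:
            dfi_section["comparison"] = compare_systems(*breakdowns).to_dict()
        bundle["dfi"] = dfi_section

    if sessions:
        tasks_section = []
        pogo_section = []
        for session in sessions:
            tasks_section.append(
                {
                    "session_id": session.session_id,
                    "total_time_s": session.total_time_s,
                    "tasks": [t.to_dict() for t in task_summary(session)],
                }
            )
            findings = detect_pogo_sticking(session, min_repeats=min_repeats)
            pogo_section.append(
                {
                    "session_id": session.session_id,
                    "findings": [f.to_dict() for f in findings],
                    "suggestions": suggest_juxtapositions(findings),
                }
            )
        bundle["tasks"] = tasks_section
        bundle["pogo"] = pogo_section
        rows, legend = layout_timebelt(list(sessions))
        bundle["figures"]["timebelt"] = render_timebelt(rows, legend)

    return bundle


def render_html(bundle: Mapping) -> str:
    """Single-page HTML wrapper around the bundle (figures inlined)."""
    parts = [
        "<!DOCTYPE html>",
        '<html><head><meta charset="utf-8"><title>Fragmentation report</title>',
        "<style>body{font-family:sans-serif;max-width:70em;margin:2em auto}"
        "pre{background:#f6f6f6;padding:1em;overflow-x:auto}</style></head><body>",
        "<h1>Display and task fragmentation report</h1>",
    ]
    if "dfi" in bundle:
        parts.append("<h2>Display Fragmentation Index</h2>")
        for system in bundle["dfi"]["systems"]:
            parts.append(f"<p><code>{_svg.escape(system['summary'])}</code></p>")
        if "comparison" in bundle["dfi"]:
            ratio = bundle["dfi"]["comparison"]["ratio"]
            if ratio is not None:
                parts.append(f"<p>Ratio of totals (system 1 / system 0): {ratio:.3f}</p>")
    if "tasks" in bundle:
        parts.append("<h2>Task metrics (ACT / PPI)</h2><pre>")
        parts.append(_svg.escape(json.dumps(bundle["tasks"], indent=2)))
        parts.append("</pre>")
    if "pogo" in bundle:
        parts.append("<h2>Pogo-sticking</h2><pre>")
        parts.append(_svg.escape(json.dumps(bundle["pogo"], indent=2)))
        parts.append("</pre>")
    for name in sorted(bundle.get("figures", {})):
        parts.append(f"<h2>{_svg.escape(name)}</h2>")
        parts.append(bundle["figures"][name])
    parts.append("</body></html>")
    return "\n".join(parts)


def write_report(bundle: Mapping, out_dir) -> None:
    """Write report.json, report.html and the SVG figures under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    serializable = {k: v for k, v in bundle.items() if k != "figures"}
    serializable["figures"] = sorted(bundle.get("figures", {}))
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(serializable, fh, indent=2)
        fh.write("\n")
    with open(out / "report.html", "w", encoding="utf-8") as fh:
        fh.write(render_html(bundle))
    for name, svg in bundle.get("figures", {}).items():
        with open(out / f"{name}.svg", "w", encoding="utf-8") as fh:
            fh.write(svg)
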