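"""Minimal deterministic SVG 1.1 string builder.

Rendering here is intentionally dependency-free and byte-stable: the same
layout always produces the identical document, which makes figure output
diffable and testable.
"""

from __future__ import annotations

import math

#: fixed qualitative palette (tab20-style), cycled when labels exceed it
QUALITATIVE_PALETTE = (
    "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c",
    "#98df8a", "#d62728", "#ff9896", "#9467bd", "#c5b0d5",
    "#8c564b", "#c49c94", "#e377c2", "#f7b6d2", "#7f7f7f",
    "#c7c7c7", "#bcbd22", "#dbdb8d", "#17becf", "#9edae5",
)


def fmt(x: float) -> str:
    """Fixed-precision coordinate formatting (4 decimals, no trailing zeros)."""
    s = f"{x:.4f}".rstrip("0").rstrip(".")
    return "0" if s == "-0" else s


def escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def document(width: float, height: float, body: list[str]) -> str:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{fmt(width)}" height="{fmt(height)}" '
        f'viewBox="0 0 {fmt(width)} {fmt(height)}">\n'
    )
    return head + "\n".join(body) + "\n</svg>\n"


def rect(x: float, y: float, w: float, h: float, fill: str, **attrs: str) -> str:
    extra = "".join(f' {k.replace("_", "-")}="{v}"' for k, v in attrs.items())
    return (
        f'<rect x="{fmt(x)}" y="{fmt(y)}" width="{fmt(w)}" height="{fmt(h)}" '
        f'fill="{fill}"{extra}/>'
    )


def circle(cx: float, cy: float, r: float, fill: str, **attrs: str) -> str:
    extra = "".join(f' {k.replace("_", "-")}="{v}"' for k, v in attrs.items())
    return f'<circle cx="{fmt(cx)}" cy="{fmt(cy)}" r="{fmt(r)}" fill="{fill}"{extra}/>'


def text(x: float, y: float, content: str, size: float = 12, **attrs: str) -> str:
    extra = "".join(f' {k.replace("_", "-")}="{v}"' for k, v in attrs.items())
    return (
        f'<text x="{fmt(x)}" y="{fmt(y)}" font-size="{fmt(size)}" '
        f'font-family="sans-serif"{extra}>{escape(content)}</text>'
    )


def _polar(cx: float, cy: float, r: float, angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return cx + r * math.cos(a), cy - r * math.sin(a)


def annular_sector(
    cx: float,
    cy: float,
    r_inner: float,
    r_outer: float,
    start_deg: float,
    end_deg: float,
    fill: str,
    **attrs: str,
) -> str:
    """Path for the annular sector between two radii and two angles.

    A full-turn extent is drawn as a ring of two semicircular arcs
    (a single 360-degree arc would collapse to nothing).
    """
    extra = "".join(f' {k.replace("_", "-")}="{v}"' for k, v in attrs.items())
    extent = end_deg - start_deg
    if extent >= 360:
        d_parts = []
        for r in (r_outer, r_inner):
            x0, y0 = _polar(cx, cy, r, 0)
            x1, y1 = _polar(cx, cy, r, 180)
            d_parts.append(
                f"M {fmt(x0)} {fmt(y0)} "
                f"A {fmt(r)} {fmt(r)} 0 1 1 {fmt(x1)} {fmt(y1)} "
                f"A {fmt(r)} {fmt(r)} 0 1 1 {fmt(x0)} {fmt(y0)} Z"
            )
        d = " ".join(d_parts)
        return f'<path d="{d}" fill="{fill}" fill-rule="evenodd"{extra}/>'
    large = 1 if extent > 180 else 0
    x0, y0 = _polar(cx, cy, r_outer, start_deg)
    x1, y1 = _polar(cx, cy, r_outer, end_deg)
    x2, y2 = _polar(cx, cy, r_inner, end_deg)
    x3, y3 = _polar(cx, cy, r_inner, start_deg)
    d = (
        f"M {fmt(x0)} {fmt(y0)} "
        f"A {fmt(r_outer)} {fmt(r_outer)} 0 {large} 0 {fmt(x1)} {fmt(y1)} "
        f"L {fmt(x2)} {fmt(y2)} "
        f"A {fmt(r_inner)} {fmt(r_inner)} 0 {large} 1 {fmt(x3)} {fmt(y3)} Z"
    )
    return f'<path d="{d}" fill="{fill}"{extra}/>'
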