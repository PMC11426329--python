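"""2D rendering of structural profiles as SVG.

Each profile column is drawn as a cluster of circles (one per nucleotide
symbol present, plus the gap symbol), with radius growing with frequency;
each surviving base-pair entry is drawn as an edge whose width grows with
frequency, and the nucleotide circles participating in an interaction are
highlighted with a circular outline.  Hairpins and internal loops are laid
out on strand rows; profiles with three or more strands are laid out in a
circular orientation.

Display filtering keeps the image readable: base-pair entries and
nucleotides observed in fewer than ``min_interaction_frac`` of the
instances are dropped, mostly-gap columns (gap fraction above
``max_gap_frac``) are dropped unless they participate in a surviving
interaction, and stackings are never drawn (they remain in the .pfl text).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .profile import GAP, Profile

__all__ = ["RenderSpec", "ProfileView", "filter_for_display", "render", "render_text"]


@dataclass(frozen=True)
class RenderSpec:
    min_interaction_frac: float = 0.10
    max_gap_frac: float = 0.75
    min_radius: float = 3.0
    max_radius: float = 11.0
    min_edge_width: float = 0.6
    max_edge_width: float = 4.5
    spacing: float = 46.0

    def __post_init__(self) -> None:
        for f in (self.min_interaction_frac, self.max_gap_frac):
            if not 0.0 <= f <= 1.0:
                raise ValueError("display fractions must lie in [0, 1]")


@dataclass
class ProfileView:
    """A display-filtered projection of a profile (not a valid Profile:
    column sums are no longer conserved)."""

    columns: list[dict[str, int]]
    bp: dict[tuple[int, int], dict[tuple[str, str], int]]
    kept: list[bool]
    break_points: list[int]
    mc: int
    stk: dict = field(default_factory=dict)  # always empty; stackings are never drawn


def filter_for_display(p: Profile | ProfileView, spec: RenderSpec = RenderSpec()) -> ProfileView:
    """Apply the display thresholds; idempotent on its own output."""
    mc = p.mc
    thr = spec.min_interaction_frac
    bp = {
        cell: kept_entries
        for cell, entries in p.bp.items()
        if (kept_entries := {k: c for k, c in entries.items() if c / mc >= thr})
    }
    participating: set[int] = set()
    for i, j in bp:
        participating.update((i, j))
    columns = [{k: c for k, c in col.items() if c / mc >= thr} for col in p.columns]
    kept = []
    for idx, col in enumerate(p.columns, start=1):
        gap_frac = col.get(GAP, 0) / mc
        kept.append(gap_frac <= spec.max_gap_frac or idx in participating)
    return ProfileView(
        columns=columns, bp=bp, kept=kept, break_points=list(p.break_points), mc=mc
    )


# ---------------------------------------------------------------------------
# Geometry


def _column_anchors(view: ProfileView, spec: RenderSpec) -> dict[int, tuple[float, float]]:
    bounds = []
    start = 1
    for b in view.break_points:
        bounds.append((start, b))
        start = b + 1
    anchors: dict[int, tuple[float, float]] = {}
    margin = 40.0
    if len(bounds) <= 2:
        for row, (a, b) in enumerate(bounds):
            y = margin + row * 110.0
            positions = list(range(a, b + 1))
            if row == 1:  # second strand runs antiparallel
                positions = positions[::-1]
            for k, pos in enumerate(positions):
                anchors[pos] = (margin + k * spec.spacing, y)
    else:
        n = len(view.columns)
        radius = max(90.0, n * spec.spacing / (2 * math.pi))
        cx = cy = margin + radius
        for pos in range(1, n + 1):
            theta = 2 * math.pi * (pos - 1) / n - math.pi / 2
            anchors[pos] = (cx + radius * math.cos(theta), cy + radius * math.sin(theta))
    return anchors


_NT_FILL = {"A": "#e45756", "C": "#4c78a8", "G": "#54a24b", "U": "#eeca3b", GAP: "#bbbbbb"}
_GLYPH_OFFSETS = [(0.0, 0.0), (13.0, -7.0), (13.0, 7.0), (-13.0, 7.0), (-13.0, -7.0)]


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_text(view: ProfileView, spec: RenderSpec = RenderSpec()) -> str:
    """Deterministic SVG text for a filtered profile view."""
    anchors = _column_anchors(view, spec)
    mc = view.mc

    def radius(count: int) -> float:
        return spec.min_radius + (spec.max_radius - spec.min_radius) * count / mc

    def width(count: int) -> float:
        return spec.min_edge_width + (spec.max_edge_width - spec.min_edge_width) * count / mc

    outlined: set[tuple[int, str]] = set()
    edge_elems: list[str] = []
    for (i, j) in sorted(view.bp):
        if not (view.kept[i - 1] and view.kept[j - 1]):
            continue
        (x1, y1), (x2, y2) = anchors[i], anchors[j]
        entries = sorted(view.bp[(i, j)].items(), key=lambda kv: (-kv[1], kv[0]))
        for k, ((lw, pair), count) in enumerate(entries):
            off = (k - (len(entries) - 1) / 2) * 3.0
            edge_elems.append(
                f'<line x1="{_fmt(x1)}" y1="{_fmt(y1 + off)}" x2="{_fmt(x2)}" y2="{_fmt(y2 + off)}" '
                f'stroke="#2e7d32" stroke-width="{_fmt(width(count))}">'
                f"<title>{i}-{j} {lw}({pair}):{count}</title></line>"
            )
            nt5, nt3 = pair.split("-")
            outlined.add((i, nt5))
            outlined.add((j, nt3))

    node_elems: list[str] = []
    for idx, col in enumerate(view.columns, start=1):
        if not view.kept[idx - 1]:
            continue
        cx, cy = anchors[idx]
        entries = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
        for k, (sym, count) in enumerate(entries[: len(_GLYPH_OFFSETS)]):
            dx, dy = _GLYPH_OFFSETS[k]
            extra = (
                ' stroke="#222222" stroke-width="1.2"' if (idx, sym) in outlined else ""
            )
            node_elems.append(
                f'<circle cx="{_fmt(cx + dx)}" cy="{_fmt(cy + dy)}" r="{_fmt(radius(count))}" '
                f'fill="{_NT_FILL.get(sym, "#888888")}"{extra}>'
                f"<title>col {idx} {sym}:{count}</title></circle>"
            )
            node_elems.append(
                f'<text x="{_fmt(cx + dx)}" y="{_fmt(cy + dy + 2.5)}" font-size="7" '
                f'text-anchor="middle" font-family="monospace">{sym}</text>'
            )

    xs = [a[0] for a in anchors.values()]
    ys = [a[1] for a in anchors.values()]
    w, h = max(xs) + 60.0, max(ys) + 60.0
    body = "\n".join(edge_elems + node_elems)
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(w)}" height="{_fmt(h)}" '
        f'viewBox="0 0 {_fmt(w)} {_fmt(h)}">\n{body}\n</svg>\n'
    )


def render(view: ProfileView, path, spec: RenderSpec = RenderSpec()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(render_text(view, spec))
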