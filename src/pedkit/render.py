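"""Pedigree drawing, step 2: layout -> plot elements -> SVG.

Symbols follow the standard pedigree conventions (Pedigree Standardization
Task Force): square = male, circle = female, diamond = unknown sex, a
diagonal slash = deceased, an arrow with "P" = proband, and the symbol area
divided into equal angular sectors — one per displayed affection — filled
according to the affection's colour scale.  Border colour encodes sample
availability.  Mating lines are horizontal between mates on the same level
and routed when a cross-generational mating was drawn with spouse-alignment
bypassed; duplicated copies of a loop-breaking individual are joined by a
dotted line.

The SVG output is byte-deterministic for a fixed input and option set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, pi, sin
from typing import Optional

import pandas as pd

from .layout import LayoutTable
from .model import Pedigree, RelCode, Sex, Status
from .scales import BORDER_AVAILABLE, BORDER_UNAVAILABLE

__all__ = ["Symbol", "Connector", "PlotElements",
           "build_plot_elements", "render_svg"]

#: vertical distance between generations, in symbol-width units
ROW_HEIGHT = 2.0
#: symbol half-width in the same units (gap between neighbours is >= 1)
HALF = 0.35


@dataclass
class Symbol:
    x: float
    y: float
    shape: str                      # square | circle | diamond
    fill_sectors: list              # one colour per displayed affection
    border_color: str
    dead: bool
    proband: bool
    label: str
    annotations: list = field(default_factory=list)
    dup_group: Optional[str] = None


@dataclass
class Connector:
    kind: str    # mating | offspring-drop | sibship-bar | twin-fork |
    #              MZ-bar | duplicate-dotted
    points: list                     # [(x, y), ...] polyline
    dashed: bool = False


@dataclass
class PlotElements:
    symbols: list
    connectors: list
    width: float
    height: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "x": s.x, "y": s.y, "shape": s.shape,
            "fills": ";".join(s.fill_sectors), "border": s.border_color,
            "dead": s.dead, "proband": s.proband, "label": s.label,
            "dup_group": s.dup_group or "",
        } for s in self.symbols])


_SHAPES = {Sex.MALE: "square", Sex.FEMALE: "circle", Sex.UNKNOWN: "diamond"}


def build_plot_elements(layout: LayoutTable, pedigree: Pedigree,
                        scales: Optional[dict] = None,
                        display_affections: Optional[list] = None,
                        annotate: bool = True) -> PlotElements:
    """Assemble every drawable element from a layout and its pedigree.

    ``scales`` maps affection column index -> :class:`FillScale`
    (defaults to the pedigree's own scales slot); ``display_affections``
    selects which columns are shown (default: every column with a scale,
    else none).  A displayed affection without a scale is an error.
    """
    if scales is None:
        scales = pedigree.scales
    if display_affections is None:
        display_affections = sorted(scales)
    missing = [i for i in display_affections if i not in scales]
    if missing:
        raise ValueError(f"no fill scale for displayed affection "
                         f"column(s) {missing}")

    symbols = []
    for entry in layout.entries:
        rec = pedigree[entry.key]
        fills = []
        for idx in display_affections:
            value = rec.affections[idx] if idx < len(rec.affections) else None
            fills.append(scales[idx].color_for(value))
        annotations = []
        if annotate:
            annotations.append(f"id: {rec.id} (family {rec.famid})")
            annotations.append(f"sex: {rec.sex.value}")
            for k, idx in enumerate(display_affections):
                value = rec.affections[idx] if idx < len(rec.affections) else None
                annotations.append(
                    f"affection {idx}: "
                    + ("missing" if value is None else f"{value:g}"))
        symbols.append(Symbol(
            x=entry.x, y=entry.generation * ROW_HEIGHT,
            shape=_SHAPES[rec.sex], fill_sectors=fills,
            border_color=BORDER_AVAILABLE if rec.avail else BORDER_UNAVAILABLE,
            dead=rec.status is Status.DEAD, proband=rec.proband,
            label=rec.id, annotations=annotations,
            dup_group=entry.dup_group))

    twin_pairs = {}
    for rel in pedigree.relationships:
        if rel.code in (RelCode.MZ_TWIN, RelCode.DZ_TWIN, RelCode.UZ_TWIN):
            a, b = (rel.famid, rel.id1), (rel.famid, rel.id2)
            twin_pairs[frozenset((a, b))] = rel.code

    connectors = []
    for union in layout.unions:
        dad = layout.entries[union.dad_entry]
        mom = layout.entries[union.mom_entry]
        dy, my = dad.generation * ROW_HEIGHT, mom.generation * ROW_HEIGHT
        left, right = sorted((dad, mom), key=lambda e: e.x)
        if union.same_generation:
            connectors.append(Connector("mating", [
                (left.x + HALF, dy), (right.x - HALF, dy)]))
            mid_x, drop_y = 0.5 * (dad.x + mom.x), dy
        else:
            # routed mating line for a bypassed cross-generational union
            mid_x = 0.5 * (dad.x + mom.x)
            ly = dy if left is dad else my
            ry = my if left is dad else dy
            connectors.append(Connector("mating", [
                (left.x + HALF, ly), (mid_x, ly), (mid_x, ry),
                (right.x - HALF, ry)]))
            drop_y = max(dy, my)
        children = [layout.entries[c] for c in union.children_entries]
        if not children:
            continue
        child_y = children[0].generation * ROW_HEIGHT
        bar_y = child_y - 0.7
        top_y = child_y - HALF
        if len(children) == 1:
            c = children[0]
            connectors.append(Connector("offspring-drop", [
                (mid_x, drop_y), (mid_x, bar_y), (c.x, bar_y), (c.x, top_y)]))
            continue
        xs = sorted(c.x for c in children)
        connectors.append(Connector("offspring-drop", [
            (mid_x, drop_y), (mid_x, bar_y)]))
        connectors.append(Connector("sibship-bar", [
            (xs[0], bar_y), (xs[-1], bar_y)]))
        handled = set()
        for i, c in enumerate(children):
            if i in handled:
                continue
            partner = None
            for j in range(i + 1, len(children)):
                code = twin_pairs.get(frozenset((c.key, children[j].key)))
                if code is not None:
                    partner = (j, code)
                    break
            if partner is None:
                connectors.append(Connector("offspring-drop", [
                    (c.x, bar_y), (c.x, top_y)]))
                continue
            j, code = partner
            handled.add(j)
            t = children[j]
            apex = 0.5 * (c.x + t.x)
            connectors.append(Connector("twin-fork", [
                (c.x, top_y), (apex, bar_y), (t.x, top_y)]))
            if code is RelCode.MZ_TWIN:
                mid = 0.5
                connectors.append(Connector("MZ-bar", [
                    (apex + (c.x - apex) * mid, bar_y + (top_y - bar_y) * mid),
                    (apex + (t.x - apex) * mid, bar_y + (top_y - bar_y) * mid)]))

    # dotted links between copies of a duplicated individual
    groups: dict = {}
    for s in symbols:
        if s.dup_group:
            groups.setdefault(s.dup_group, []).append(s)
    for group in sorted(groups):
        members = sorted(groups[group], key=lambda s: (s.y, s.x))
        for a, b in zip(members, members[1:]):
            connectors.append(Connector("duplicate-dotted", [
                (a.x, a.y - HALF - 0.1), (a.x, a.y - HALF - 0.25),
                (b.x, b.y - HALF - 0.25), (b.x, b.y - HALF - 0.1)],
                dashed=True))

    width = max((s.x for s in symbols), default=0.0) + 2 * HALF + 1.0
    height = max((s.y for s in symbols), default=0.0) + 2 * HALF + 1.0
    return PlotElements(symbols=symbols, connectors=connectors,
                        width=width, height=height)


# ---------------------------------------------------------------------------
# SVG generation

def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _sector_path(cx, cy, r, start_frac, end_frac) -> str:
    """Pie-wedge path from the top, clockwise, in fractions of a turn."""
    a0 = -pi / 2 + 2 * pi * start_frac
    a1 = -pi / 2 + 2 * pi * end_frac
    x0, y0 = cx + r * cos(a0), cy + r * sin(a0)
    x1, y1 = cx + r * cos(a1), cy + r * sin(a1)
    large = 1 if (end_frac - start_frac) > 0.5 else 0
    return (f"M {_fmt(cx)} {_fmt(cy)} L {_fmt(x0)} {_fmt(y0)} "
            f"A {_fmt(r)} {_fmt(r)} 0 {large} 1 {_fmt(x1)} {_fmt(y1)} Z")


def _shape_outline(shape: str, cx, cy, h) -> str:
    if shape == "square":
        return (f'<rect class="outline" x="{_fmt(cx - h)}" y="{_fmt(cy - h)}" '
                f'width="{_fmt(2 * h)}" height="{_fmt(2 * h)}"/>')
    if shape == "circle":
        return (f'<circle class="outline" cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
                f'r="{_fmt(h)}"/>')
    pts = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in
                   [(cx, cy - h), (cx + h, cy), (cx, cy + h), (cx - h, cy)])
    return f'<polygon class="outline" points="{pts}"/>'


def render_svg(elements: PlotElements, path=None, scale: float = 40.0,
               font_size: float = 10.0) -> str:
    """Serialize plot elements to SVG 1.1; returns the document text.

    Byte-deterministic for fixed inputs and options.  When ``path`` is
    given the document is also written there (UTF-8, "\\n" newlines).
    """
    margin = scale
    width = elements.width * scale + 2 * margin
    height = elements.height * scale + 2 * margin

    def X(v):
        return v * scale + margin + HALF * scale

    def Y(v):
        return v * scale + margin + HALF * scale

    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
        '<style>.outline{fill:none}'
        '.connector{stroke:#000000;fill:none;stroke-width:1.2}'
        '.connector.dashed{stroke-dasharray:4 3}'
        '.slash{stroke:#000000;stroke-width:1.4}'
        '.proband-arrow{stroke:#000000;stroke-width:1.4;fill:none}'
        f'text{{font-family:sans-serif;font-size:{_fmt(font_size)}px;'
        'text-anchor:middle}</style>',
    ]

    for conn in elements.connectors:
        pts = " ".join(f"{_fmt(X(x))},{_fmt(Y(y))}" for x, y in conn.points)
        cls = f"connector {conn.kind}" + (" dashed" if conn.dashed else "")
        out.append(f'<polyline class="{cls}" points="{pts}"/>')

    r = HALF * scale
    for i, sym in enumerate(elements.symbols):
        cx, cy = X(sym.x), Y(sym.y)
        parts = [f'<g class="symbol shape-{sym.shape}">']
        clip_id = f"clip{i}"
        outline = _shape_outline(sym.shape, cx, cy, r)
        parts.append(f'<clipPath id="{clip_id}">{outline}</clipPath>')
        n = len(sym.fill_sectors)
        if n == 0:
            parts.append(f'<g clip-path="url(#{clip_id})">'
                         f'<rect class="fill-sector" x="{_fmt(cx - r)}" '
                         f'y="{_fmt(cy - r)}" width="{_fmt(2 * r)}" '
                         f'height="{_fmt(2 * r)}" fill="#ffffff"/></g>')
        else:
            sectors = []
            for k, color in enumerate(sym.fill_sectors):
                if n == 1:
                    sectors.append(
                        f'<rect class="fill-sector" x="{_fmt(cx - r)}" '
                        f'y="{_fmt(cy - r)}" width="{_fmt(2 * r)}" '
                        f'height="{_fmt(2 * r)}" fill="{color}"/>')
                else:
                    d = _sector_path(cx, cy, 1.5 * r, k / n, (k + 1) / n)
                    sectors.append(f'<path class="fill-sector" d="{d}" '
                                   f'fill="{color}"/>')
            parts.append(f'<g clip-path="url(#{clip_id})">'
                         + "".join(sectors) + "</g>")
        stroked = outline.replace(
            'class="outline"',
            f'class="outline" stroke="{sym.border_color}" stroke-width="1.5"')
        parts.append(stroked)
        if sym.dead:
            parts.append(f'<line class="slash" '
                         f'x1="{_fmt(cx - 1.3 * r)}" y1="{_fmt(cy + 1.3 * r)}" '
                         f'x2="{_fmt(cx + 1.3 * r)}" y2="{_fmt(cy - 1.3 * r)}"/>')
        if sym.proband:
            ax, ay = cx - 1.9 * r, cy + 1.9 * r
            parts.append(
                f'<path class="proband-arrow" d="M {_fmt(ax)} {_fmt(ay)} '
                f'L {_fmt(cx - 1.1 * r)} {_fmt(cy + 1.1 * r)} '
                f'M {_fmt(cx - 1.1 * r)} {_fmt(cy + 1.1 * r)} '
                f'l -6.00 1.50 M {_fmt(cx - 1.1 * r)} {_fmt(cy + 1.1 * r)} '
                f'l -1.50 6.00"/>')
            parts.append(f'<text class="proband-label" x="{_fmt(ax - 4)}" '
                         f'y="{_fmt(ay + 8)}">P</text>')
        parts.append(f'<text class="id-label" x="{_fmt(cx)}" '
                     f'y="{_fmt(cy + r + font_size + 2)}">{sym.label}</text>')
        if sym.annotations:
            title = "&#10;".join(sym.annotations)
            parts.append(f"<title>{title}</title>")
        parts.append("</g>")
        out.append("".join(parts))

    out.append("</svg>")
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    return text
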