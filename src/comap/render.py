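"""Scene construction and deterministic SVG output.

A :class:`Scene` is a flat list of drawable primitives — axis segments,
ticks, marker glyphs, strand triangles, label texts, link lines and
legend entries — each carrying the identifier of the model object it
came from (map id, marker name, link type).  That traceability is what
the parse-back tests rely on: counting SVG elements by their
``data-*`` attributes must reproduce the scene tally exactly.

Rendering is byte-deterministic: the same scene always serialises to
the identical SVG document.
"""

from __future__ import annotations

import math
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .layout import (
    Canvas,
    OutOfViewError,
    Placement,
    adjacent_pairs,
    compute_columns,
    place_labels,
    to_canvas_y,
)
from .model import GenomeMap
from .relations import Link, link_color

__all__ = [
    "Scene",
    "AxisLine",
    "TickMark",
    "MarkerGlyph",
    "RangeBar",
    "StrandGlyph",
    "LabelText",
    "LinkLine",
    "LegendEntry",
    "NonAdjacentLinkError",
    "build_scene",
    "render_svg",
    "axis_ticks",
]

AXIS_COLOR = "#CC0000"  # maps draw as a scaled red axis
TEXT_COLOR = "#000000"


class NonAdjacentLinkError(ValueError):
    """A link was supplied between maps not in adjacent columns."""


@dataclass(frozen=True)
class AxisLine:
    map_id: str
    x: float
    y_top: float
    y_bottom: float


@dataclass(frozen=True)
class TickMark:
    map_id: str
    value: float
    x: float
    y: float
    text: str


@dataclass(frozen=True)
class MarkerGlyph:
    map_id: str
    marker_name: str
    x: float
    y: float


@dataclass(frozen=True)
class RangeBar:
    map_id: str
    marker_name: str
    x: float
    y_top: float
    y_bottom: float


@dataclass(frozen=True)
class StrandGlyph:
    map_id: str
    marker_name: str
    x: float
    y: float
    direction: str  # "up" (forward) | "down" (reverse)


@dataclass(frozen=True)
class LabelText:
    map_id: str
    marker_name: str
    x: float
    y: float
    text: str


@dataclass(frozen=True)
class LinkLine:
    link_type: str
    map_a: str
    marker_a: str
    x1: float
    y1: float
    x2: float
    y2: float
    map_b: str
    marker_b: str
    color: str


@dataclass(frozen=True)
class LegendEntry:
    link_type: str
    color: str


@dataclass
class Scene:
    axes: list[AxisLine] = field(default_factory=list)
    ticks: list[TickMark] = field(default_factory=list)
    marker_glyphs: list[MarkerGlyph] = field(default_factory=list)
    range_bars: list[RangeBar] = field(default_factory=list)
    strand_glyphs: list[StrandGlyph] = field(default_factory=list)
    labels: list[LabelText] = field(default_factory=list)
    link_lines: list[LinkLine] = field(default_factory=list)
    legend: list[LegendEntry] = field(default_factory=list)
    width: float = 0.0
    height: float = 0.0


def axis_ticks(view_start: float, view_end: float) -> list[float]:
    """Round-number tick values: largest 1/2/5 x 10^k step giving 4-10
    ticks inside the view window."""
    span = view_end - view_start
    if span <= 0:
        return []
    best = None
    k = math.floor(math.log10(span))
    for exp in (k + 1, k, k - 1, k - 2):
        for mult in (5.0, 2.0, 1.0):
            step = mult * 10.0 ** exp
            first = math.ceil(view_start / step) * step
            count = 0
            v = first
            while v <= view_end + step * 1e-9:
                count += 1
                v += step
            if 4 <= count <= 10:
                return [first + i * step for i in range(count)]
            if best is None and count >= 2:
                best = [first + i * step for i in range(count)]
    return best or [view_start, view_end]


def _fmt_tick(v: float) -> str:
    return f"{v:g}"


def build_scene(
    canvas: Canvas,
    maps: dict[str, GenomeMap],
    links: Sequence[Link] = (),
    palette: Optional[dict] = None,
) -> Scene:
    """Turn a canvas + maps + links into drawable primitives.

    Per visible map: one red axis spanning the placement height, tick
    labels at round intervals of the view window, point markers as
    ticks, range markers as side bars, strand glyphs as up/down
    triangles, and labels per the placement's label mode.  Per link: a
    straight line between endpoint canvas positions, coloured by type;
    links with an out-of-view endpoint are omitted.  Links between maps
    not in adjacent columns are a contract violation.
    """
    palette = dict(canvas.style.get("palette", {})) | dict(palette or {})
    columns = compute_columns(canvas)
    allowed = set()
    for a, b in adjacent_pairs(canvas):
        allowed.add(frozenset((a, b)))

    column_order = {m: i for i, col in enumerate(columns) for m in col}
    visible = sorted(
        (p for p in canvas.placements if p.visible),
        key=lambda p: (column_order.get(p.map_id, 1 << 30), p.x, p.map_id),
    )

    scene = Scene()
    linked_names: dict[str, set[str]] = {}
    for link in links:
        linked_names.setdefault(link.map_a, set()).add(link.marker_a.name)
        linked_names.setdefault(link.map_b, set()).add(link.marker_b.name)

    for p in visible:
        gmap = maps.get(p.map_id)
        if gmap is None:
            raise KeyError(f"no map supplied for placement {p.map_id!r}")
        axis_x = p.x + 0.35 * p.width
        scene.axes.append(AxisLine(p.map_id, axis_x, p.y, p.y + p.height))
        for value in axis_ticks(p.view_start, p.view_end):
            try:
                y = to_canvas_y(p, value)
            except OutOfViewError:
                continue
            scene.ticks.append(
                TickMark(p.map_id, value, axis_x, y, _fmt_tick(value))
            )
        in_view = [
            m for m in gmap.markers
            if m.end >= p.view_start and m.start <= p.view_end
        ]
        for m in in_view:
            mid = min(max(m.midpoint, p.view_start), p.view_end)
            y = to_canvas_y(p, mid)
            if m.is_point:
                scene.marker_glyphs.append(MarkerGlyph(p.map_id, m.name, axis_x, y))
            else:
                top = to_canvas_y(p, max(min(m.start, p.view_end), p.view_start))
                bot = to_canvas_y(p, max(min(m.end, p.view_end), p.view_start))
                y_top, y_bot = min(top, bot), max(top, bot)
                scene.range_bars.append(
                    RangeBar(p.map_id, m.name, axis_x - 5.0, y_top, y_bot)
                )
            if m.strand == "forward":
                scene.strand_glyphs.append(
                    StrandGlyph(p.map_id, m.name, axis_x + 4.0, y, "up")
                )
            elif m.strand == "reverse":
                scene.strand_glyphs.append(
                    StrandGlyph(p.map_id, m.name, axis_x + 4.0, y, "down")
                )
        boxes, _dropped = place_labels(
            p, in_view, linked_names.get(p.map_id, set())
        )
        for box in boxes:
            scene.labels.append(
                LabelText(p.map_id, box.marker_name, box.x,
                          box.y + box.height * 0.8, box.marker_name)
            )

    seen_types = set()
    for link in links:
        pair = frozenset((link.map_a, link.map_b))
        if pair not in allowed:
            raise NonAdjacentLinkError(
                f"link {link.marker_a.name!r}-{link.marker_b.name!r} joins maps "
                f"{link.map_a!r} and {link.map_b!r} which are not in adjacent "
                f"columns"
            )
        pa = canvas.placement(link.map_a)
        pb = canvas.placement(link.map_b)
        ma, mb = link.marker_a, link.marker_b
        if not (pa.in_view(ma.midpoint) and pb.in_view(mb.midpoint)):
            continue  # clipped: out-of-view endpoint
        xa = pa.x + 0.35 * pa.width
        xb = pb.x + 0.35 * pb.width
        color = link_color(link.link_type, palette)
        scene.link_lines.append(
            LinkLine(
                link.link_type,
                link.map_a, ma.name, xa, to_canvas_y(pa, ma.midpoint),
                xb, to_canvas_y(pb, mb.midpoint), link.map_b, mb.name,
                color,
            )
        )
        seen_types.add(link.link_type)

    from .relations import LINK_TYPES

    for lt in LINK_TYPES:  # legend lists only the link types present
        if lt in seen_types:
            scene.legend.append(LegendEntry(lt, link_color(lt, palette)))

    if visible:
        scene.width = max(p.x + p.width for p in visible) + 160.0
        scene.height = max(p.y + p.height for p in visible) + 40.0
        scene.height += 18.0 * len(scene.legend) + 20.0
    else:
        scene.width, scene.height = 200.0, 100.0
    return scene


# ---------------------------------------------------------------------------
# SVG serialisation
# ---------------------------------------------------------------------------

def _f(v: float) -> str:
    return f"{v:.3f}".rstrip("0").rstrip(".")


def scene_to_svg(scene: Scene) -> str:
    """Serialise a scene to an SVG 1.1 document string (deterministic)."""
    root = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": _f(scene.width),
            "height": _f(scene.height),
        },
    )
    ET.SubElement(
        root, "rect",
        {"x": "0", "y": "0", "width": _f(scene.width),
         "height": _f(scene.height), "fill": "#FFFFFF",
         "data-role": "background"},
    )

    for ax in scene.axes:
        ET.SubElement(
            root, "line",
            {"x1": _f(ax.x), "y1": _f(ax.y_top), "x2": _f(ax.x),
             "y2": _f(ax.y_bottom), "stroke": AXIS_COLOR, "stroke-width": "2",
             "data-role": "axis", "data-map": ax.map_id},
        )
    for t in sorted(scene.ticks, key=lambda t: (t.map_id, t.value)):
        ET.SubElement(
            root, "line",
            {"x1": _f(t.x - 4), "y1": _f(t.y), "x2": _f(t.x), "y2": _f(t.y),
             "stroke": AXIS_COLOR, "stroke-width": "1",
             "data-role": "tick", "data-map": t.map_id},
        )
        el = ET.SubElement(
            root, "text",
            {"x": _f(t.x - 6), "y": _f(t.y + 3), "text-anchor": "end",
             "font-size": "8", "fill": TEXT_COLOR,
             "data-role": "tick-label", "data-map": t.map_id},
        )
        el.text = t.text
    for g in sorted(scene.marker_glyphs, key=lambda g: (g.map_id, g.y, g.marker_name)):
        ET.SubElement(
            root, "line",
            {"x1": _f(g.x), "y1": _f(g.y), "x2": _f(g.x + 6), "y2": _f(g.y),
             "stroke": TEXT_COLOR, "stroke-width": "1",
             "data-role": "marker", "data-map": g.map_id,
             "data-marker": g.marker_name},
        )
    for rb in sorted(scene.range_bars, key=lambda r: (r.map_id, r.y_top, r.marker_name)):
        ET.SubElement(
            root, "rect",
            {"x": _f(rb.x - 3), "y": _f(rb.y_top), "width": "3",
             "height": _f(max(rb.y_bottom - rb.y_top, 0.5)),
             "fill": "#555555",
             "data-role": "marker-range", "data-map": rb.map_id,
             "data-marker": rb.marker_name},
        )
    for sg in sorted(scene.strand_glyphs, key=lambda s: (s.map_id, s.y, s.marker_name)):
        if sg.direction == "up":
            pts = f"{_f(sg.x)},{_f(sg.y + 3)} {_f(sg.x + 6)},{_f(sg.y + 3)} {_f(sg.x + 3)},{_f(sg.y - 3)}"
        else:
            pts = f"{_f(sg.x)},{_f(sg.y - 3)} {_f(sg.x + 6)},{_f(sg.y - 3)} {_f(sg.x + 3)},{_f(sg.y + 3)}"
        ET.SubElement(
            root, "polygon",
            {"points": pts, "fill": TEXT_COLOR,
             "data-role": "strand", "data-map": sg.map_id,
             "data-marker": sg.marker_name, "data-direction": sg.direction},
        )
    for ll in sorted(
        scene.link_lines,
        key=lambda l: (l.link_type, l.map_a, l.marker_a, l.map_b, l.marker_b),
    ):
        ET.SubElement(
            root, "line",
            {"x1": _f(ll.x1), "y1": _f(ll.y1), "x2": _f(ll.x2), "y2": _f(ll.y2),
             "stroke": ll.color, "stroke-width": "1",
             "data-role": "link", "data-link-type": ll.link_type,
             "data-map-a": ll.map_a, "data-marker-a": ll.marker_a,
             "data-map-b": ll.map_b, "data-marker-b": ll.marker_b},
        )
    for lb in sorted(scene.labels, key=lambda l: (l.map_id, l.y, l.marker_name)):
        el = ET.SubElement(
            root, "text",
            {"x": _f(lb.x), "y": _f(lb.y), "font-size": "9", "fill": TEXT_COLOR,
             "data-role": "label", "data-map": lb.map_id,
             "data-marker": lb.marker_name},
        )
        el.text = lb.text
    y0 = scene.height - 18.0 * len(scene.legend) - 10.0
    for i, entry in enumerate(scene.legend):
        y = y0 + 18.0 * i
        ET.SubElement(
            root, "line",
            {"x1": "10", "y1": _f(y), "x2": "40", "y2": _f(y),
             "stroke": entry.color, "stroke-width": "2",
             "data-role": "legend-line", "data-link-type": entry.link_type},
        )
        el = ET.SubElement(
            root, "text",
            {"x": "46", "y": _f(y + 3), "font-size": "9", "fill": TEXT_COLOR,
             "data-role": "legend-label", "data-link-type": entry.link_type},
        )
        el.text = entry.link_type
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        + ET.tostring(root, encoding="unicode")
        + "\n"
    )


def render_svg(scene: Scene, path: str | os.PathLike) -> None:
    """Write the scene as a well-formed, byte-stable SVG 1.1 file."""
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write(scene_to_svg(scene))
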