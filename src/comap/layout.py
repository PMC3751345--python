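"""Canvas layout: placements, virtual columns and coordinate transforms.

Maps are placed freely in 2-D; *virtual columns* are derived as the
connected components of horizontal-interval overlap (closed intervals:
a shared boundary joins two maps into one column), ordered by minimum
x.  Relationship lines are only ever drawn between maps in adjacent
columns, so column structure is what decides which map pairs may show
links.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import GenomeMap

__all__ = [
    "Placement",
    "Canvas",
    "OutOfViewError",
    "LabelBox",
    "compute_columns",
    "adjacent_pairs",
    "to_canvas_y",
    "from_canvas_y",
    "place_labels",
    "load_canvas_json",
    "auto_canvas",
]

LABEL_MODES = ("all", "linked_only", "none")


class OutOfViewError(ValueError):
    """A map coordinate falls outside a placement's view window."""


@dataclass
class Placement:
    """Where and how one map appears on the canvas."""

    map_id: str
    x: float
    y: float
    width: float
    height: float
    view_start: float
    view_end: float
    flipped: bool = False
    visible: bool = True
    label_mode: str = "all"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"placement {self.map_id!r}: non-positive size")
        if not self.view_start < self.view_end:
            raise ValueError(
                f"placement {self.map_id!r}: view_start must be < view_end"
            )
        if self.label_mode not in LABEL_MODES:
            raise ValueError(
                f"placement {self.map_id!r}: unknown label_mode {self.label_mode!r}"
            )

    @property
    def x_interval(self) -> tuple[float, float]:
        return (self.x, self.x + self.width)

    def in_view(self, c: float) -> bool:
        return self.view_start <= c <= self.view_end


@dataclass
class Canvas:
    """A set of placements plus style settings consumed by the renderer."""

    placements: list[Placement] = field(default_factory=list)
    style: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.map_id for p in self.placements]
        if len(ids) != len(set(ids)):
            raise ValueError("canvas placements must have unique map_ids")

    def placement(self, map_id: str) -> Placement:
        for p in self.placements:
            if p.map_id == map_id:
                return p
        raise KeyError(map_id)


def compute_columns(canvas: Canvas) -> list[set[str]]:
    """Virtual columns: connected components of horizontal overlap.

    Visible placements only; intervals ``[x, x + width]`` are closed,
    so touching boundaries share a column.  Components are ordered by
    their minimum x.
    """
    visible = [p for p in canvas.placements if p.visible]
    if not visible:
        return []
    visible.sort(key=lambda p: (p.x, p.x + p.width, p.map_id))
    columns: list[set[str]] = []
    col_min: list[float] = []
    current: set[str] = {visible[0].map_id}
    cur_min = visible[0].x
    reach = visible[0].x + visible[0].width
    for p in visible[1:]:
        if p.x <= reach:  # closed-interval overlap, transitively grouped
            current.add(p.map_id)
            reach = max(reach, p.x + p.width)
        else:
            columns.append(current)
            col_min.append(cur_min)
            current = {p.map_id}
            cur_min = p.x
            reach = p.x + p.width
    columns.append(current)
    col_min.append(cur_min)
    order = sorted(range(len(columns)), key=lambda i: col_min[i])
    return [columns[i] for i in order]


def adjacent_pairs(canvas: Canvas) -> list[tuple[str, str]]:
    """All cross-column map pairs between consecutive columns.

    Pairs within one column are never returned; only maps in columns i
    and i+1 may be linked.
    """
    columns = compute_columns(canvas)
    pairs = []
    for left, right in zip(columns, columns[1:]):
        for a in sorted(left):
            for b in sorted(right):
                pairs.append((a, b))
    return pairs


def to_canvas_y(placement: Placement, c: float) -> float:
    """Map coordinate -> canvas y along the placement's vertical axis.

    The view window maps linearly onto ``[y, y + height]``; a flipped
    axis reverses direction.  Raises :class:`OutOfViewError` outside
    the window (callers clip).
    """
    if not placement.in_view(c):
        raise OutOfViewError(
            f"coordinate {c} outside view [{placement.view_start}, "
            f"{placement.view_end}] of {placement.map_id!r}"
        )
    span = placement.view_end - placement.view_start
    if placement.flipped:
        frac = (placement.view_end - c) / span
    else:
        frac = (c - placement.view_start) / span
    return placement.y + placement.height * frac


def from_canvas_y(placement: Placement, y: float) -> float:
    """Inverse of :func:`to_canvas_y` (round-trips to ~1e-9 relative)."""
    frac = (y - placement.y) / placement.height
    if frac < -1e-12 or frac > 1 + 1e-12:
        raise OutOfViewError(f"canvas y {y} outside axis of {placement.map_id!r}")
    span = placement.view_end - placement.view_start
    if placement.flipped:
        return placement.view_end - frac * span
    return placement.view_start + frac * span


@dataclass(frozen=True)
class LabelBox:
    marker_name: str
    x: float
    y: float  # top of the box
    width: float
    height: float
    anchor_y: float  # canvas y of the marker itself


def place_labels(
    placement: Placement,
    markers: Sequence,
    linked_names: Optional[set[str]] = None,
    label_height: float = 10.0,
    char_width: float = 6.0,
    label_x_offset: float = 8.0,
) -> tuple[list[LabelBox], int]:
    """Greedy top-down horizontal label placement beside one axis.

    Labels are anchored at each marker's canvas y and nudged downward
    so that no two boxes on this axis overlap; labels pushed past the
    bottom of the placement are dropped.  ``label_mode`` governs which
    markers get labels: ``linked_only`` keeps markers present in
    *linked_names*; ``none`` yields no labels.

    Returns (boxes, dropped_count).
    """
    if placement.label_mode == "none":
        return [], 0
    candidates = []
    for m in markers:
        if not placement.in_view(m.midpoint):
            continue
        if placement.label_mode == "linked_only" and (
            linked_names is None or m.name not in linked_names
        ):
            continue
        candidates.append((to_canvas_y(placement, m.midpoint), m))
    candidates.sort(key=lambda t: (t[0], t[1].name))

    boxes: list[LabelBox] = []
    dropped = 0
    x = placement.x + placement.width + label_x_offset
    floor = -float("inf")
    bottom = placement.y + placement.height
    for anchor_y, m in candidates:
        top = max(anchor_y - label_height / 2.0, floor)
        if top + label_height > bottom:  # cannot fit within the axis height
            dropped += 1
            continue
        boxes.append(
            LabelBox(
                marker_name=m.name,
                x=x,
                y=top,
                width=char_width * len(m.name),
                height=label_height,
                anchor_y=anchor_y,
            )
        )
        floor = top + label_height
    return boxes, dropped


# ---------------------------------------------------------------------------
# layout files
# ---------------------------------------------------------------------------

_PLACEMENT_DEFAULTS = {
    "width": 120.0,
    "height": 400.0,
    "flipped": False,
    "visible": True,
    "label_mode": "all",
}


def auto_canvas(
    maps: Sequence[GenomeMap],
    width: float = 120.0,
    height: float = 400.0,
    gap: float = 80.0,
    style: Optional[dict] = None,
) -> Canvas:
    """Tile maps left-to-right, one per column, full extent in view."""
    placements = []
    for i, gmap in enumerate(maps):
        placements.append(
            Placement(
                map_id=gmap.map_id,
                x=i * (width + gap),
                y=40.0,
                width=width,
                height=height,
                view_start=gmap.extent_min,
                view_end=gmap.extent_max,
            )
        )
    return Canvas(placements=placements, style=dict(style or {}))


def load_canvas_json(
    path: str | os.PathLike, maps: Optional[dict[str, GenomeMap]] = None
) -> Canvas:
    """Load a canvas layout description from JSON.

    The document is ``{"placements": [...], "style": {...}}`` where
    each placement object carries the :class:`Placement` fields keyed
    by name.  Omitted fields default; omitted x positions auto-tile
    left-to-right in file order; omitted view windows default to the
    map's full extent (requires *maps*).
    """
    with open(path, "rt", encoding="utf-8") as handle:
        doc = json.load(handle)
    placements = []
    cursor = 0.0
    for entry in doc.get("placements", []):
        map_id = entry["map_id"]
        width = float(entry.get("width", _PLACEMENT_DEFAULTS["width"]))
        x = float(entry["x"]) if "x" in entry else cursor
        cursor = max(cursor, x + width + 80.0)
        view_start = entry.get("view_start")
        view_end = entry.get("view_end")
        if view_start is None or view_end is None:
            if maps is None or map_id not in maps:
                raise KeyError(
                    f"layout placement {map_id!r} omits the view window and no "
                    f"map was supplied to default it from"
                )
            gmap = maps[map_id]
            view_start = gmap.extent_min if view_start is None else view_start
            view_end = gmap.extent_max if view_end is None else view_end
        placements.append(
            Placement(
                map_id=map_id,
                x=x,
                y=float(entry.get("y", 40.0)),
                width=width,
                height=float(entry.get("height", _PLACEMENT_DEFAULTS["height"])),
                view_start=float(view_start),
                view_end=float(view_end),
                flipped=bool(entry.get("flipped", False)),
                visible=bool(entry.get("visible", True)),
                label_mode=entry.get("label_mode", "all"),
            )
        )
    return Canvas(placements=placements, style=doc.get("style", {}))


def save_canvas_json(canvas: Canvas, path: str | os.PathLike) -> None:
    doc = {
        "placements": [
            {
                "map_id": p.map_id,
                "x": p.x,
                "y": p.y,
                "width": p.width,
                "height": p.height,
                "view_start": p.view_start,
                "view_end": p.view_end,
                "flipped": p.flipped,
                "visible": p.visible,
                "label_mode": p.label_mode,
            }
            for p in canvas.placements
        ],
        "style": canvas.style,
    }
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        json.dump(doc, handle, indent=2, sort_keys=True)
        handle.write("\n")
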