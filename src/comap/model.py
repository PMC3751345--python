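"""Core domain model: markers, maps and map regions.

A :class:`GenomeMap` is a self-contained one-dimensional coordinate system
for a single chromosome or linkage group of one species.  Coordinates are
real-valued so the same model serves base-pair maps (whole numbers by
convention, 1-based, intervals inclusive at both ends) and centimorgan
linkage maps (decimals).  Each map carries its own extent; nothing relates
two maps except explicit links computed elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "STRANDS",
    "MARKER_KINDS",
    "Marker",
    "GenomeMap",
    "MapRegion",
    "RegionError",
    "subregion",
    "reorient",
    "validate_map",
]

STRANDS = ("forward", "reverse", "unstranded")

MARKER_KINDS = (
    "gene",
    "variant",
    "microsatellite",
    "sequence",
    "assembly_exception",
    "generic",
)

_FLIP = {"forward": "reverse", "reverse": "forward", "unstranded": "unstranded"}


class RegionError(ValueError):
    """A region does not lie within the extent of its map."""


@dataclass(frozen=True)
class Marker:
    """A named feature placed at a point or range on one map.

    A point marker has ``start == end``.  ``accession`` is a stable
    database identifier; ``name`` is the display name and need not be
    unique or stable.
    """

    name: str
    start: float
    end: float
    strand: str = "unstranded"
    kind: str = "generic"
    accession: Optional[str] = None
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"marker {self.name!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"marker {self.name!r}: unknown strand {self.strand!r}")
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"marker {self.name!r}: unknown kind {self.kind!r}")
        if self.accession is not None and self.accession == "":
            raise ValueError(f"marker {self.name!r}: accession must not be empty")

    @property
    def is_point(self) -> bool:
        return self.start == self.end

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def sort_key(self) -> tuple:
        return (self.start, self.end, self.name)


@dataclass
class GenomeMap:
    """One chromosome / linkage group of one species, with its markers.

    Markers are canonically ordered by ``(start, end, name)`` on
    construction so that equal maps serialise identically.
    """

    map_id: str
    species: str
    chromosome: str
    units: str  # "bp" | "cM" | "arbitrary"
    extent_min: float
    extent_max: float
    markers: tuple[Marker, ...] = field(default_factory=tuple)
    title: str = ""
    assembly_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.map_id:
            raise ValueError("map_id must be non-empty")
        if self.units not in ("bp", "cM", "arbitrary"):
            raise ValueError(f"map {self.map_id!r}: unknown units {self.units!r}")
        if not self.extent_min < self.extent_max:
            raise ValueError(
                f"map {self.map_id!r}: extent_min {self.extent_min} must be "
                f"< extent_max {self.extent_max}"
            )
        self.markers = tuple(sorted(self.markers, key=Marker.sort_key))
        if not self.title:
            self.title = self.map_id

    def __len__(self) -> int:
        return len(self.markers)

    def marker_by_accession(self, accession: str) -> list[Marker]:
        return [m for m in self.markers if m.accession == accession]

    def with_markers(self, markers: Iterable[Marker]) -> "GenomeMap":
        return replace(self, markers=tuple(markers))


@dataclass(frozen=True)
class MapRegion:
    """A closed sub-interval of one map, addressed by map_id."""

    map_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region start {self.start} must be < end {self.end}")


def _check_region(gmap: GenomeMap, region: MapRegion) -> None:
    if region.map_id != gmap.map_id:
        raise RegionError(
            f"region references map {region.map_id!r}, got map {gmap.map_id!r}"
        )
    if region.start < gmap.extent_min or region.end > gmap.extent_max:
        raise RegionError(
            f"region [{region.start}, {region.end}] outside extent "
            f"[{gmap.extent_min}, {gmap.extent_max}] of map {gmap.map_id!r}"
        )


def subregion(gmap: GenomeMap, region: MapRegion, new_id: str) -> GenomeMap:
    """Zoom/project: duplicate the selected region as a new map.

    The result's extent is ``[region.start, region.end]`` and it contains
    exactly the source markers whose interval intersects the region,
    with coordinates unchanged (same coordinate system).  Markers only
    partially overlapping the region are retained un-clipped; renderers
    clip visually.  The source map is not modified.
    """
    _check_region(gmap, region)
    kept = [
        m
        for m in gmap.markers
        if m.end >= region.start and m.start <= region.end
    ]
    return GenomeMap(
        map_id=new_id,
        species=gmap.species,
        chromosome=gmap.chromosome,
        units=gmap.units,
        extent_min=region.start,
        extent_max=region.end,
        markers=tuple(kept),
        title=f"{gmap.title} [{region.start}-{region.end}]",
        assembly_tag=gmap.assembly_tag,
    )


def reorient(gmap: GenomeMap) -> GenomeMap:
    """Reflect the map about its extent midpoint and flip strands.

    Coordinates map ``c -> extent_min + extent_max - c`` with start/end
    swapped to keep ``start <= end``; forward and reverse strands are
    exchanged.  Applying twice restores the original map.
    """
    pivot = gmap.extent_min + gmap.extent_max
    flipped = [
        replace(m, start=pivot - m.end, end=pivot - m.start, strand=_FLIP[m.strand])
        for m in gmap.markers
    ]
    return gmap.with_markers(flipped)


def validate_map(gmap: GenomeMap) -> list[str]:
    """Return a human-readable description of every invariant violation.

    An empty list means the map is well-formed.  Purely diagnostic;
    never raises.
    """
    violations: list[str] = []
    if not gmap.extent_min < gmap.extent_max:
        violations.append(
            f"map {gmap.map_id!r}: extent_min must be < extent_max"
        )
    for m in gmap.markers:
        if m.start > m.end:
            violations.append(f"marker {m.name!r}: start > end")
        if m.start < gmap.extent_min:
            violations.append(
                f"marker {m.name!r}: start {m.start} below extent_min "
                f"{gmap.extent_min}"
            )
        if m.end > gmap.extent_max:
            violations.append(
                f"marker {m.name!r}: end {m.end} beyond extent_max "
                f"{gmap.extent_max}"
            )
    return violations
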