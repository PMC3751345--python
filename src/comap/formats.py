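"""Readers and writers for all supported file dialects.

Supported formats:

* **Plain-text map dialect** — whitespace/tab-separated columns
  ``name start [end] [strand] [kind] [accession]``, with ``#``-prefixed
  header lines carrying map metadata::

      #map <chromosome> <species> <units>
      #id <map_id>
      #title <free text>
      #assembly <tag>
      #extent <min> <max>

  Missing ``end`` means a point marker.  Strand is ``+``/``-``/``.``.
  ``.`` in the accession column means "no accession".  When no
  ``#extent`` header is present the extent defaults to the span of the
  markers.

* **Map-interchange XML dialect** (documented in the README): a
  ``<mapset>`` root nesting ``<species name=...>`` → ``<map>`` →
  ``<marker>`` elements, UTF-8.  Round-trips the full model.

* **GFF3** (standard, 1-based inclusive) and **BED** (0-based
  half-open, converted on read) for building gene-annotation maps.

* **Homology TSV** with fixed column names ``gene_a species_a gene_b
  species_b homology_type perc_identity perc_similarity``.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import gffutils

from .model import MARKER_KINDS, GenomeMap, Marker, validate_map

__all__ = [
    "HOMOLOGY_TYPES",
    "HomologyRecord",
    "HomologyTable",
    "MapParseError",
    "MapSchemaError",
    "ChromosomeNotFoundError",
    "read_map_text",
    "write_map_text",
    "read_map_xml",
    "write_map_xml",
    "read_gff3_genes",
    "read_bed_map",
    "read_homology_tsv",
    "write_homology_tsv",
]

HOMOLOGY_TYPES = (
    "ortholog_one2one",
    "apparent_ortholog_one2one",
    "ortholog_one2many",
    "ortholog_many2many",
    "possible_ortholog",
    "paralog",
)


class MapParseError(ValueError):
    """A text map file line could not be parsed."""


class MapSchemaError(ValueError):
    """An XML map document does not match the documented dialect."""


class ChromosomeNotFoundError(KeyError):
    """Requested landmark absent from an annotation file."""


# ---------------------------------------------------------------------------
# plain-text map dialect
# ---------------------------------------------------------------------------

_STRAND_FROM_SYM = {"+": "forward", "-": "reverse", ".": "unstranded"}
_SYM_FROM_STRAND = {v: k for k, v in _STRAND_FROM_SYM.items()}


def _parse_marker_line(tokens: list[str], lineno: int) -> Marker:
    name = tokens[0]
    if len(tokens) < 2:
        raise MapParseError(f"line {lineno}: marker {name!r} has no position")
    try:
        start = float(tokens[1])
    except ValueError:
        raise MapParseError(
            f"line {lineno}: cannot parse start coordinate {tokens[1]!r}"
        ) from None
    rest = tokens[2:]
    end = start
    if rest:
        try:
            end = float(rest[0])
            rest = rest[1:]
        except ValueError:
            pass
    strand = "unstranded"
    if rest and rest[0] in _STRAND_FROM_SYM:
        strand = _STRAND_FROM_SYM[rest[0]]
        rest = rest[1:]
    kind = "generic"
    if rest and rest[0] in MARKER_KINDS:
        kind = rest[0]
        rest = rest[1:]
    accession: Optional[str] = None
    if rest:
        accession = rest[0] if rest[0] != "." else None
        rest = rest[1:]
    if rest:
        raise MapParseError(
            f"line {lineno}: trailing tokens {rest!r} after marker {name!r}"
        )
    try:
        return Marker(
            name=name, start=start, end=end, strand=strand, kind=kind,
            accession=accession,
        )
    except ValueError as exc:
        raise MapParseError(f"line {lineno}: {exc}") from None


def read_map_text(path: str | os.PathLike) -> GenomeMap:
    """Parse one map from the plain-text dialect; see module docstring."""
    chromosome = "unknown"
    species = "unknown"
    units = "arbitrary"
    map_id: Optional[str] = None
    title = ""
    assembly: Optional[str] = None
    extent: Optional[tuple[float, float]] = None
    markers: list[Marker] = []

    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split()
                if not fields:
                    continue
                key, args = fields[0], fields[1:]
                if key == "map":
                    if len(args) != 3:
                        raise MapParseError(
                            f"line {lineno}: '#map' needs chromosome, species, "
                            f"units; got {args!r}"
                        )
                    chromosome, species, units = args
                elif key == "id" and args:
                    map_id = args[0]
                elif key == "title":
                    title = " ".join(args)
                elif key == "assembly" and args:
                    assembly = args[0]
                elif key == "extent":
                    if len(args) != 2:
                        raise MapParseError(
                            f"line {lineno}: '#extent' needs two numbers"
                        )
                    try:
                        extent = (float(args[0]), float(args[1]))
                    except ValueError:
                        raise MapParseError(
                            f"line {lineno}: non-numeric extent {args!r}"
                        ) from None
                # unknown header keys are ignored (forward compatible)
                continue
            markers.append(_parse_marker_line(line.split(), lineno))

    if extent is None:
        if not markers:
            raise MapParseError(
                f"{path}: no markers and no '#extent' header; map is empty"
            )
        extent = (min(m.start for m in markers), max(m.end for m in markers))
        if extent[0] == extent[1]:
            extent = (extent[0], extent[0] + 1.0)

    gmap = GenomeMap(
        map_id=map_id or chromosome,
        species=species,
        chromosome=chromosome,
        units=units,
        extent_min=extent[0],
        extent_max=extent[1],
        markers=tuple(markers),
        title=title,
        assembly_tag=assembly,
    )
    problems = validate_map(gmap)
    if problems:
        raise MapParseError(f"{path}: " + "; ".join(problems))
    return gmap


def _fmt(x: float) -> str:
    return repr(float(x))


def write_map_text(gmap: GenomeMap, path: str | os.PathLike) -> None:
    """Write a map in the plain-text dialect (deterministic output)."""
    lines = [f"#map {gmap.chromosome} {gmap.species} {gmap.units}"]
    lines.append(f"#id {gmap.map_id}")
    if gmap.title and gmap.title != gmap.map_id:
        lines.append(f"#title {gmap.title}")
    if gmap.assembly_tag:
        lines.append(f"#assembly {gmap.assembly_tag}")
    lines.append(f"#extent {_fmt(gmap.extent_min)} {_fmt(gmap.extent_max)}")
    for m in gmap.markers:
        lines.append(
            "\t".join(
                [
                    m.name,
                    _fmt(m.start),
                    _fmt(m.end),
                    _SYM_FROM_STRAND[m.strand],
                    m.kind,
                    m.accession if m.accession is not None else ".",
                ]
            )
        )
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XML map-interchange dialect
# ---------------------------------------------------------------------------

def _require(elem: ET.Element, attr: str) -> str:
    value = elem.get(attr)
    if value is None:
        raise MapSchemaError(
            f"<{elem.tag}> element missing required attribute {attr!r}"
        )
    return value


def read_map_xml(path: str | os.PathLike) -> list[GenomeMap]:
    """Parse all maps from a map-interchange XML document."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise MapSchemaError(f"{path}: not well-formed XML: {exc}") from None
    root = tree.getroot()
    if root.tag != "mapset":
        raise MapSchemaError(f"root element must be <mapset>, got <{root.tag}>")
    maps: list[GenomeMap] = []
    for sp in root:
        if sp.tag != "species":
            raise MapSchemaError(f"unexpected element <{sp.tag}> under <mapset>")
        species = _require(sp, "name")
        for mp in sp:
            if mp.tag != "map":
                raise MapSchemaError(f"unexpected element <{mp.tag}> under <species>")
            markers = []
            for mk in mp:
                if mk.tag != "marker":
                    raise MapSchemaError(
                        f"unexpected element <{mk.tag}> under <map>"
                    )
                markers.append(
                    Marker(
                        name=_require(mk, "name"),
                        start=float(_require(mk, "start")),
                        end=float(_require(mk, "end")),
                        strand=mk.get("strand", "unstranded"),
                        kind=mk.get("kind", "generic"),
                        accession=mk.get("accession"),
                        description=mk.get("description"),
                    )
                )
            maps.append(
                GenomeMap(
                    map_id=_require(mp, "id"),
                    species=species,
                    chromosome=_require(mp, "chromosome"),
                    units=_require(mp, "units"),
                    extent_min=float(_require(mp, "extent_min")),
                    extent_max=float(_require(mp, "extent_max")),
                    markers=tuple(markers),
                    title=mp.get("title", ""),
                    assembly_tag=mp.get("assembly"),
                )
            )
    return maps


def write_map_xml(maps: Sequence[GenomeMap], path: str | os.PathLike) -> None:
    """Write maps as a map-interchange XML document (deterministic)."""
    root = ET.Element("mapset")
    by_species: dict[str, list[GenomeMap]] = defaultdict(list)
    for gmap in maps:
        by_species[gmap.species].append(gmap)
    for species in sorted(by_species):
        sp = ET.SubElement(root, "species", {"name": species})
        for gmap in by_species[species]:
            attrs = {
                "id": gmap.map_id,
                "title": gmap.title,
                "units": gmap.units,
                "chromosome": gmap.chromosome,
                "extent_min": _fmt(gmap.extent_min),
                "extent_max": _fmt(gmap.extent_max),
            }
            if gmap.assembly_tag is not None:
                attrs["assembly"] = gmap.assembly_tag
            mp = ET.SubElement(sp, "map", attrs)
            for m in gmap.markers:
                mattrs = {
                    "name": m.name,
                    "start": _fmt(m.start),
                    "end": _fmt(m.end),
                    "strand": m.strand,
                    "kind": m.kind,
                }
                if m.accession is not None:
                    mattrs["accession"] = m.accession
                if m.description is not None:
                    mattrs["description"] = m.description
                ET.SubElement(mp, "marker", mattrs)
    ET.indent(root)
    body = ET.tostring(root, encoding="unicode")
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write('<?xml version="1.0" encoding="UTF-8"?>\n')
        handle.write(body + "\n")


# ---------------------------------------------------------------------------
# gene annotations: GFF3 and BED
# ---------------------------------------------------------------------------

_GFF_STRAND = {"+": "forward", "-": "reverse", ".": "unstranded", "?": "unstranded"}


def read_gff3_genes(
    path: str | os.PathLike,
    chromosome: str,
    species: str,
    assembly_tag: Optional[str] = None,
    map_id: Optional[str] = None,
) -> GenomeMap:
    """Build a gene map from the ``gene`` features of one GFF3 landmark.

    Marker name is the ``Name`` attribute, falling back to ``ID``;
    accession is ``ID``.  Extent comes from the ``##sequence-region``
    directive when present, else from the features themselves.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    landmarks = sorted({f.seqid for f in db.all_features()})
    if chromosome not in landmarks:
        raise ChromosomeNotFoundError(
            f"landmark {chromosome!r} not in {path}; available: "
            + ", ".join(landmarks)
        )
    extent: Optional[tuple[float, float]] = None
    for directive in db.directives:
        fields = directive.split()
        if len(fields) == 4 and fields[0] == "sequence-region" and fields[1] == chromosome:
            extent = (float(fields[2]), float(fields[3]))
    markers = []
    for feat in db.features_of_type("gene"):
        if feat.seqid != chromosome:
            continue
        fid = feat.id
        name = feat.attributes.get("Name", [fid])[0]
        markers.append(
            Marker(
                name=name,
                start=float(feat.start),
                end=float(feat.end),
                strand=_GFF_STRAND.get(feat.strand, "unstranded"),
                kind="gene",
                accession=fid,
            )
        )
    if extent is None:
        if markers:
            extent = (min(m.start for m in markers), max(m.end for m in markers))
        else:
            extent = (1.0, 2.0)
    return GenomeMap(
        map_id=map_id or f"{species}_{chromosome}",
        species=species,
        chromosome=chromosome,
        units="bp",
        extent_min=extent[0],
        extent_max=extent[1],
        markers=tuple(markers),
        assembly_tag=assembly_tag,
    )


def read_bed_map(
    path: str | os.PathLike,
    chromosome: str,
    species: str,
    assembly_tag: Optional[str] = None,
    map_id: Optional[str] = None,
    kind: str = "generic",
) -> GenomeMap:
    """Build a map from BED intervals on one chromosome.

    BED is 0-based half-open; coordinates are converted to 1-based
    inclusive on read.
    """
    markers = []
    seen = set()
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MapParseError(f"line {lineno}: BED needs >= 3 columns")
            chrom = fields[0]
            seen.add(chrom)
            if chrom != chromosome:
                continue
            start0, end0 = int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
            strand = "unstranded"
            if len(fields) > 5 and fields[5] in ("+", "-"):
                strand = _GFF_STRAND[fields[5]]
            markers.append(
                Marker(
                    name=name, start=float(start0 + 1), end=float(end0),
                    strand=strand, kind=kind,
                )
            )
    if chromosome not in seen:
        raise ChromosomeNotFoundError(
            f"chromosome {chromosome!r} not in {path}; available: "
            + ", ".join(sorted(seen))
        )
    extent = (min(m.start for m in markers), max(m.end for m in markers)) if markers else (1.0, 2.0)
    return GenomeMap(
        map_id=map_id or f"{species}_{chromosome}",
        species=species,
        chromosome=chromosome,
        units="bp",
        extent_min=extent[0],
        extent_max=extent[1],
        markers=tuple(markers),
        assembly_tag=assembly_tag,
    )


# ---------------------------------------------------------------------------
# homology tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyRecord:
    """One asserted gene-pair homology with optional percent scores.

    The record is unordered: ``(gene_a, gene_b)`` and ``(gene_b,
    gene_a)`` denote the same relationship.
    """

    gene_a: str
    species_a: str
    gene_b: str
    species_b: str
    homology_type: str
    perc_identity: Optional[float] = None
    perc_similarity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.homology_type not in HOMOLOGY_TYPES:
            raise ValueError(f"unknown homology_type {self.homology_type!r}")
        for label, v in (("perc_identity", self.perc_identity),
                         ("perc_similarity", self.perc_similarity)):
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{label} {v} outside [0, 100]")
        if (
            self.perc_identity is not None
            and self.perc_similarity is not None
            and self.perc_similarity < self.perc_identity
        ):
            raise ValueError(
                f"perc_similarity {self.perc_similarity} < perc_identity "
                f"{self.perc_identity}"
            )

    def partner_of(self, accession: str) -> tuple[str, str]:
        """Return (gene, species) of the other end relative to *accession*."""
        if accession == self.gene_a:
            return self.gene_b, self.species_b
        if accession == self.gene_b:
            return self.gene_a, self.species_a
        raise KeyError(accession)

    def mentions(self, accession: str) -> bool:
        return accession in (self.gene_a, self.gene_b)


class HomologyTable:
    """Symmetric gene-pair lookup over a collection of homology records."""

    def __init__(self, records: Iterable[HomologyRecord] = ()):
        self.records: list[HomologyRecord] = list(records)
        self._index: dict[str, list[HomologyRecord]] = defaultdict(list)
        for rec in self.records:
            self._index[rec.gene_a].append(rec)
            if rec.gene_b != rec.gene_a:
                self._index[rec.gene_b].append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, accession: str) -> list[HomologyRecord]:
        """Every record mentioning *accession*, regardless of column."""
        return list(self._index.get(accession, ()))


_HOMOLOGY_COLUMNS = (
    "gene_a", "species_a", "gene_b", "species_b",
    "homology_type", "perc_identity", "perc_similarity",
)


def read_homology_tsv(path: str | os.PathLike) -> HomologyTable:
    """Read a homology table; see module docstring for the column contract."""
    records = []
    with open(path, "rt", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != _HOMOLOGY_COLUMNS:
            raise MapParseError(
                f"{path}: homology TSV header must be "
                + "\t".join(_HOMOLOGY_COLUMNS)
            )
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise MapParseError(f"row {lineno}: expected 7 columns")
            try:
                records.append(
                    HomologyRecord(
                        gene_a=fields[0],
                        species_a=fields[1],
                        gene_b=fields[2],
                        species_b=fields[3],
                        homology_type=fields[4],
                        perc_identity=float(fields[5]) if fields[5] else None,
                        perc_similarity=float(fields[6]) if fields[6] else None,
                    )
                )
            except ValueError as exc:
                raise MapParseError(f"row {lineno}: {exc}") from None
    return HomologyTable(records)


def write_homology_tsv(table: HomologyTable, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(_HOMOLOGY_COLUMNS) + "\n")
        for rec in table.records:
            handle.write(
                "\t".join(
                    [
                        rec.gene_a,
                        rec.species_a,
                        rec.gene_b,
                        rec.species_b,
                        rec.homology_type,
                        "" if rec.perc_identity is None else repr(rec.perc_identity),
                        "" if rec.perc_similarity is None else repr(rec.perc_similarity),
                    ]
                )
                + "\n"
            )
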