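"""Typed links between markers of two maps.

Three families of relationship are computed: *identity* (shared stable
accession), *synonymy* (shared name, with identity taking precedence for
the same marker pair) and *homology* (asserted gene-pair relationships
consumed from a :class:`~comap.formats.HomologyTable`).  Matching is
exact and case-sensitive throughout — accessions are case-significant
and silent case-folding of names risks false synonymy.

Links are unordered edges; endpoints are stored in a canonical order so
that link sets computed from ``(a, b)`` and ``(b, a)`` compare equal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .formats import HOMOLOGY_TYPES, HomologyTable
from .model import GenomeMap, Marker

__all__ = [
    "LINK_TYPES",
    "DEFAULT_PALETTE",
    "Link",
    "identity_links",
    "synonymy_links",
    "homology_links",
    "all_links",
    "filter_links",
    "link_color",
    "write_links_tsv",
]

LINK_TYPES = ("identity", "synonymy") + HOMOLOGY_TYPES

# Okabe-Ito colour-universal-design palette, one colour per link type.
DEFAULT_PALETTE = {
    "identity": "#CC79A7",                 # reddish-purple
    "synonymy": "#56B4E9",                 # sky-blue
    "ortholog_one2one": "#000000",         # black
    "apparent_ortholog_one2one": "#D55E00",  # vermilion
    "ortholog_one2many": "#E69F00",        # orange
    "ortholog_many2many": "#009E73",       # blue-green
    "possible_ortholog": "#0072B2",        # blue
    "paralog": "#F0E442",                  # yellow
}


@dataclass(frozen=True)
class Link:
    """A typed edge between two markers on two different maps."""

    map_a: str
    marker_a: Marker
    map_b: str
    marker_b: Marker
    link_type: str
    perc_identity: Optional[float] = None
    perc_similarity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.map_a == self.map_b:
            raise ValueError("links are inter-map: map_a must differ from map_b")
        if self.link_type not in LINK_TYPES:
            raise ValueError(f"unknown link type {self.link_type!r}")

    @property
    def is_homology(self) -> bool:
        return self.link_type in HOMOLOGY_TYPES

    def endpoint_on(self, map_id: str) -> Marker:
        if map_id == self.map_a:
            return self.marker_a
        if map_id == self.map_b:
            return self.marker_b
        raise KeyError(map_id)


def make_link(
    map_a: str,
    marker_a: Marker,
    map_b: str,
    marker_b: Marker,
    link_type: str,
    perc_identity: Optional[float] = None,
    perc_similarity: Optional[float] = None,
) -> Link:
    """Build a link with endpoints in canonical (sorted) order."""
    key_a = (map_a, marker_a.sort_key())
    key_b = (map_b, marker_b.sort_key())
    if key_b < key_a:
        map_a, marker_a, map_b, marker_b = map_b, marker_b, map_a, marker_a
    return Link(map_a, marker_a, map_b, marker_b, link_type,
                perc_identity, perc_similarity)


def _pairs_by(a: GenomeMap, b: GenomeMap, key) -> Iterable[tuple[Marker, Marker]]:
    index: dict[str, list[Marker]] = {}
    for m in a.markers:
        k = key(m)
        if k is not None:
            index.setdefault(k, []).append(m)
    for n in b.markers:
        k = key(n)
        if k is None:
            continue
        for m in index.get(k, ()):
            yield m, n


def identity_links(a: GenomeMap, b: GenomeMap) -> list[Link]:
    """One identity link per marker pair sharing a non-absent accession.

    All-pairs semantics: an accession occurring twice on one map and
    once on the other yields two links.
    """
    return [
        make_link(a.map_id, m, b.map_id, n, "identity")
        for m, n in _pairs_by(a, b, lambda mk: mk.accession)
    ]


def synonymy_links(a: GenomeMap, b: GenomeMap) -> list[Link]:
    """One synonymy link per marker pair sharing a name, unless the same
    pair is already related by identity (identity takes precedence)."""
    links = []
    for m, n in _pairs_by(a, b, lambda mk: mk.name):
        if m.accession is not None and m.accession == n.accession:
            continue
        links.append(make_link(a.map_id, m, b.map_id, n, "synonymy"))
    return links


def homology_links(a: GenomeMap, b: GenomeMap, table: HomologyTable) -> list[Link]:
    """One link per homology record joining an accession on *a* with one
    on *b*.  Markers without accession never match.  Link type and
    scores are carried over from the record."""
    index_b: dict[str, list[Marker]] = {}
    for n in b.markers:
        if n.accession is not None:
            index_b.setdefault(n.accession, []).append(n)
    links = []
    seen_records = set()
    for m in a.markers:
        if m.accession is None:
            continue
        for rec in table.lookup(m.accession):
            partner, _species = rec.partner_of(m.accession)
            for n in index_b.get(partner, ()):
                key = (id(rec), m.sort_key(), n.sort_key())
                if key in seen_records:
                    continue
                seen_records.add(key)
                links.append(
                    make_link(
                        a.map_id, m, b.map_id, n, rec.homology_type,
                        rec.perc_identity, rec.perc_similarity,
                    )
                )
    return links


def all_links(
    a: GenomeMap, b: GenomeMap, table: Optional[HomologyTable] = None
) -> list[Link]:
    """Identity + synonymy (+ homology when a table is given)."""
    links = identity_links(a, b) + synonymy_links(a, b)
    if table is not None:
        links += homology_links(a, b, table)
    return links


def filter_links(
    links: Iterable[Link],
    min_identity: Optional[float] = None,
    min_similarity: Optional[float] = None,
) -> list[Link]:
    """Apply score thresholds to homology links.

    Non-homology links (identity, synonymy) always pass.  A homology
    link passes iff each active threshold is met by the corresponding
    score; a link lacking a score fails any threshold applied to that
    score (conservative reporting).
    """
    for label, t in (("min_identity", min_identity),
                     ("min_similarity", min_similarity)):
        if t is not None and not 0.0 <= t <= 100.0:
            raise ValueError(f"{label} {t} outside [0, 100]")
    kept = []
    for link in links:
        if link.is_homology:
            if min_identity is not None and (
                link.perc_identity is None or link.perc_identity < min_identity
            ):
                continue
            if min_similarity is not None and (
                link.perc_similarity is None
                or link.perc_similarity < min_similarity
            ):
                continue
        kept.append(link)
    return kept


def link_color(link_type: str, palette: Optional[dict] = None) -> str:
    """Colour (hex) for a link type; user palettes override the default."""
    if link_type not in LINK_TYPES:
        raise KeyError(f"unknown link type {link_type!r}")
    if palette and link_type in palette:
        return palette[link_type]
    return DEFAULT_PALETTE[link_type]


def write_links_tsv(links: Sequence[Link], path: str | os.PathLike) -> None:
    """Export links as TSV (deterministic row order)."""
    rows = sorted(
        links,
        key=lambda l: (l.link_type, l.map_a, l.marker_a.sort_key(),
                       l.map_b, l.marker_b.sort_key()),
    )
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write(
            "map_a\tmarker_a\tmap_b\tmarker_b\ttype\tperc_identity\tperc_similarity\n"
        )
        for l in rows:
            handle.write(
                "\t".join(
                    [
                        l.map_a,
                        l.marker_a.name,
                        l.map_b,
                        l.marker_b.name,
                        l.link_type,
                        "" if l.perc_identity is None else repr(l.perc_identity),
                        "" if l.perc_similarity is None else repr(l.perc_similarity),
                    ]
                )
                + "\n"
            )
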