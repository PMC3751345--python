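"""Conserved-synteny discovery, marker transfer and in-silico PCR.

``find_conserved_regions`` walks the gene markers of a selected map
region, collects homology records to a target species, and groups the
matched target genes by target chromosome — one candidate region per
chromosome, ranked by the number of contributing source genes.  No
minimum gene count is imposed on what constitutes a region; callers
threshold on the reported counts.

``epcr_map`` locates primer-pair amplicons in a genome by exact string
matching on both strands, keeping only pairs with a single hit across
all assembled sequences; multi-hit pairs and hits on unplaced fragments
are discarded and reported.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .formats import HomologyTable
from .model import GenomeMap, Marker, MapRegion, _check_region
from .relations import Link, make_link

__all__ = [
    "ConservedRegion",
    "SkippedGene",
    "PrimerPair",
    "EpcrHit",
    "DiscardedPair",
    "find_conserved_regions",
    "crossing_count",
    "transfer_markers",
    "epcr_map",
    "read_primers_tsv",
    "write_primers_tsv",
    "write_discard_tsv",
    "UNPLACED_PATTERN",
]


# ---------------------------------------------------------------------------
# conserved synteny
# ---------------------------------------------------------------------------

@dataclass
class ConservedRegion:
    """Genes on one target chromosome homologous to a queried source region."""

    target_species: str
    target_chromosome: str
    target_map_id: str
    span_start: float
    span_end: float
    target_gene_accessions: set[str]
    source_gene_count: int
    links: list[Link] = field(default_factory=list)


@dataclass(frozen=True)
class SkippedGene:
    """A homologue asserted in the table but absent from every target map."""

    source_accession: str
    target_accession: str
    reason: str = "not_on_target_maps"


def find_conserved_regions(
    source: GenomeMap,
    region: MapRegion,
    table: HomologyTable,
    target_species: str,
    target_maps: Sequence[GenomeMap],
    skipped: Optional[list[SkippedGene]] = None,
) -> list[ConservedRegion]:
    """Search a source map region for conserved synteny in a target species.

    For each gene marker in *region*, homology records whose partner
    species is *target_species* are collected; partners located on the
    supplied *target_maps* are grouped by target chromosome.  One
    :class:`ConservedRegion` is emitted per chromosome, spanning its
    target genes, sorted by descending source-gene count.  Partners in
    the table but on no target map are appended to *skipped* (when
    given) rather than raising.
    """
    _check_region(source, region)
    locate: dict[str, tuple[GenomeMap, Marker]] = {}
    for tmap in target_maps:
        for m in tmap.markers:
            if m.accession is not None:
                locate.setdefault(m.accession, (tmap, m))

    per_chrom: dict[str, dict] = {}
    for m in source.markers:
        if m.kind != "gene" or m.accession is None:
            continue
        if m.end < region.start or m.start > region.end:
            continue
        for rec in table.lookup(m.accession):
            partner, partner_species = rec.partner_of(m.accession)
            if partner_species != target_species:
                continue
            hit = locate.get(partner)
            if hit is None:
                if skipped is not None:
                    skipped.append(SkippedGene(m.accession, partner))
                continue
            tmap, tmarker = hit
            bucket = per_chrom.setdefault(
                tmap.chromosome,
                {"map": tmap, "genes": set(), "sources": set(), "links": []},
            )
            bucket["genes"].add(partner)
            bucket["sources"].add(m.accession)
            bucket["links"].append(
                make_link(
                    source.map_id, m, tmap.map_id, tmarker,
                    rec.homology_type, rec.perc_identity, rec.perc_similarity,
                )
            )

    regions = []
    for chrom, bucket in per_chrom.items():
        tmap = bucket["map"]
        targets = [locate[acc][1] for acc in bucket["genes"]]
        regions.append(
            ConservedRegion(
                target_species=target_species,
                target_chromosome=chrom,
                target_map_id=tmap.map_id,
                span_start=min(t.start for t in targets),
                span_end=max(t.end for t in targets),
                target_gene_accessions=set(bucket["genes"]),
                source_gene_count=len(bucket["sources"]),
                links=bucket["links"],
            )
        )
    regions.sort(key=lambda r: (-r.source_gene_count, r.target_chromosome))
    return regions


def crossing_count(links: Sequence[Link]) -> int:
    """Number of discordantly ordered link pairs between two maps.

    Links must all join the same two maps.  A pair (i, j) crosses iff
    ``sign(a_i - a_j) != sign(b_i - b_j)`` where a/b are endpoint
    midpoints on each map.  Counted in O(k log k) by merge-sort
    inversion counting with explicit tie handling.
    """
    if not links:
        return 0
    map_ids = {links[0].map_a, links[0].map_b}
    if len(map_ids) != 2:
        raise ValueError("links must join two distinct maps")
    lo, hi = sorted(map_ids)
    pts = []
    for link in links:
        if {link.map_a, link.map_b} != map_ids:
            raise ValueError("all links must join the same two maps")
        pts.append((link.endpoint_on(lo).midpoint, link.endpoint_on(hi).midpoint))

    n = len(pts)
    total = n * (n - 1) // 2

    def tie_pairs(values: Iterable[float]) -> int:
        counts: dict[float, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        return sum(c * (c - 1) // 2 for c in counts.values())

    t_a = tie_pairs(v for v, _ in pts)
    t_b = tie_pairs(v for _, v in pts)
    t_ab = tie_pairs(pts)

    # strict inversions: a_i < a_j but b_i > b_j.  Sorting by (a, b)
    # ascending makes a-tied pairs non-inverting in b, so they are not
    # counted here and are handled via the tie terms below.
    pts.sort()
    b_seq = [b for _, b in pts]

    def count_inv(seq: list[float]) -> int:
        if len(seq) <= 1:
            return 0
        mid = len(seq) // 2
        left, right = seq[:mid], seq[mid:]
        inv = count_inv(left) + count_inv(right)
        merged = []
        i = j = 0
        while i < len(left) and j < len(right):
            if left[i] <= right[j]:
                merged.append(left[i])
                i += 1
            else:
                inv += len(left) - i
                merged.append(right[j])
                j += 1
        merged.extend(left[i:])
        merged.extend(right[j:])
        seq[:] = merged
        return inv

    strict_inv = count_inv(b_seq)
    concordant_strict = total - strict_inv - (t_a + t_b - t_ab)
    # crossing pairs = all pairs minus those with equal signs
    # (strictly concordant, or tied on both axes)
    return total - concordant_strict - t_ab


def transfer_markers(source: GenomeMap, dest: GenomeMap) -> GenomeMap:
    """Copy source markers onto a co-assembled destination map.

    Both maps must share units and assembly tag (the same coordinate
    system); only markers whose intervals lie fully within the
    destination extent are copied.  Names, accessions, strands and
    kinds are preserved.
    """
    if source.units != dest.units:
        raise ValueError(
            f"incompatible coordinates: units {source.units!r} vs {dest.units!r}"
        )
    if source.assembly_tag != dest.assembly_tag:
        raise ValueError(
            f"incompatible coordinates: assembly {source.assembly_tag!r} vs "
            f"{dest.assembly_tag!r}"
        )
    moved = [
        m
        for m in source.markers
        if m.start >= dest.extent_min and m.end <= dest.extent_max
    ]
    return dest.with_markers(dest.markers + tuple(moved))


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

UNPLACED_PATTERN = r"(?:scaffold|contig|random|Un)"

_DNA_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class PrimerPair:
    """A named primer pair with expected product-size bounds (bp)."""

    name: str
    forward: str
    reverse: str
    min_product: int
    max_product: int

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not _DNA_RE.match(seq):
                raise ValueError(
                    f"primer pair {self.name!r}: {label} primer must be "
                    f"non-empty over A/C/G/T, got {seq!r}"
                )
        if not 0 < self.min_product <= self.max_product:
            raise ValueError(
                f"primer pair {self.name!r}: need 0 < min_product <= max_product"
            )


@dataclass(frozen=True)
class EpcrHit:
    """One amplicon location, 1-based inclusive."""

    pair: str
    sequence: str
    start: int
    end: int


@dataclass(frozen=True)
class DiscardedPair:
    pair: str
    reason: str  # no_hit | multiple_hits | unplaced
    hit_count: int


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based match positions."""
    out = []
    pos = haystack.find(needle)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def _hits_on_sequence(seq: str, name: str, pair: PrimerPair) -> list[EpcrHit]:
    hits = []
    rc = lambda s: str(Seq(s).reverse_complement())
    # plus-strand product: forward primer then reverse-complemented
    # reverse primer downstream; minus-strand product: roles swapped.
    for left, right in ((pair.forward, rc(pair.reverse)),
                        (pair.reverse, rc(pair.forward))):
        left_pos = _find_all(seq, left)
        right_pos = _find_all(seq, right)
        for s in left_pos:
            for p in right_pos:
                if p < s:
                    continue
                end = p + len(right)  # 0-based exclusive
                length = end - s
                if pair.min_product <= length <= pair.max_product:
                    hits.append(EpcrHit(pair.name, name, s + 1, end))
    # a palindromic site can be found identically in both orientations
    return sorted(set(hits), key=lambda h: (h.sequence, h.start, h.end))


def epcr_map(
    pairs: Iterable[PrimerPair],
    genome_fasta: str | os.PathLike,
    unplaced_pattern: str = UNPLACED_PATTERN,
    species: str = "unknown",
    assembly_tag: Optional[str] = None,
) -> tuple[dict[str, GenomeMap], list[DiscardedPair]]:
    """Map primer pairs onto a genome by exact-match in-silico PCR.

    A hit is an exact forward-primer match with an exact
    reverse-complemented reverse-primer match downstream on the same
    sequence and a product length within the pair's bounds (both
    orientations tried).  Pairs with exactly one hit across all placed
    sequences become range markers (kind ``sequence``, accession = pair
    name); pairs with zero or multiple hits, or whose only hits fall on
    sequences matching *unplaced_pattern*, are discarded and reported.

    Returns one map per placed sequence (possibly empty) and the
    discard report.
    """
    unplaced = re.compile(unplaced_pattern)
    sequences = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(genome_fasta), "fasta")
    ]
    placed = [(n, s) for n, s in sequences if not unplaced.search(n)]

    markers_per_seq: dict[str, list[Marker]] = {n: [] for n, _ in placed}
    discards = []
    for pair in pairs:
        all_hits: list[EpcrHit] = []
        unplaced_hits = 0
        for name, seq in sequences:
            found = _hits_on_sequence(seq, name, pair)
            if unplaced.search(name):
                unplaced_hits += len(found)
            else:
                all_hits.extend(found)
        total = len(all_hits) + unplaced_hits
        if total == 0:
            discards.append(DiscardedPair(pair.name, "no_hit", 0))
        elif total > 1:
            discards.append(DiscardedPair(pair.name, "multiple_hits", total))
        elif unplaced_hits == 1:
            discards.append(DiscardedPair(pair.name, "unplaced", 1))
        else:
            hit = all_hits[0]
            markers_per_seq[hit.sequence].append(
                Marker(
                    name=pair.name,
                    start=float(hit.start),
                    end=float(hit.end),
                    kind="sequence",
                    accession=pair.name,
                )
            )

    maps = {
        name: GenomeMap(
            map_id=name,
            species=species,
            chromosome=name,
            units="bp",
            extent_min=1.0,
            extent_max=float(max(len(seq), 2)),
            markers=tuple(markers_per_seq[name]),
            title=f"ePCR map of {name}",
            assembly_tag=assembly_tag,
        )
        for name, seq in placed
    }
    return maps, discards


def read_primers_tsv(path: str | os.PathLike) -> list[PrimerPair]:
    """Primer panel TSV: name, forward, reverse, min_product, max_product."""
    pairs = []
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"line {lineno}: expected 5 tab-separated columns")
            pairs.append(
                PrimerPair(fields[0], fields[1], fields[2],
                           int(fields[3]), int(fields[4]))
            )
    return pairs


def write_primers_tsv(pairs: Sequence[PrimerPair], path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("name\tforward\treverse\tmin_product\tmax_product\n")
        for p in pairs:
            handle.write(
                f"{p.name}\t{p.forward}\t{p.reverse}\t{p.min_product}\t{p.max_product}\n"
            )


def write_discard_tsv(discards: Sequence[DiscardedPair], path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as handle:
        handle.write("pair\treason\thit_count\n")
        for d in discards:
            handle.write(f"{d.pair}\t{d.reason}\t{d.hit_count}\n")
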