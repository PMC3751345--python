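"""Synthetic fixture generators with known ground truth.

Every generator is a pure function of its parameters and seed, so any
released fixture file can be regenerated byte-identically.  The
generators produce the same file formats the pipeline consumes: maps,
homology tables, FASTA genomes, primer panels, layout JSON — plus a
truth record describing what was implanted.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats import (
    HomologyRecord,
    HomologyTable,
    write_homology_tsv,
    write_map_text,
)
from .layout import Canvas, save_canvas_json
from .model import GenomeMap, Marker
from .synteny import PrimerPair

__all__ = [
    "BlockSpec",
    "SimSpec",
    "simulate_genome_pair",
    "simulate_linkage_map",
    "simulate_genome_fasta",
    "random_map",
    "six_map_recipe",
]

_GENE_LEN = (1_000, 50_000)  # cosmetic; uniform, non-overlapping by rejection


@dataclass(frozen=True)
class BlockSpec:
    """One implanted orthologous block."""

    length: int
    orientation: str  # "preserved" | "inverted"
    target_chromosome: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("block length must be >= 1")
        if self.orientation not in ("preserved", "inverted"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class SimSpec:
    """Parameters for :func:`simulate_genome_pair`."""

    n_genes: int
    blocks: list[BlockSpec]
    identity_range: tuple[float, float] = (60.0, 95.0)
    similarity_gap: float = 5.0
    paralog_fraction: float = 0.0
    seed: int = 0
    source_species: str = "sourcesp"
    target_species: str = "targetsp"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if sum(b.length for b in self.blocks) > self.n_genes:
            raise ValueError("block lengths must sum to <= n_genes")
        chroms = [b.target_chromosome for b in self.blocks]
        if len(chroms) != len(set(chroms)):
            raise ValueError("blocks must use distinct target chromosomes")
        if not 0.0 <= self.paralog_fraction <= 1.0:
            raise ValueError("paralog_fraction must lie in [0, 1]")


def _nonoverlapping_intervals(
    rng: np.random.Generator, n: int, extent: int
) -> list[tuple[int, int]]:
    """n random non-overlapping (start, end) gene intervals, sorted."""
    intervals: list[tuple[int, int]] = []
    attempts = 0
    while len(intervals) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError(f"cannot fit {n} genes in extent {extent}")
        length = int(rng.integers(_GENE_LEN[0], _GENE_LEN[1] + 1))
        start = int(rng.integers(1, extent - length))
        end = start + length - 1
        if all(end < s or start > e for s, e in intervals):
            intervals.append((start, end))
    intervals.sort()
    return intervals


def simulate_genome_pair(
    spec: SimSpec,
) -> tuple[GenomeMap, list[GenomeMap], HomologyTable, dict]:
    """Simulate a source gene map, target maps with implanted orthologous
    blocks, the homology table linking them, and a truth record.

    Blocks are assigned to consecutive runs of source genes (in source
    order).  Each block's target genes appear on the named target
    chromosome in preserved or reversed order; each pair gets a
    one-to-one orthology record with scores drawn from the configured
    distribution.  An extra ``paralog_fraction`` of source genes gets a
    paralog record to a gene placed on *no* target map (exercising the
    skipped-genes path downstream).
    """
    rng = np.random.default_rng(spec.seed)
    extent = max(200_000 * spec.n_genes, 1_000_000)
    intervals = _nonoverlapping_intervals(rng, spec.n_genes, extent)
    strands = rng.choice(["forward", "reverse"], size=spec.n_genes)
    source_markers = [
        Marker(
            name=f"sgene{i:04d}",
            start=float(s),
            end=float(e),
            strand=str(strands[i]),
            kind="gene",
            accession=f"SRC{i:04d}",
        )
        for i, (s, e) in enumerate(intervals)
    ]
    source = GenomeMap(
        map_id=f"{spec.source_species}_chr1",
        species=spec.source_species,
        chromosome="1",
        units="bp",
        extent_min=1.0,
        extent_max=float(extent),
        markers=tuple(source_markers),
        assembly_tag="srcAsm1",
    )

    records: list[HomologyRecord] = []
    target_maps: list[GenomeMap] = []
    truth_blocks = []
    cursor = 0
    tgt_serial = 0
    for block in spec.blocks:
        members = source.markers[cursor : cursor + block.length]
        cursor += block.length
        t_extent = max(200_000 * block.length, 1_000_000)
        t_intervals = _nonoverlapping_intervals(rng, block.length, t_extent)
        order = list(range(block.length))
        if block.orientation == "inverted":
            order = order[::-1]
        pairs = []
        t_markers = []
        for slot, src_idx in enumerate(order):
            src = members[src_idx]
            acc = f"TGT{tgt_serial:04d}"
            tgt_serial += 1
            s, e = t_intervals[slot]
            t_markers.append(
                Marker(
                    name=f"tgene_{acc}",
                    start=float(s),
                    end=float(e),
                    strand=src.strand,
                    kind="gene",
                    accession=acc,
                )
            )
            identity = float(
                rng.uniform(spec.identity_range[0], spec.identity_range[1])
            )
            similarity = min(100.0, identity + float(rng.uniform(0, spec.similarity_gap)))
            records.append(
                HomologyRecord(
                    gene_a=src.accession,
                    species_a=spec.source_species,
                    gene_b=acc,
                    species_b=spec.target_species,
                    homology_type="ortholog_one2one",
                    perc_identity=round(identity, 2),
                    perc_similarity=round(similarity, 2),
                )
            )
            pairs.append((src.accession, acc))
        target_maps.append(
            GenomeMap(
                map_id=f"{spec.target_species}_chr{block.target_chromosome}",
                species=spec.target_species,
                chromosome=block.target_chromosome,
                units="bp",
                extent_min=1.0,
                extent_max=float(t_extent),
                markers=tuple(t_markers),
                assembly_tag="tgtAsm1",
            )
        )
        truth_blocks.append(
            {
                "target_chromosome": block.target_chromosome,
                "orientation": block.orientation,
                "pairs": pairs,
                "source_span": [float(members[0].start), float(members[-1].end)],
                "target_span": [
                    float(min(m.start for m in t_markers)),
                    float(max(m.end for m in t_markers)),
                ],
            }
        )

    n_paralog = int(round(spec.paralog_fraction * spec.n_genes))
    paralog_pairs = []
    for i in range(n_paralog):
        src = source.markers[int(rng.integers(0, spec.n_genes))]
        acc = f"OFFMAP{i:04d}"
        identity = float(rng.uniform(20.0, 60.0))
        records.append(
            HomologyRecord(
                gene_a=src.accession,
                species_a=spec.source_species,
                gene_b=acc,
                species_b=spec.target_species,
                homology_type="paralog",
                perc_identity=round(identity, 2),
                perc_similarity=round(min(100.0, identity + 5.0), 2),
            )
        )
        paralog_pairs.append((src.accession, acc))

    truth = {
        "seed": spec.seed,
        "rng": "numpy.default_rng",
        "n_genes": spec.n_genes,
        "source_map": source.map_id,
        "target_species": spec.target_species,
        "blocks": truth_blocks,
        "offmap_paralogs": paralog_pairs,
    }
    return source, target_maps, HomologyTable(records), truth


def simulate_linkage_map(
    physical: GenomeMap,
    cm_per_unit: float,
    jitter_sd: float,
    seed: int,
    map_id: Optional[str] = None,
) -> GenomeMap:
    """Derive a cM linkage map from a bp physical map.

    Marker names/accessions are shared with the physical map; cM
    positions are the scaled physical midpoints plus Gaussian jitter,
    clamped monotone non-decreasing in physical order.
    """
    if physical.units != "bp":
        raise ValueError("physical map must be in bp")
    rng = np.random.default_rng(seed)
    positions = []
    cm = 0.0
    for m in physical.markers:
        raw = (m.midpoint - physical.extent_min) * cm_per_unit
        if jitter_sd > 0:
            raw += float(rng.normal(0.0, jitter_sd))
        cm = max(cm, max(raw, 0.0))  # clamp monotone non-decreasing
        positions.append(cm)
    markers = [
        Marker(
            name=m.name,
            start=pos,
            end=pos,
            kind=m.kind,
            accession=m.accession,
        )
        for m, pos in zip(physical.markers, positions)
    ]
    top = max(positions) if positions else 1.0
    return GenomeMap(
        map_id=map_id or f"{physical.map_id}_cM",
        species=physical.species,
        chromosome=physical.chromosome,
        units="cM",
        extent_min=0.0,
        extent_max=max(top, 1e-6) * 1.02 + 1e-9,
        markers=tuple(markers),
        title=f"linkage map of {physical.chromosome}",
    )


@dataclass(frozen=True)
class Implant:
    pair: PrimerPair
    position: int  # 1-based start of the first copy
    copies: int = 1


def simulate_genome_fasta(
    length: int,
    implants: Sequence[Implant],
    seed: int,
    sequence_name: str = "chrSim",
    out_fasta: Optional[str | os.PathLike] = None,
) -> tuple[str, dict]:
    """Uniform-random ACGT sequence with primer amplicon sites implanted.

    Each implant places ``copies`` complete amplicons (forward primer +
    filler + reverse-complemented reverse primer, total length midway
    between the pair's product bounds), the first at ``position`` and
    further copies spaced downstream.  Overlapping implants are a
    validation error.  Returns the sequence and a truth record listing
    expected amplicon intervals and expected discards (>= 2 copies =>
    ``multiple_hits``).
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))

    def revcomp(s: str) -> str:
        return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    occupied: list[tuple[int, int]] = []
    truth_hits = []
    truth_discards = []
    for implant in implants:
        pair = implant.pair
        amp_len = (pair.min_product + pair.max_product) // 2
        amp_len = max(amp_len, len(pair.forward) + len(pair.reverse))
        spacing = amp_len + 1_000
        intervals = []
        for c in range(implant.copies):
            start = implant.position + c * spacing  # 1-based
            end = start + amp_len - 1
            if end > length:
                raise ValueError(
                    f"implant {pair.name!r} copy {c} exceeds sequence length"
                )
            if any(not (end < s or start > e) for s, e in occupied):
                raise ValueError(f"implant {pair.name!r} overlaps another implant")
            occupied.append((start, end))
            intervals.append((start, end))
            filler_len = amp_len - len(pair.forward) - len(pair.reverse)
            filler = "".join(rng.choice(list("ACGT"), size=filler_len))
            amplicon = pair.forward + filler + revcomp(pair.reverse)
            seq[start - 1 : start - 1 + amp_len] = list(amplicon)
        if implant.copies == 1:
            truth_hits.append(
                {"pair": pair.name, "sequence": sequence_name,
                 "start": intervals[0][0], "end": intervals[0][1]}
            )
        else:
            truth_discards.append(
                {"pair": pair.name, "reason": "multiple_hits",
                 "hit_count": implant.copies}
            )
    sequence = "".join(seq)
    truth = {
        "seed": seed,
        "rng": "numpy.default_rng",
        "sequence_name": sequence_name,
        "length": length,
        "expected_hits": truth_hits,
        "expected_discards": truth_discards,
    }
    if out_fasta is not None:
        with open(out_fasta, "wt", encoding="utf-8", newline="\n") as handle:
            handle.write(f">{sequence_name}\n")
            for i in range(0, length, 70):
                handle.write(sequence[i : i + 70] + "\n")
    return sequence, truth


def random_map(
    rng: np.random.Generator,
    map_id: str,
    n_markers: int,
    species: str = "simsp",
    chromosome: str = "1",
    units: str = "bp",
    extent: float = 1_000_000.0,
    accession_prefix: Optional[str] = None,
) -> GenomeMap:
    """A random map for property tests: mixed point/range markers."""
    markers = []
    for i in range(n_markers):
        start = float(np.round(rng.uniform(1, extent * 0.95), 1))
        if rng.random() < 0.5:
            end = start
        else:
            end = float(np.round(start + rng.uniform(1, extent * 0.05), 1))
        acc = None
        if accession_prefix is not None:
            acc = f"{accession_prefix}{i:05d}"
        markers.append(
            Marker(
                name=f"{map_id}_mk{i:05d}",
                start=start,
                end=min(end, extent),
                strand=str(rng.choice(["forward", "reverse", "unstranded"])),
                kind=str(rng.choice(["gene", "variant", "microsatellite",
                                     "sequence", "generic"])),
                accession=acc,
            )
        )
    return GenomeMap(
        map_id=map_id,
        species=species,
        chromosome=chromosome,
        units=units,
        extent_min=0.0,
        extent_max=float(extent),
        markers=tuple(markers),
    )


def six_map_recipe(outdir: str | os.PathLike, seed: int = 7) -> dict:
    """Write the bundled six-map comparative recipe to *outdir*.

    The canvas topology mirrors a typical cross-species integration:
    a private linkage map and a published-style linkage map in the
    first column pair, two physical bridge maps stacked in one column,
    and two gene-annotated assemblies stacked in the next.  Identity
    and synonymy relationships join the adjacent columns.

    Emits map text files, a layout JSON and a truth record; returns the
    truth record (paths + seed).
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)

    # two "species" physical maps carrying shared orthologous-sequence
    # markers named after the source panel
    n = 14
    panel = [f"snpmk{i:03d}" for i in range(n)]
    accs = [f"PANEL{i:03d}" for i in range(n)]

    def physical(map_id, species, chromosome, assembly):
        intervals = _nonoverlapping_intervals(rng, n, 3_000_000)
        markers = [
            Marker(name=panel[i], start=float(s), end=float(s),
                   kind="sequence", accession=accs[i])
            for i, (s, e) in enumerate(intervals)
        ]
        return GenomeMap(
            map_id=map_id, species=species, chromosome=chromosome,
            units="bp", extent_min=1.0, extent_max=3_000_000.0,
            markers=tuple(markers), assembly_tag=assembly,
        )

    bridge3 = physical("bridge_fishA", "fishA", "VII", "fishA_v1")
    bridge4 = physical("bridge_fishB", "fishB", "12", "fishB_v1")

    def annotated(bridge, map_id):
        genes = []
        g_int = _nonoverlapping_intervals(rng, 20, 3_000_000)
        for i, (s, e) in enumerate(g_int):
            genes.append(
                Marker(name=f"{map_id}_g{i:03d}", start=float(s), end=float(e),
                       strand=str(rng.choice(["forward", "reverse"])),
                       kind="gene", accession=f"{map_id.upper()}G{i:03d}")
            )
        base = GenomeMap(
            map_id=map_id, species=bridge.species, chromosome=bridge.chromosome,
            units="bp", extent_min=1.0, extent_max=3_000_000.0,
            markers=tuple(genes), assembly_tag=bridge.assembly_tag,
        )
        from .synteny import transfer_markers

        return transfer_markers(bridge, base)

    asm5 = annotated(bridge3, "asm_fishA")
    asm6 = annotated(bridge4, "asm_fishB")

    published = simulate_linkage_map(bridge3, 3e-5, 0.4, seed + 1,
                                     map_id="published_linkage")
    published = GenomeMap(
        map_id=published.map_id, species="salmonid", chromosome="26",
        units="cM", extent_min=published.extent_min,
        extent_max=published.extent_max, markers=published.markers,
        title=published.title,
    )
    # private map: subset of the panel, same names, no accessions
    keep = sorted(rng.choice(n, size=8, replace=False))
    private_markers = [
        Marker(name=panel[i], start=float(published.markers[i].start),
               end=float(published.markers[i].start), kind="variant")
        for i in keep
    ]
    private = GenomeMap(
        map_id="private_qtl", species="salmonid", chromosome="26",
        units="cM", extent_min=0.0, extent_max=published.extent_max,
        markers=tuple(private_markers), title="private QTL linkage map",
    )

    maps = [private, published, bridge3, bridge4, asm5, asm6]
    paths = {}
    for gmap in maps:
        path = os.path.join(outdir, f"{gmap.map_id}.map")
        write_map_text(gmap, path)
        paths[gmap.map_id] = path

    from .layout import Placement

    canvas = Canvas(
        placements=[
            Placement("private_qtl", 0, 40, 120, 400,
                      private.extent_min, private.extent_max),
            Placement("published_linkage", 200, 40, 120, 400,
                      published.extent_min, published.extent_max),
            Placement("bridge_fishA", 400, 20, 120, 200, 1.0, 3_000_000.0),
            Placement("bridge_fishB", 420, 260, 120, 200, 1.0, 3_000_000.0),
            Placement("asm_fishA", 620, 20, 120, 200, 1.0, 3_000_000.0,
                      label_mode="linked_only"),
            Placement("asm_fishB", 640, 260, 120, 200, 1.0, 3_000_000.0,
                      label_mode="linked_only"),
        ]
    )
    layout_path = os.path.join(outdir, "layout.json")
    save_canvas_json(canvas, layout_path)

    truth = {
        "seed": seed,
        "rng": "numpy.default_rng",
        "maps": paths,
        "layout": layout_path,
        "columns": [["private_qtl"], ["published_linkage"],
                    ["bridge_fishA", "bridge_fishB"],
                    ["asm_fishA", "asm_fishB"]],
        "panel_size": n,
        "private_panel_size": len(keep),
    }
    with open(os.path.join(outdir, "truth.json"), "wt", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
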