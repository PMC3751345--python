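# comap

Comparative genetic/genomic map toolkit: load marker maps from files,
relate markers across maps by **identity** (shared stable accession),
**synonymy** (shared name) or tabulated **homology** (orthology/paralogy
with percent identity/similarity scores), discover regions of conserved
synteny from a homology table, map primer panels onto genomes by exact
in-silico PCR, lay maps out in virtual columns on a canvas, and render
aligned vertical maps with colour-coded relationship lines to SVG.

Every map is a self-contained coordinate system (bp, cM or arbitrary
units) for one chromosome or linkage group of one species, so genetic
linkage maps, physical assembly maps, ePCR bridge maps and ad-hoc local
maps can all be aligned side by side.

## Package layout

| module            | role |
|-------------------|------|
| `comap.model`     | `Marker`, `GenomeMap`, `MapRegion`; zoom/project (`subregion`), `reorient`, `validate_map` |
| `comap.formats`   | plain-text map dialect, map-interchange XML, GFF3/BED gene import, homology TSV |
| `comap.relations` | identity / synonymy / homology link discovery, score thresholds, CUD-safe palette |
| `comap.synteny`   | conserved-region search, crossing counts, marker transfer, in-silico PCR |
| `comap.layout`    | canvas placements, virtual columns, adjacency, map↔canvas coordinate transforms, label placement |
| `comap.render`    | scene construction and deterministic SVG 1.1 output |
| `comap.simulate`  | synthetic maps, genome pairs with implanted orthologous blocks, genomes with implanted amplicons — all seeded and regenerable |
| `comap.cli`       | `comap` command-line interface |

## CLI

```sh
comap convert in.map out.xml                  # text <-> XML; GFF3/BED import
comap link a.map b.map --homology h.tsv --min-identity 60 --out links.tsv
comap synteny --source cow.map --region cow_chr20:1-4500000 \
    --homology h.tsv --target-species human \
    --target-maps hum2.map --target-maps hum5.map --out-prefix out
comap draw layout.json *.map --out figure.svg [--no-links] [--label-mode none]
comap epcr primers.tsv genome.fa --out-prefix epcr_ --discard-report disc.tsv
comap simulate pair|sixmap|fasta ...          # synthetic data with truth JSON
```

Regions are written `MAPID:start-end` in the map's own units.  Canvas
layouts are JSON (`{"placements": [{"map_id": ..., "x": ..., "view_start":
...}], "style": {...}}`); omitted fields default, omitted `x` auto-tiles
left-to-right.

Relationship lines are drawn only between maps in **adjacent virtual
columns** — columns are the connected components of horizontal overlap
of map placements (closed intervals, ordered by minimum x) — so layout
controls which comparisons are shown.  Homology links can be filtered
by minimum percent identity and/or similarity; identity/synonymy links
always pass.  The default palette uses the Okabe–Ito colour-universal
design hex values and assigns a distinct colour per link type
(identity reddish-purple `#CC79A7`, synonymy sky-blue `#56B4E9`,
one-to-one orthology black, apparent one-to-one vermilion, one-to-many
orange, many-to-many blue-green, possible orthology blue, paralogy
yellow).

## File dialects

**Plain-text maps** — whitespace/tab-separated `name start [end]
[strand] [kind] [accession]` rows with `#`-prefixed headers:

```
#map 26 salmon cM
#id published_linkage
#extent 0.0 92.4
mk1    0.0
geneX  100 250 - gene ENSG0001
```

`+`/`-`/`.` strand, kinds from {gene, variant, microsatellite, sequence,
assembly_exception, generic}, `.` for "no accession"; a missing end makes
a point marker.

**XML maps** — a `<mapset>` root nesting `<species name=...>` →
`<map id title units chromosome extent_min extent_max [assembly]>` →
`<marker name start end strand kind [accession] [description]/>`.
This dialect is defined by this package (modelled on map-interchange
schemas; not claimed byte-compatible with any external schema).

**Homology TSV** — columns `gene_a species_a gene_b species_b
homology_type perc_identity perc_similarity`; records are symmetric, and
`homology_type` is one of ortholog_one2one, apparent_ortholog_one2one,
ortholog_one2many, ortholog_many2many, possible_ortholog, paralog.

**Primer panels** — TSV `name forward reverse min_product max_product`;
ePCR hits are exact matches, both orientations, with amplicon intervals
reported 1-based inclusive.  Pairs with zero or multiple hits, or hits
only on unplaced fragments (sequence names matching
`scaffold|contig|random|Un` by default), are discarded with a reason.

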