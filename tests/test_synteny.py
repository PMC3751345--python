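import itertools

import numpy as np
import pytest

from comap.formats import HomologyRecord, HomologyTable
from comap.model import GenomeMap, MapRegion, Marker
from comap.relations import make_link
from comap.simulate import BlockSpec, Implant, SimSpec, simulate_genome_fasta, simulate_genome_pair
from comap.synteny import (
    DiscardedPair,
    PrimerPair,
    SkippedGene,
    crossing_count,
    epcr_map,
    find_conserved_regions,
    transfer_markers,
)


def gene(name, start, end, acc):
    return Marker(name, float(start), float(end), kind="gene", accession=acc)


def bp_map(map_id, species, chromosome, markers, extent=1e6, assembly=None):
    return GenomeMap(map_id, species, chromosome, "bp", 0.0, float(extent),
                     tuple(markers), assembly_tag=assembly)


class TestFindConservedRegions:
    def make_case(self):
        source = bp_map(
            "cow20", "cow", "20",
            [gene(f"g{i}", i * 1000 + 1, i * 1000 + 500, f"g{i}")
             for i in range(1, 6)],
        )
        chr2 = bp_map(
            "hum2", "human", "2",
            [gene(f"h{i}", i * 2000 + 1, i * 2000 + 900, f"h{i}")
             for i in range(1, 5)],
        )
        chr7 = bp_map("hum7", "human", "7", [gene("h5", 100, 900, "h5")])
        records = [
            HomologyRecord(f"g{i}", "cow", f"h{i}", "human",
                           "ortholog_one2one", 80.0, 90.0)
            for i in range(1, 6)
        ]
        return source, [chr2, chr7], HomologyTable(records)

    def test_two_chromosomes_ranked_by_count(self):
        source, targets, table = self.make_case()
        regions = find_conserved_regions(
            source, MapRegion("cow20", 0.0, 1e6), table, "human", targets
        )
        assert [(r.target_chromosome, r.source_gene_count) for r in regions] \
            == [("2", 4), ("7", 1)]

    def test_span_covers_target_genes(self):
        source, targets, table = self.make_case()
        regions = find_conserved_regions(
            source, MapRegion("cow20", 0.0, 1e6), table, "human", targets
        )
        chr2 = regions[0]
        assert chr2.span_start == 2001.0
        assert chr2.span_end == 8900.0
        assert chr2.target_gene_accessions == {"h1", "h2", "h3", "h4"}
        assert len(chr2.links) == 4

    def test_empty_region(self):
        source, targets, table = self.make_case()
        regions = find_conserved_regions(
            source, MapRegion("cow20", 900000.0, 1e6), table, "human", targets
        )
        assert regions == []

    def test_target_gene_off_map_reported_not_fatal(self):
        source, targets, table = self.make_case()
        table = HomologyTable(table.records + [
            HomologyRecord("g1", "cow", "h99", "human", "paralog")
        ])
        skipped = []
        regions = find_conserved_regions(
            source, MapRegion("cow20", 0.0, 1e6), table, "human", targets,
            skipped=skipped,
        )
        assert len(regions) == 2
        assert skipped == [SkippedGene("g1", "h99")]

    def test_other_species_records_ignored(self):
        source, targets, table = self.make_case()
        table = HomologyTable(table.records + [
            HomologyRecord("g1", "cow", "m1", "mouse", "ortholog_one2one")
        ])
        regions = find_conserved_regions(
            source, MapRegion("cow20", 0.0, 1e6), table, "human", targets
        )
        assert sum(len(r.links) for r in regions) == 5

    def test_source_count_sums_match_brute_force_join(self, rng):
        # invariant: source_gene_count values sum to the number of
        # distinct (source gene, target chromosome) pairs with >= 1 record
        src, targets, table, truth = simulate_genome_pair(
            SimSpec(40, [BlockSpec(12, "preserved", "2"),
                         BlockSpec(10, "inverted", "5"),
                         BlockSpec(8, "preserved", "9")], seed=11)
        )
        regions = find_conserved_regions(
            src, MapRegion(src.map_id, src.extent_min, src.extent_max),
            table, "targetsp", targets,
        )
        located = {m.accession: t.chromosome for t in targets for m in t.markers}
        brute = set()
        for m in src.markers:
            for rec in table.lookup(m.accession):
                partner, sp = rec.partner_of(m.accession)
                if sp == "targetsp" and partner in located:
                    brute.add((m.accession, located[partner]))
        assert sum(r.source_gene_count for r in regions) == len(brute)

    def test_implanted_block_recovered_exactly(self):
        src, targets, table, truth = simulate_genome_pair(
            SimSpec(30, [BlockSpec(20, "preserved", "Z")], seed=5)
        )
        block = truth["blocks"][0]
        regions = find_conserved_regions(
            src, MapRegion(src.map_id, block["source_span"][0],
                           block["source_span"][1]),
            table, "targetsp", targets,
        )
        assert len(regions) == 1
        reg = regions[0]
        assert reg.target_gene_accessions == {t for _, t in block["pairs"]}
        assert [reg.span_start, reg.span_end] == block["target_span"]
        assert reg.source_gene_count == 20


class TestCrossingCount:
    def _links(self, a_positions, b_positions):
        links = []
        for i, (pa, pb) in enumerate(zip(a_positions, b_positions)):
            links.append(make_link(
                "L", Marker(f"la{i}", float(pa), float(pa)),
                "R", Marker(f"rb{i}", float(pb), float(pb)),
                "identity",
            ))
        return links

    def test_parallel_links(self):
        assert crossing_count(self._links([1, 2], [10, 20])) == 0

    def test_complete_inversion(self):
        for k in (2, 5, 10):
            links = self._links(range(k), range(k, 0, -1))
            assert crossing_count(links) == k * (k - 1) // 2

    def test_empty(self):
        assert crossing_count([]) == 0

    def test_brute_force_oracle(self, rng):
        # oracle: O(k^2) sign comparison over all unordered pairs
        for _ in range(30):
            k = int(rng.integers(2, 40))
            a = [float(x) for x in rng.integers(0, 25, size=k)]  # with ties
            b = [float(x) for x in rng.integers(0, 25, size=k)]
            links = self._links(a, b)
            expected = sum(
                1
                for i, j in itertools.combinations(range(k), 2)
                if np.sign(a[i] - a[j]) != np.sign(b[i] - b[j])
            )
            assert crossing_count(links) == expected

    def test_rejects_mixed_map_pairs(self):
        links = self._links([1], [2]) + [make_link(
            "L", Marker("x", 1, 1), "Q", Marker("y", 2, 2), "identity")]
        with pytest.raises(ValueError):
            crossing_count(links)


class TestTransferMarkers:
    def test_transfer_within_extent(self):
        src = bp_map("epcr", "cow", "1",
                     [Marker("a", 1.2e6, 1.2e6, accession="a"),
                      Marker("b", 3.4e6, 3.4e6, accession="b")],
                     extent=5e6, assembly="asmV1")
        dest = GenomeMap("asm", "cow", "1", "bp", 1e6, 4e6,
                         assembly_tag="asmV1")
        out = transfer_markers(src, dest)
        assert {m.name for m in out.markers} == {"a", "b"}
        assert len(dest.markers) == 0  # dest unmodified

    def test_outside_extent_not_transferred(self):
        src = bp_map("epcr", "cow", "1",
                     [Marker("far", 9e5, 9e5)], extent=5e6, assembly="asmV1")
        dest = GenomeMap("asm", "cow", "1", "bp", 1e6, 4e6,
                         assembly_tag="asmV1")
        assert len(transfer_markers(src, dest).markers) == 0

    def test_unit_mismatch(self):
        src = GenomeMap("lnk", "cow", "1", "cM", 0.0, 100.0,
                        assembly_tag="asmV1")
        dest = GenomeMap("asm", "cow", "1", "bp", 0.0, 1e6,
                         assembly_tag="asmV1")
        with pytest.raises(ValueError, match="incompatible"):
            transfer_markers(src, dest)

    def test_assembly_mismatch(self):
        src = GenomeMap("a", "cow", "1", "bp", 0.0, 1e6, assembly_tag="v1")
        dest = GenomeMap("b", "cow", "1", "bp", 0.0, 1e6, assembly_tag="v2")
        with pytest.raises(ValueError, match="incompatible"):
            transfer_markers(src, dest)

    def test_transfer_then_identity_links_round_trip(self):
        from comap.relations import identity_links

        src = bp_map("epcr", "cow", "1",
                     [Marker(f"m{i}", 1e5 * (i + 1), 1e5 * (i + 1),
                             accession=f"M{i}") for i in range(8)],
                     extent=1e6, assembly="asmV1")
        dest = GenomeMap("asm", "cow", "1", "bp", 0.0, 1e6,
                         assembly_tag="asmV1")
        merged = transfer_markers(src, dest)
        assert len(identity_links(merged, src)) == 8


REVCOMP = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(REVCOMP)[::-1]


class TestEpcr:
    PAIR = PrimerPair("p1", "ACGTACGTACGTACGTACGT", "TTGCATTGCATTGCATTGCA",
                      100, 1000)

    def _genome(self, tmp_path, sequences):
        path = tmp_path / "g.fa"
        with open(path, "w") as fh:
            for name, seq in sequences:
                fh.write(f">{name}\n{seq}\n")
        return path

    def _background(self, rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_implanted_site_recovered(self, rng, tmp_path):
        bg = self._background(rng, 10_000)
        amplicon = self.PAIR.forward + self._background(rng, 560) + rc(self.PAIR.reverse)
        seq = bg[:1000] + amplicon + bg[1000 + len(amplicon):]
        path = self._genome(tmp_path, [("chr1", seq)])
        maps, discards = epcr_map([self.PAIR], path)
        assert discards == []
        m = maps["chr1"].markers[0]
        assert (m.start, m.end) == (1001.0, 1000.0 + len(amplicon))
        assert m.kind == "sequence" and m.accession == "p1"

    def test_minus_strand_orientation_found(self, rng, tmp_path):
        bg = self._background(rng, 10_000)
        amplicon = self.PAIR.forward + self._background(rng, 400) + rc(self.PAIR.reverse)
        seq = bg[:2000] + rc(amplicon) + bg[2000 + len(amplicon):]
        path = self._genome(tmp_path, [("chr1", seq)])
        maps, discards = epcr_map([self.PAIR], path)
        assert discards == []
        assert len(maps["chr1"].markers) == 1

    def test_duplicate_implant_discarded(self, rng, tmp_path):
        amplicon = self.PAIR.forward + self._background(rng, 300) + rc(self.PAIR.reverse)
        bg = self._background(rng, 10_000)
        seq = bg[:1000] + amplicon + bg[:2000] + amplicon + bg[:1000]
        path = self._genome(tmp_path, [("chr1", seq)])
        maps, discards = epcr_map([self.PAIR], path)
        assert discards == [DiscardedPair("p1", "multiple_hits", 2)]
        assert len(maps["chr1"].markers) == 0

    def test_product_size_bound(self, rng, tmp_path):
        long_pair = PrimerPair("p1", self.PAIR.forward, self.PAIR.reverse,
                               100, 1000)
        amplicon = (long_pair.forward + self._background(rng, 1560)
                    + rc(long_pair.reverse))  # product 1600 > max 1000
        seq = self._background(rng, 2000) + amplicon + self._background(rng, 2000)
        path = self._genome(tmp_path, [("chr1", seq)])
        maps, discards = epcr_map([long_pair], path)
        assert discards == [DiscardedPair("p1", "no_hit", 0)]

    def test_unplaced_sequence_hit_discarded(self, rng, tmp_path):
        amplicon = self.PAIR.forward + self._background(rng, 300) + rc(self.PAIR.reverse)
        seq = self._background(rng, 1000) + amplicon + self._background(rng, 1000)
        path = self._genome(tmp_path, [("scaffold_12", seq)])
        maps, discards = epcr_map([self.PAIR], path)
        assert discards == [DiscardedPair("p1", "unplaced", 1)]
        assert maps == {}

    def test_non_acgt_primer_rejected(self):
        with pytest.raises(ValueError, match="A/C/G/T"):
            PrimerPair("bad", "ACGTN", "ACGT", 10, 100)

    def test_hits_equal_brute_force_scan(self, rng, tmp_path):
        # oracle: every position, both orientations, on a <= 50 kb sequence
        seq, truth = simulate_genome_fasta(
            30_000,
            [Implant(self.PAIR, 2_001, 1),
             Implant(PrimerPair("p2", "GGATCCGGATCCGGATCCAA",
                                "CCTAGGCCTAGGCCTAGGTT", 150, 450),
                     12_001, 2)],
            seed=99,
        )
        path = self._genome(tmp_path, [("chr1", seq)])
        pairs = [self.PAIR,
                 PrimerPair("p2", "GGATCCGGATCCGGATCCAA",
                            "CCTAGGCCTAGGCCTAGGTT", 150, 450)]
        maps, discards = epcr_map(pairs, path)

        def brute_hits(pair):
            hits = set()
            for left, right in ((pair.forward, rc(pair.reverse)),
                                (pair.reverse, rc(pair.forward))):
                for s in range(len(seq)):
                    if seq[s:s + len(left)] != left:
                        continue
                    for p in range(s, len(seq)):
                        if seq[p:p + len(right)] != right:
                            continue
                        length = p + len(right) - s
                        if pair.min_product <= length <= pair.max_product:
                            hits.add((s + 1, p + len(right)))
            return hits

        hits1 = brute_hits(pairs[0])
        assert len(hits1) == 1
        m = maps["chr1"].markers[0]
        assert (int(m.start), int(m.end)) in hits1
        assert len(brute_hits(pairs[1])) == 2
        assert discards == [DiscardedPair("p2", "multiple_hits", 2)]
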