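"""Junction extraction, back-splice classification, filtering and snapping."""

import pytest

from splicearc import (
    AlignedRead,
    GeneModel,
    GenomicInterval,
    JunctionSet,
    ScenarioSpec,
    SpliceJunction,
    classify_backsplice,
    extract_forward_junctions,
    filter_junctions,
    generate_locus,
    import_backsplice_bed,
    simulate_backsplice_bed,
    snap_to_exons,
    synthesize_read_set,
)
from splicearc.io import JunctionRecord
from splicearc.junctions import gap_to_donor_acceptor
from splicearc.model import BACK, FORWARD

from _oracles import tally_junctions


def region(start=0, end=10_000, strand="+"):
    return GenomicInterval("chr1", start, end, strand)


def read(pos, cigar, name="r"):
    return AlignedRead(name, "chr1", pos, tuple(cigar), "+", 60)


class TestExtractForwardJunctions:
    def test_single_gap_read_yields_one_junction(self):
        # 10M 50N 10M at pos 100: M 100..109, N 110..159, M 160..169
        js = extract_forward_junctions([read(100, [("M", 10), ("N", 50), ("M", 10)])], region())
        assert {k: v.count for k, v in js.junctions.items()} == {(109, 160): 1}

    def test_ungapped_read_yields_nothing(self):
        assert len(extract_forward_junctions([read(100, [("M", 20)])], region())) == 0

    def test_identical_gaps_aggregate_counts(self):
        reads = [read(100, [("M", 10), ("N", 50), ("M", 10)], f"r{i}") for i in range(2)]
        js = extract_forward_junctions(reads, region())
        assert js.junctions[(109, 160)].count == 2

    def test_gaps_below_min_intron_are_deletions(self):
        js = extract_forward_junctions(
            [read(100, [("M", 10), ("N", 19), ("M", 10)])], region()
        )
        assert len(js) == 0
        js = extract_forward_junctions(
            [read(100, [("M", 10), ("N", 19), ("M", 10)])], region(), min_intron=19
        )
        assert len(js) == 1

    def test_minus_strand_swaps_donor_acceptor_roles(self):
        js = extract_forward_junctions(
            [read(100, [("M", 10), ("N", 50), ("M", 10)])], region(strand="-")
        )
        (j,) = js
        assert (j.donor, j.acceptor) == (160, 109)
        assert classify_backsplice(j.donor, j.acceptor, "-") == FORWARD

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_brute_force_cigar_walk_on_simulated_scenarios(self, seed, strand):
        spec = ScenarioSpec(
            n_exons=3 + seed % 3, strand=strand, seed=seed,
            intron_len_range=(100, 300), depth=8.0,
        )
        gene = GeneModel.from_exons(
            spec.gene_name,
            [GenomicInterval(spec.chrom, 1000 + 300 * i, 1100 + 300 * i, strand)
             for i in range(spec.n_exons)],
        )
        reads, truth = synthesize_read_set(spec, gene)
        js = extract_forward_junctions(reads, gene.interval)
        got = {k: v.count for k, v in js.junctions.items()}
        assert got == tally_junctions(reads, strand, 20) == truth


class TestClassifyBacksplice:
    @pytest.mark.parametrize(
        "donor,acceptor,strand,expected",
        [
            (5000, 1000, "+", BACK),     # downstream donor to upstream acceptor
            (1000, 5000, "+", FORWARD),  # canonical downstream splice
            (1000, 5000, "-", BACK),     # mirrored on the minus strand
            (5000, 1000, "-", FORWARD),
            (5000, 1000, ".", BACK),     # unstranded falls back to '+' rule
        ],
    )
    def test_orientation_rule(self, donor, acceptor, strand, expected):
        assert classify_backsplice(donor, acceptor, strand) == expected

    def test_exon5_to_exon3_circle_is_back(self):
        """A donor at exon 5's end fused to exon 3's acceptor circularizes."""
        exons = [GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 100, "+")
                 for i in range(5)]
        donor = exons[4].end - 1
        acceptor = exons[2].start
        assert classify_backsplice(donor, acceptor, "+") == BACK


class TestImportBacksplice:
    @pytest.fixture()
    def gene(self):
        return GeneModel.from_exons(
            "G", [GenomicInterval("chr1", s, s + 100, "+") for s in (1000, 2000, 3000)]
        )

    def test_record_within_gene_becomes_back_junction(self, gene):
        rec = JunctionRecord("chr1", 1000, 3100, "circ", 9, "+")
        js = import_backsplice_bed([rec], gene)
        (j,) = js
        assert (j.donor, j.acceptor, j.kind, j.count) == (3099, 1000, BACK, 9)
        assert classify_backsplice(j.donor, j.acceptor, "+") == BACK

    def test_off_chromosome_and_off_gene_records_dropped(self, gene):
        recs = [
            JunctionRecord("chr2", 1000, 3100, "other", 5, "+"),
            JunctionRecord("chr1", 9000, 9500, "far", 5, "+"),
            JunctionRecord("chr1", 2000, 2100, "in", 5, "+"),
        ]
        assert len(import_backsplice_bed(recs, gene)) == 1

    def test_exon_block_span_lands_on_exon_edges(self, gene):
        """A circle spanning exons 2-3 has endpoints on those exon edges."""
        rec = JunctionRecord("chr1", 2000, 3100, "circ", 4, "+")
        (j,) = import_backsplice_bed([rec], gene)
        assert j.acceptor == gene.exons[1].start
        assert j.donor == gene.exons[2].end - 1


class TestFilterJunctions:
    def _set(self, counts):
        js = JunctionSet(region())
        for i, c in enumerate(counts):
            js.add(SpliceJunction("chr1", 100 + 1000 * i, 600 + 1000 * i, "+", c, FORWARD))
        return js

    def test_threshold_keeps_at_or_above(self):
        js = filter_junctions(self._set([3, 7, 1]), 2)
        assert sorted(j.count for j in js) == [3, 7]

    def test_zero_threshold_is_identity_and_input_unmodified(self):
        src = self._set([3, 7, 1])
        out = filter_junctions(src, 0)
        assert {k: v.count for k, v in out.junctions.items()} == {
            k: v.count for k, v in src.junctions.items()
        }
        filter_junctions(src, 100)
        assert len(src) == 3

    def test_threshold_above_max_empties_set(self):
        assert len(filter_junctions(self._set([3, 7, 1]), 8)) == 0

    def test_never_increases_count_mass(self):
        src = self._set([3, 7, 1])
        for t in range(0, 10):
            assert filter_junctions(src, t).total_count() <= src.total_count()


class TestSnapToExons:
    @pytest.fixture()
    def gene(self):
        return GeneModel.from_exons(
            "G", [GenomicInterval("chr1", s, s + 100, "+") for s in (1000, 2000, 3000)]
        )

    def _js(self, gene, donor, acceptor, count=5):
        js = JunctionSet(gene.interval)
        js.add(SpliceJunction("chr1", donor, acceptor, "+", count, FORWARD))
        return js

    def test_endpoint_near_exon_edge_snaps(self, gene):
        js = self._js(gene, 1099, 2002)  # acceptor 2 nt from exon start
        (j,) = snap_to_exons(js, gene, tolerance=5)
        assert (j.donor, j.acceptor, j.novel) == (1099, 2000, False)

    def test_tolerance_zero_is_identity(self, gene):
        js = self._js(gene, 1099, 2017)
        (j,) = snap_to_exons(js, gene, tolerance=0)
        assert (j.donor, j.acceptor, j.novel) == (1099, 2017, False)

    def test_far_endpoint_kept_verbatim_and_flagged_novel(self, gene):
        """A cryptic acceptor 20 nt inside an exon survives snapping intact."""
        js = self._js(gene, 1099, 2020)
        (j,) = snap_to_exons(js, gene, tolerance=5)
        assert (j.donor, j.acceptor, j.novel) == (1099, 2020, True)

    def test_count_mass_conserved_when_junctions_merge(self, gene):
        js = self._js(gene, 1099, 2002, count=3)
        js.add(SpliceJunction("chr1", 1097, 2000, "+", 4, FORWARD))
        out = snap_to_exons(js, gene, tolerance=5)
        assert out.total_count() == 7
        assert len(out) == 1  # both collapse onto (1099, 2000)


class TestSimulatedScenarios:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_linear_reads_give_consecutive_forward_junctions(
        self, tmp_path, seed, strand
    ):
        spec = ScenarioSpec(n_exons=4, strand=strand, seed=seed, depth=6.0)
        locus = generate_locus(spec, tmp_path / f"{strand}{seed}")
        reads, _ = synthesize_read_set(spec, locus.gene)
        js = extract_forward_junctions(reads, locus.gene.interval)
        edges = {
            (a.end - 1, b.start) if strand == "+" else (b.start, a.end - 1)
            for a, b in zip(locus.gene.exons, locus.gene.exons[1:])
        }
        assert js.junctions.keys() <= edges
        for j in js:
            assert classify_backsplice(j.donor, j.acceptor, strand) == FORWARD

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_backsplice_bed_junctions_all_classify_back(self, tmp_path, seed, strand):
        spec = ScenarioSpec(
            n_exons=4, strand=strand, seed=seed, backsplices=((0, 2, 7), (1, 1, 3))
        )
        locus = generate_locus(spec, tmp_path / f"{strand}{seed}")
        _, truth = simulate_backsplice_bed(spec, locus, tmp_path / f"b{strand}{seed}.bed")
        from splicearc import parse_junction_bed

        js = import_backsplice_bed(
            parse_junction_bed(tmp_path / f"b{strand}{seed}.bed"), locus.gene
        )
        assert {k: v.count for k, v in js.junctions.items()} == truth
        for j in js:
            assert j.kind == BACK
            assert classify_backsplice(j.donor, j.acceptor, strand) == BACK


def test_gap_to_donor_acceptor_orientation():
    assert gap_to_donor_acceptor(110, 160, "+") == (109, 160)
    assert gap_to_donor_acceptor(110, 160, "-") == (160, 109)
    assert gap_to_donor_acceptor(110, 160, ".") == (109, 160)
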