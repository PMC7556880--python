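"""Interval containers, BED round-trips, and interval arithmetic."""

import numpy as np
import pytest

from comotif.intervals_io import (
    BedParseError,
    ChromTable,
    GeneAnnot,
    GeneRecord,
    Interval,
    PeakSet,
    SequenceStore,
    ValidationError,
    assign_nearest_genes,
    extract_sequences,
    intersect,
    merge_replicates,
    read_bed,
    write_bed,
)


class TestBedIO:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\n")
        ps = read_bed(p)
        assert len(ps) == 1
        assert (ps[0].chrom, ps[0].start, ps[0].end) == ("chr1", 10, 20)

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t20\t10\n")
        with pytest.raises(ValidationError):
            read_bed(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr1\tten\t30\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_unsorted_input_sorted(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2\t5\t10\nchr1\t50\t60\nchr1\t5\t15\n")
        ps = read_bed(p)
        assert [(iv.chrom, iv.start) for iv in ps] == [("chr1", 5), ("chr1", 50), ("chr2", 5)]

    def test_strict_vs_lenient_unknown_chrom(self, tmp_path, small_chroms):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t10\t20\nchr1\t10\t20\n")
        with pytest.raises(ValidationError):
            read_bed(p, small_chroms, strict=True)
        ps = read_bed(p, small_chroms, strict=False)
        assert len(ps) == 1

    def test_roundtrip_identity(self, tmp_path, rng):
        ivs = []
        for i in range(100):
            s = int(rng.integers(0, 9000))
            e = s + int(rng.integers(1, 500))
            ivs.append(Interval("chr1", s, e, name=f"p{i}", strand="+" if i % 2 else "-"))
        ps = PeakSet("x", ivs)
        path = tmp_path / "r.bed"
        write_bed(ps, path)
        back = read_bed(path)
        assert [(iv.chrom, iv.start, iv.end, iv.name, iv.strand) for iv in back] == [
            (iv.chrom, iv.start, iv.end, iv.name, iv.strand) for iv in ps
        ]

    def test_empty_roundtrip(self, tmp_path):
        path = tmp_path / "e.bed"
        write_bed(PeakSet("e", []), path)
        assert len(read_bed(path)) == 0


class TestChromTable:
    def test_duplicate_name_rejected(self):
        with pytest.raises(ValidationError):
            ChromTable([("chr1", 100), ("chr1", 200)])

    def test_interval_beyond_bounds_rejected(self, small_chroms):
        with pytest.raises(ValidationError):
            PeakSet("x", [Interval("chr2", 4000, 6000)], small_chroms)

    def test_store_length_mismatch_rejected(self, small_chroms):
        with pytest.raises(ValidationError):
            SequenceStore({"chr1": "ACGT"}, small_chroms)


class TestMergeReplicates:
    def test_identical_replicates_kept(self, make_peakset):
        r = make_peakset("r", [("chr1", 10, 100)])
        merged = merge_replicates([r, r], min_support=2)
        assert [(iv.start, iv.end) for iv in merged] == [(10, 100)]

    def test_disjoint_replicates_dropped(self, make_peakset):
        r1 = make_peakset("r1", [("chr1", 0, 100)])
        r2 = make_peakset("r2", [("chr1", 200, 300)])
        assert len(merge_replicates([r1, r2], min_support=2)) == 0

    def test_overlapping_spans_merged(self, make_peakset):
        r1 = make_peakset("r1", [("chr1", 0, 100)])
        r2 = make_peakset("r2", [("chr1", 50, 150)])
        merged = merge_replicates([r1, r2], min_support=2)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 150)]

    def test_bookended_not_merged(self, make_peakset):
        r1 = make_peakset("r1", [("chr1", 0, 100)])
        r2 = make_peakset("r2", [("chr1", 100, 200)])
        assert len(merge_replicates([r1, r2], min_support=2)) == 0

    def test_min_support_validation(self, make_peakset):
        r = make_peakset("r", [("chr1", 0, 10)])
        with pytest.raises(ValidationError):
            merge_replicates([r], min_support=0)
        with pytest.raises(ValidationError):
            merge_replicates([r], min_support=2)

    def test_idempotent_on_merged_set(self, rng, make_peakset):
        triples = []
        for _ in range(200):
            s = int(rng.integers(0, 50_000))
            triples.append(("chr1", s, s + int(rng.integers(10, 400))))
        reps = [make_peakset("r1", triples[:100]), make_peakset("r2", triples[100:])]
        merged = merge_replicates(reps, min_support=2)
        again = merge_replicates([merged, merged], min_support=2)
        assert [(iv.start, iv.end) for iv in again] == [(iv.start, iv.end) for iv in merged]


class TestIntersect:
    def test_self_intersection_full(self, make_peakset):
        a = make_peakset("a", [("chr1", 0, 10), ("chr1", 20, 30)])
        _, frac = intersect(a, a)
        assert frac == 1.0

    def test_disjoint_chromosomes(self, make_peakset):
        a = make_peakset("a", [("chr1", 0, 10)])
        b = make_peakset("b", [("chr2", 0, 10)])
        overlap, frac = intersect(a, b)
        assert frac == 0.0 and len(overlap) == 0

    def test_manual_case(self, make_peakset):
        a = make_peakset("a", [("chr1", 0, 10), ("chr1", 20, 30)])
        b = make_peakset("b", [("chr1", 5, 8)])
        overlap, frac = intersect(a, b)
        assert [(iv.start, iv.end) for iv in overlap] == [(0, 10)]
        assert frac == 0.5

    def test_min_bp_counts_single_b_interval(self, make_peakset):
        a = make_peakset("a", [("chr1", 0, 10)])
        b = make_peakset("b", [("chr1", 8, 20)])
        assert intersect(a, b, min_bp=2)[1] == 1.0
        assert intersect(a, b, min_bp=3)[1] == 0.0

    def test_min_bp_validation(self, make_peakset):
        a = make_peakset("a", [("chr1", 0, 10)])
        with pytest.raises(ValidationError):
            intersect(a, a, min_bp=0)

    def test_monotone_in_b(self, rng, make_peakset):
        def rand_triples(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 100_000))
                out.append(("chr1", s, s + int(rng.integers(5, 300))))
            return out

        a = make_peakset("a", rand_triples(100))
        small = rand_triples(30)
        b_small = make_peakset("b", small)
        b_big = make_peakset("b", small + rand_triples(50))
        assert intersect(a, b_big)[1] >= intersect(a, b_small)[1]


def _make_annot(entries):
    records = []
    for gid, chrom, tss in entries:
        records.append(GeneRecord(gid, chrom, "+", tss, Interval(chrom, tss, tss + 1000)))
    return GeneAnnot(records)


class TestNearestGenes:
    def test_tss_inside_peak_fills_both_slots(self, make_peakset):
        genes = _make_annot([("g1", "chr1", 500)])
        peaks = make_peakset("p", [("chr1", 480, 520)])
        ng = assign_nearest_genes(peaks, genes)["p0"]
        assert (ng.upstream, ng.downstream) == ("g1", "g1")
        assert (ng.upstream_dist, ng.downstream_dist) == (0, 0)

    def test_flanking_distances(self, make_peakset):
        genes = _make_annot([("g1", "chr1", 100), ("g2", "chr1", 900)])
        peaks = make_peakset("p", [("chr1", 400, 410)])
        ng = assign_nearest_genes(peaks, genes)["p0"]
        assert (ng.upstream, ng.upstream_dist) == ("g1", 300)
        assert (ng.downstream, ng.downstream_dist) == ("g2", 490)

    def test_peak_left_of_all_genes(self, make_peakset):
        genes = _make_annot([("g1", "chr1", 5000)])
        peaks = make_peakset("p", [("chr1", 10, 20)])
        ng = assign_nearest_genes(peaks, genes)["p0"]
        assert ng.upstream is None and ng.downstream == "g1"

    def test_no_gene_on_chromosome(self, make_peakset):
        genes = _make_annot([("g1", "chr2", 100)])
        peaks = make_peakset("p", [("chr1", 10, 20)])
        ng = assign_nearest_genes(peaks, genes)["p0"]
        assert ng.upstream is None and ng.downstream is None

    def test_tie_broken_lexicographically(self, make_peakset):
        genes = _make_annot([("gB", "chr1", 100), ("gA", "chr1", 100)])
        peaks = make_peakset("p", [("chr1", 400, 410)])
        assert assign_nearest_genes(peaks, genes)["p0"].upstream == "gA"

    def test_agrees_with_brute_force(self, rng, make_peakset):
        genes = _make_annot(
            [(f"g{i:03d}", "chr1", int(rng.integers(0, 1_000_000))) for i in range(100)]
        )
        triples = []
        for _ in range(50):
            s = int(rng.integers(0, 999_000))
            triples.append(("chr1", s, s + int(rng.integers(10, 500))))
        peaks = make_peakset("p", triples)
        result = assign_nearest_genes(peaks, genes)
        for iv in peaks:
            inside = sorted(
                r.gene_id for r in genes if iv.start <= r.tss < iv.end
            )
            ng = result[iv.key]
            if inside:
                assert ng.upstream == ng.downstream == inside[0]
                continue
            ups = [(iv.start - r.tss, r.gene_id) for r in genes if r.tss <= iv.start]
            downs = [(r.tss - iv.end, r.gene_id) for r in genes if r.tss >= iv.end]
            if ups:
                d, g = min(ups)
                assert (ng.upstream, ng.upstream_dist) == (g, d)
            else:
                assert ng.upstream is None
            if downs:
                d, g = min(downs)
                assert (ng.downstream, ng.downstream_dist) == (g, d)
            else:
                assert ng.downstream is None


class TestExtractSequences:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(0, 4, "ACGT"), (4, 8, "ACGT"), (2, 6, "GTAC")],
    )
    def test_substrings(self, toy_store, make_peakset, start, end, expected):
        peaks = make_peakset("p", [("chr1", start, end)])
        assert extract_sequences(peaks, toy_store)["p0"] == expected

    def test_out_of_bounds(self, toy_store, make_peakset):
        peaks = make_peakset("p", [("chr1", 4, 12)])
        with pytest.raises(ValidationError):
            extract_sequences(peaks, toy_store)


class TestGeneAnnotIO:
    def test_tsv_roundtrip(self, tmp_path):
        annot = _make_annot([("g1", "chr1", 100), ("g2", "chr2", 50)])
        path = tmp_path / "genes.tsv"
        annot.write_tsv(path)
        back = GeneAnnot.read_tsv(path)
        assert back.gene_ids() == annot.gene_ids()
        assert back["g1"].tss == 100

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(ValidationError):
            _make_annot([("g1", "chr1", 100), ("g1", "chr1", 200)])
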