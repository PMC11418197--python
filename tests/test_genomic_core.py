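import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from v2gmap.genomic_core import (
    OCR,
    BedRecord,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    ParseError,
    SummaryStatRecord,
    distance_to_tss,
    intersect,
    nearest_gene,
    point_interval,
    promoter_windows,
    read_bed,
    read_gene_table,
    read_ocr_bed,
    read_summary_stats,
    write_bed,
    write_gene_table,
    write_ocr_bed,
    write_summary_stats,
)

from conftest import random_intervals


def brute_force_pairs(a, b):
    """O(n*m) overlap oracle."""
    return sorted(
        (i, j)
        for i, ai in enumerate(a)
        for j, bj in enumerate(b)
        if ai.chrom == bj.chrom and ai.start < bj.end and bj.start < ai.end
    )


class TestGenomicInterval:
    def test_valid(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.length == 100

    @pytest.mark.parametrize("start,end", [(200, 100), (100, 100), (-1, 5)])
    def test_invalid_bounds(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_empty_chrom_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 1)

    def test_half_open_boundary_no_overlap(self):
        assert not GenomicInterval("chr1", 10, 20).overlaps(GenomicInterval("chr1", 20, 30))

    def test_single_base_overlap(self):
        assert GenomicInterval("chr1", 10, 20).overlaps(GenomicInterval("chr1", 19, 30))

    def test_point_interval(self):
        iv = point_interval("chr1", 500)
        assert (iv.start, iv.end) == (500, 501)


class TestGeneModel:
    def test_multi_tss_sorted_deduplicated(self):
        g = GeneModel("G1", "S1", "chr1", "+", (300, 100, 300))
        assert g.tss_list == (100, 300)

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("G1", "S1", "chr1", "+", ())

    def test_bad_strand(self):
        with pytest.raises(ValueError):
            GeneModel("G1", "S1", "chr1", ".", (100,))


class TestBedIO:
    def test_bed3_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        (rec,) = read_bed(p)
        assert rec.interval == GenomicInterval("chr1", 100, 200)

    def test_inverted_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(p)

    def test_non_integer_error(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\tx\t200\n")
        with pytest.raises(ParseError, match=":1"):
            read_bed(p)

    def test_three_line_file_order_preserved(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t5\t10\nchr1\t1\t4\nchr2\t0\t9\n")
        recs = read_bed(p)
        assert [r.interval.start for r in recs] == [5, 1, 0]

    @pytest.mark.parametrize(
        "content",
        [
            "chr1\t100\t200\nchr2\t5\t10\n",  # BED3
            "chr1\t100\t200\tpeakA\t17\t+\nchr2\t5\t10\tpeakB\t0\t-\n",  # BED6
        ],
    )
    def test_round_trip_byte_identical(self, tmp_path, content):
        src = tmp_path / "in.bed"
        src.write_text(content)
        out = tmp_path / "out.bed"
        write_bed(read_bed(src), out)
        assert out.read_text() == content

    def test_gzip_transparent(self, tmp_path):
        import gzip

        p = tmp_path / "a.bed.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chr1\t1\t2\n")
        assert len(read_bed(p)) == 1

    def test_chr_prefix_normalization(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("1\t0\t5\n")
        (rec,) = read_bed(p, chr_prefix=True)
        assert rec.interval.chrom == "chr1"


class TestOcrIO:
    def test_round_trip(self, tmp_path):
        ocrs = [
            OCR("p1", GenomicInterval("chr1", 10, 300), frozenset({"unstim", "24h"}), 3),
            OCR("p2", GenomicInterval("chr1", 400, 900), frozenset({"8h"}), 2),
        ]
        p = tmp_path / "peaks.bed"
        write_ocr_bed(ocrs, p)
        back = read_ocr_bed(p)
        assert back == ocrs

    def test_no_timepoint_rejected(self):
        with pytest.raises(ValueError):
            OCR("p1", GenomicInterval("chr1", 0, 10), frozenset())


class TestGeneTable:
    def test_tsv_round_trip_one_based_conversion(self, tmp_path):
        genes = [GeneModel("G1", "S1", "chr1", "+", (999, 1999), "protein_coding")]
        p = tmp_path / "genes.tsv"
        write_gene_table(genes, p)
        assert "1000,2000" in p.read_text()
        assert read_gene_table(p) == genes

    def test_gtf_plus_strand_tss(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\ttranscript\t1001\t2000\t.\t+\t.\tgene_id "G1"; gene_name "S1";\n'
        )
        (g,) = read_gene_table(p)
        assert g.tss_list == (1000,)

    def test_gtf_minus_strand_tss(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\ttranscript\t1001\t2000\t.\t-\t.\tgene_id "G1";\n'
        )
        (g,) = read_gene_table(p)
        assert g.tss_list == (1999,)

    def test_gtf_two_transcripts_two_tss(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\ttranscript\t1001\t2000\t.\t+\t.\tgene_id "G1";\n'
            'chr1\tsrc\ttranscript\t5001\t6000\t.\t+\t.\tgene_id "G1";\n'
        )
        (g,) = read_gene_table(p)
        assert g.tss_list == (1000, 5000)

    def test_gtf_unknown_strand(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\ttranscript\t1\t10\t.\t?\t.\tgene_id "G1";\n')
        with pytest.raises(ParseError):
            read_gene_table(p)


class TestSummaryStats:
    def test_round_trip(self, tmp_path):
        recs = [
            SummaryStatRecord("rs1", "chr1", 999, 1e-8, "sentA", "T1D"),
            SummaryStatRecord("rs2", "chr1", 1200, 0.5, "sentA", "T1D", beta=0.1, se=0.02),
        ]
        p = tmp_path / "ss.tsv"
        write_summary_stats(recs, p)
        assert read_summary_stats(p) == recs

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_p(self, p):
        with pytest.raises(ValueError):
            SummaryStatRecord("rs1", "chr1", 10, p, "s", "t")


class TestPromoterWindows:
    def test_plus_strand(self):
        g = GeneModel("G1", "S", "chr1", "+", (10_000,))
        (w,) = promoter_windows(g)
        assert (w.interval.start, w.interval.end) == (8_500, 10_500)

    def test_minus_strand(self):
        g = GeneModel("G1", "S", "chr1", "-", (10_000,))
        (w,) = promoter_windows(g)
        assert (w.interval.start, w.interval.end) == (9_500, 11_500)

    def test_left_clip(self):
        g = GeneModel("G1", "S", "chr1", "+", (1_000,))
        (w,) = promoter_windows(g)
        assert (w.interval.start, w.interval.end) == (0, 1_500)

    def test_strand_unaware_mode(self):
        g = GeneModel("G1", "S", "chr1", "-", (10_000,))
        (w,) = promoter_windows(g, strand_aware=False)
        assert (w.interval.start, w.interval.end) == (8_500, 10_500)

    def test_window_contains_tss_and_length(self):
        g = GeneModel("G1", "S", "chr1", "+", (5_000, 9_000))
        ws = promoter_windows(g, chrom_length=100_000)
        assert len(ws) == 2
        for w in ws:
            assert w.interval.contains_point(w.tss)
            assert w.interval.length == 2_000

    def test_strand_flip_mirrors_offsets(self):
        plus = promoter_windows(GeneModel("G1", "S", "chr1", "+", (10_000,)))[0]
        minus = promoter_windows(GeneModel("G1", "S", "chr1", "-", (10_000,)))[0]
        assert 10_000 - plus.interval.start == minus.interval.end - 10_000
        assert plus.interval.end - 10_000 == 10_000 - minus.interval.start


class TestIntersect:
    def test_touching_intervals_do_not_overlap(self):
        a = [GenomicInterval("chr1", 10, 20)]
        b = [GenomicInterval("chr1", 20, 30)]
        assert intersect(a, b) == []

    def test_one_base_overlap(self):
        a = [GenomicInterval("chr1", 10, 20)]
        b = [GenomicInterval("chr1", 19, 30)]
        assert intersect(a, b) == [(0, 0)]

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(20):
            a = random_intervals(rng, int(rng.integers(1, 500)))
            b = random_intervals(rng, int(rng.integers(1, 500)))
            assert intersect(a, b) == brute_force_pairs(a, b)

    def test_symmetry(self, rng):
        a = random_intervals(rng, 100)
        b = random_intervals(rng, 100)
        forward = set(intersect(a, b))
        backward = {(i, j) for j, i in intersect(b, a)}
        assert forward == backward

    def test_unsorted_input_sorted_with_warning(self, rng, caplog):
        import logging

        a = random_intervals(rng, 50)
        b = random_intervals(rng, 50)
        with caplog.at_level(logging.WARNING, logger="v2gmap.genomic_core"):
            result = intersect(a, b)
        assert result == brute_force_pairs(a, b)

    @given(st.integers(0, 200), st.integers(1, 50), st.integers(0, 200), st.integers(1, 50))
    def test_overlap_symmetric_property(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        assert a.overlaps(b) == b.overlaps(a)
        assert a.overlaps(b) == (s1 < s2 + l2 and s2 < s1 + l1)


class TestDistanceAndNearest:
    def test_distance_zero_at_tss(self):
        g = GeneModel("G1", "S", "chr1", "+", (5_000,))
        assert distance_to_tss(5_000, g) == 0

    def test_min_over_tss(self):
        g = GeneModel("G1", "S", "chr1", "+", (1_000, 4_000))
        assert distance_to_tss(5_000, g) == 1_000

    def test_chrom_mismatch(self):
        g = GeneModel("G1", "S", "chr1", "+", (1_000,))
        with pytest.raises(ValueError):
            distance_to_tss(10, g, chrom="chr2")

    def test_distance_matches_enumeration(self, rng):
        for _ in range(50):
            tss = tuple(int(x) for x in rng.integers(0, 100_000, size=rng.integers(1, 4)))
            g = GeneModel("G1", "S", "chr1", "+", tss)
            pos = int(rng.integers(0, 100_000))
            assert distance_to_tss(pos, g) == min(abs(pos - t) for t in g.tss_list)

    def test_nearest_simple(self):
        g1 = GeneModel("A", "A", "chr1", "+", (100,))
        g2 = GeneModel("B", "B", "chr1", "+", (10_000,))
        assert nearest_gene(200, "chr1", [g1, g2]).gene_id == "A"

    def test_tie_break_lexicographic(self):
        g1 = GeneModel("B", "B", "chr1", "+", (100,))
        g2 = GeneModel("A", "A", "chr1", "+", (300,))
        assert nearest_gene(200, "chr1", [g1, g2]).gene_id == "A"

    def test_empty_chrom_errors(self):
        g = GeneModel("A", "A", "chr1", "+", (100,))
        with pytest.raises(ValueError):
            nearest_gene(5, "chrX", [g])

    def test_nearest_matches_exhaustive_scan(self, rng):
        genes = [
            GeneModel(f"G{i:03d}", f"S{i}", "chr1", "+",
                      tuple(int(x) for x in rng.integers(0, 1_000_000, size=2)))
            for i in range(30)
        ]
        for _ in range(50):
            pos = int(rng.integers(0, 1_000_000))
            got = nearest_gene(pos, "chr1", genes)
            best = min(genes, key=lambda g: (distance_to_tss(pos, g), g.gene_id))
            assert got.gene_id == best.gene_id


class TestIntervalSet:
    def test_merge_and_query(self):
        s = IntervalSet()
        s.add(10, 20)
        s.add(30, 40)
        s.add(18, 32)  # bridges both
        assert s.overlaps(15, 16)
        assert s.overlaps(39, 45)
        assert not s.overlaps(40, 50)
        assert not s.overlaps(0, 10)

    def test_random_against_bool_array(self, rng):
        s = IntervalSet()
        occupied = np.zeros(2_000, dtype=bool)
        for _ in range(200):
            a = int(rng.integers(0, 1_990))
            b = a + int(rng.integers(1, 10))
            s.add(a, b)
            occupied[a:b] = True
        for _ in range(500):
            a = int(rng.integers(0, 1_990))
            b = a + int(rng.integers(1, 10))
            assert s.overlaps(a, b) == bool(occupied[a:b].any())
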