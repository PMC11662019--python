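"""Interval algebra: parsing, merging, intersection and round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromkit.genome_intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    intersect,
    merge_intervals,
    read_gene_models,
    read_intervals,
    write_gene_models,
    write_intervals,
)


def iset(*spans, chrom="chr1"):
    return IntervalSet([GenomicInterval(chrom, s, e) for s, e in spans])


def spans(s):
    return sorted((iv.start, iv.end) for iv in s)


class TestGenomicInterval:
    def test_invariants(self):
        iv = GenomicInterval("chr1", 100, 200, name="p1", score=5.0)
        assert iv.width == 100
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)

    def test_half_open_overlap(self):
        a = GenomicInterval("chr1", 0, 10)
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))  # bookended
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))

    def test_genome_bounds_enforced(self):
        with pytest.raises(ValueError):
            IntervalSet([GenomicInterval("chr1", 0, 2000)], genome={"chr1": 1000})


class TestMerge:
    @pytest.mark.parametrize(
        "inputs,gap,expected",
        [
            ([(0, 10), (10, 20)], 0, [(0, 20)]),          # bookended merge
            ([(0, 10), (15, 20)], 4, [(0, 10), (15, 20)]),  # gap 5 > 4
            ([(0, 10), (15, 20)], 5, [(0, 20)]),          # gap 5 <= 5
            ([(5, 8)], 0, [(5, 8)]),                      # identity
            ([(0, 10), (2, 5)], 0, [(0, 10)]),            # nested
        ],
    )
    def test_gap_semantics(self, inputs, gap, expected):
        assert spans(merge_intervals(iset(*inputs), gap)) == expected

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals(iset((0, 10)), -1)

    @given(
        st.lists(
            st.tuples(st.integers(0, 990), st.integers(1, 60)), min_size=1, max_size=50
        ),
        st.integers(0, 20),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_merge_idempotent_and_covers_union(self, raw, gap):
        s = iset(*[(a, a + w) for a, w in raw])
        once = merge_intervals(s, gap)
        twice = merge_intervals(once, gap)
        assert spans(once) == spans(twice)
        if gap == 0:
            # union of covered bases preserved exactly at gap 0
            occ = np.zeros(1100, bool)
            for a, w in raw:
                occ[a : a + w] = True
            merged_occ = np.zeros(1100, bool)
            for a, b in spans(once):
                merged_occ[a:b] = True
            assert np.array_equal(occ, merged_occ)


class TestIntersect:
    def test_one_base_overlap_counts(self):
        assert spans(intersect(iset((0, 10)), iset((9, 20)), "report_a")) == [(0, 10)]

    def test_bookended_is_no_overlap(self):
        assert spans(intersect(iset((0, 10)), iset((10, 20)), "report_a")) == []

    def test_exclude_mode(self):
        out = intersect(iset((0, 5), (20, 30)), iset((21, 22)), "exclude_a")
        assert spans(out) == [(0, 5)]

    def test_count_mode(self):
        counts = intersect(iset((0, 10), (50, 60)), iset((2, 4), (5, 8), (55, 56)), "count")
        assert counts.tolist() == [2, 1]

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            intersect(iset((0, 1)), iset((0, 1)), "bogus")

    @given(
        st.lists(st.tuples(st.integers(0, 950), st.integers(1, 50)), min_size=1, max_size=50),
        st.lists(st.tuples(st.integers(0, 950), st.integers(1, 50)), min_size=0, max_size=50),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_against_per_base_occupancy(self, raw_a, raw_b):
        a = iset(*[(x, x + w) for x, w in raw_a])
        b = iset(*[(x, x + w) for x, w in raw_b])
        occ = np.zeros(1000, bool)
        for x, w in raw_b:
            occ[x : x + w] = True
        expect_report = sorted(
            (iv.start, iv.end) for iv in a if occ[iv.start : iv.end].any()
        )
        got_report = spans(intersect(a, b, "report_a"))
        got_exclude = spans(intersect(a, b, "exclude_a"))
        assert got_report == expect_report
        # report_a and exclude_a partition a
        assert sorted(got_report + got_exclude) == spans(a)


class TestIO:
    def test_bed_parsing_and_roundtrip(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\tp1\t5.0\nchr2\t0\t50\tp2\t.\t-\n")
        s = read_intervals(p)
        assert s[0].score == 5.0 and s[0].name == "p1"
        assert s[1].strand == "-" and s[1].score is None
        out = tmp_path / "y.bed"
        write_intervals(s, out)
        assert read_intervals(out) == s

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_intervals(p)) == 0
        write_intervals(IntervalSet(), tmp_path / "out.bed")
        assert (tmp_path / "out.bed").read_text() == ""

    def test_coordinate_error_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError, match="line 1"):
            read_intervals(p)

    def test_malformed_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\nchr1\tnope\t5\n")
        with pytest.raises(ValueError, match="line 2"):
            read_intervals(p)

    def test_track_lines_skipped_and_extra_preserved(self, tmp_path):
        p = tmp_path / "np.narrowPeak"
        p.write_text(
            "track name=peaks\nchr1\t10\t90\tpk1\t100\t.\t5.5\t3.2\t2.1\t40\n"
        )
        s = read_intervals(p, format="narrowPeak")
        assert len(s) == 1 and s[0].extra == ("5.5", "3.2", "2.1", "40")
        out = tmp_path / "out.bed"
        write_intervals(s, out)
        assert read_intervals(out)[0].extra == s[0].extra

    def test_tsv_roundtrip(self, tmp_path):
        s = iset((0, 10), (5, 25))
        write_intervals(s, tmp_path / "x.tsv", format="tsv")
        assert read_intervals(tmp_path / "x.tsv", format="tsv") == s

    def test_strand_dot_preserved(self, tmp_path):
        s = IntervalSet([GenomicInterval("chr1", 0, 5, name="a", score=1.0, strand=".")])
        write_intervals(s, tmp_path / "s.bed")
        assert read_intervals(tmp_path / "s.bed")[0].strand == "."


class TestGeneModel:
    def test_validation(self):
        exons = (GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400))
        g = GeneModel("g1", "chr1", "+", 100, exons)
        assert g.length_kb == pytest.approx(0.2)
        assert (g.span.start, g.span.end) == (100, 400)
        with pytest.raises(ValueError, match="TSS"):
            GeneModel("g2", "chr1", "+", 500, exons)
        with pytest.raises(ValueError, match="overlap"):
            GeneModel("g3", "chr1", "+", 100,
                      (GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 300)))

    def test_promoter_clipping(self):
        g = GeneModel("g1", "chr1", "+", 1000, (GenomicInterval("chr1", 1000, 3000),))
        w = g.promoter(2000)
        assert (w.start, w.end) == (0, 3000)

    def test_tsv_roundtrip(self, tmp_path):
        genes = [
            GeneModel("g1", "chr1", "+", 100, (GenomicInterval("chr1", 100, 200),)),
            GeneModel("g2", "chr2", "-", 899, (GenomicInterval("chr2", 500, 900),)),
        ]
        write_gene_models(genes, tmp_path / "g.tsv")
        back = read_gene_models(tmp_path / "g.tsv")
        assert [g.gene_id for g in back] == ["g1", "g2"]
        assert back[1].tss == 899 and back[1].strand == "-"
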