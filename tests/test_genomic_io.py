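import numpy as np
import pytest

from oct4expr.genomic_io import (GeneAnnotation, NoPeakInPromoter, Peak,
                                 extract_peak_features, join_expression,
                                 peaks_from_signal, promoter_window,
                                 read_bedgraph, read_gene_annotation,
                                 read_narrowpeak, select_strongest,
                                 PeakFeatures, features_to_frame)
import pandas as pd


class TestReadBedgraph:
    def test_single_line(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1 100 200 5.0\n")
        assert read_bedgraph(p) == [("chr1", 100, 200, 5.0)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bedgraph"
        p.write_text("")
        assert read_bedgraph(p) == []

    def test_track_line_skipped(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("track type=bedGraph\nchr1 0 10 1.5\nchr1 10 20 2.5\n")
        assert read_bedgraph(p) == [("chr1", 0, 10, 1.5), ("chr1", 10, 20, 2.5)]

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_bedgraph(tmp_path / "nope.bedgraph")

    def test_bad_value_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1 0 10 1.0\nchr1 10 20 oops\n")
        with pytest.raises(ValueError, match=":2"):
            read_bedgraph(p)


class TestReadAnnotation:
    def test_bed6_plus_strand_tss(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t1000\t2000\tg1\t0\t+\n")
        (g,) = read_gene_annotation(p)
        assert g.tss == 1000 and g.strand == "+"

    def test_bed6_minus_strand_tss(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t1000\t2000\tg1\t0\t-\n")
        (g,) = read_gene_annotation(p)
        assert g.tss == 1999

    def test_duplicate_gene_fatal(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t10\tg1\t0\t+\nchr1\t50\t60\tg1\t0\t+\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gene_annotation(p)

    def test_unknown_strand_fatal(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t10\tg1\t0\t*\n")
        with pytest.raises(ValueError, match="strand"):
            read_gene_annotation(p)

    def test_gtf_gene_features(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\tgene\t3001\t4000\t.\t-\t.\tgene_id "g2";\n'
        )
        genes = read_gene_annotation(p, format="gtf")
        assert [(g.gene_id, g.tss, g.strand) for g in genes] == [
            ("g1", 1000, "+"), ("g2", 3999, "-")]


class TestPromoterWindow:
    @pytest.mark.parametrize("strand,expected", [("+", (8500, 10500)),
                                                 ("-", (9500, 11500))])
    def test_window_by_strand(self, strand, expected):
        g = GeneAnnotation("g", "chr1", 10000, strand)
        w = promoter_window(g)
        assert (w.start, w.end) == expected
        assert w.end - w.start == 2000

    def test_clipping_at_chromosome_start(self):
        g = GeneAnnotation("g", "chr1", 1000, "+")
        w = promoter_window(g)
        assert (w.start, w.end) == (0, 1500) and w.clipped

    def test_strand_reversal_reflects_about_tss(self):
        plus = promoter_window(GeneAnnotation("g", "c", 50000, "+"))
        minus = promoter_window(GeneAnnotation("g", "c", 50000, "-"))
        assert plus.end - 50000 == 50000 - minus.start
        assert 50000 - plus.start == minus.end - 50000


class TestPeaksFromSignal:
    def _window(self):
        return promoter_window(GeneAnnotation("g", "chr1", 10000, "+"))

    def test_flat_track_empty(self):
        track = [("chr1", 8000, 11000, 0.0)]
        assert peaks_from_signal(track, self._window()) == []

    def test_rectangular_block(self):
        track = [("chr1", 9000, 9200, 7.0)]
        (pk,) = peaks_from_signal(track, self._window())
        assert (pk.start, pk.end, pk.height) == (9000, 9200, 7.0)

    def test_two_blocks_split_by_gap(self):
        track = [("chr1", 9000, 9100, 5.0), ("chr1", 9100, 9200, 0.2),
                 ("chr1", 9200, 9300, 6.0)]
        peaks = peaks_from_signal(track, self._window(), min_height=1.0)
        assert [(p.start, p.end, p.height) for p in peaks] == [
            (9000, 9100, 5.0), (9200, 9300, 6.0)]

    def test_window_intersection_clips_run(self):
        track = [("chr1", 8000, 9000, 3.0)]
        (pk,) = peaks_from_signal(track, self._window())
        assert (pk.start, pk.end) == (8500, 9000)


class TestExtractFeatures:
    def test_stated_formulas(self):
        pk = Peak("chr1", 9000, 9200, 7.0)
        g = GeneAnnotation("g", "chr1", 10000, "+")
        assert extract_peak_features(pk, g) == (7.0, 900, 200)

    def test_peak_centered_on_tss(self):
        pk = Peak("chr1", 9900, 10100, 2.0)
        g = GeneAnnotation("g", "chr1", 10000, "+")
        assert extract_peak_features(pk, g)[1] == 0


class TestSelectStrongest:
    def test_max_height_wins(self):
        peaks = [Peak("c", 0, 10, 3.0), Peak("c", 20, 30, 9.0), Peak("c", 40, 50, 5.0)]
        assert select_strongest(peaks).height == 9.0

    def test_single_peak_identity(self):
        pk = Peak("c", 0, 10, 1.0)
        assert select_strongest([pk]) is pk

    def test_height_tie_broken_by_distance(self):
        near = Peak("c", 900, 1100, 9.0)   # midpoint 1000, D=100 from tss 1100
        far = Peak("c", 1400, 1600, 9.0)   # midpoint 1500, D=400
        assert select_strongest([far, near], tss=1100) is near

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        peaks = [Peak("c", int(s), int(s) + 50, float(h))
                 for s, h in zip(rng.integers(0, 5000, 12) * 2,
                                 rng.choice([1.0, 2.0, 3.0], 12))]
        ref = select_strongest(peaks, tss=2000)
        for _ in range(5):
            rng.shuffle(peaks)
            assert select_strongest(peaks, tss=2000) == ref

    def test_empty_signals_no_peak(self):
        with pytest.raises(NoPeakInPromoter):
            select_strongest([])


class TestJoinExpression:
    def _features(self, n=8):
        return [PeakFeatures(f"g{i}", 0, 1.0, 10, 100) for i in range(n)]

    def _expr(self, n=8):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                             "day": 0, "expression": np.arange(n, dtype=float)})

    def test_complete_join(self):
        recs = join_expression(self._features(8), self._expr(8))
        assert len(recs) == 8
        assert [r.gene_id for r in recs] == sorted(r.gene_id for r in recs)

    def test_inner_join_drops_unmatched(self):
        recs = join_expression(self._features(8), self._expr(7))
        assert len(recs) == 7

    def test_disjoint_keys_empty(self):
        expr = self._expr(3)
        expr["gene_id"] = ["x1", "x2", "x3"]
        assert join_expression(self._features(3), expr) == []

    def test_duplicate_keys_fatal(self):
        feats = self._features(2) + [PeakFeatures("g0", 0, 2.0, 5, 50)]
        with pytest.raises(ValueError, match="duplicate"):
            join_expression(feats, self._expr(2))


def test_narrowpeak_reader(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chr1\t100\t300\tpeak1\t0\t.\t7.5\t-1\t-1\t50\n"
                 "chr1\t400\t500\tpeak2\t0\t.\t2.0\t-1\t-1\t-1\n")
    peaks = read_narrowpeak(p)
    assert peaks[0].height == 7.5 and peaks[0].summit == 150
    assert peaks[1].summit is None
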