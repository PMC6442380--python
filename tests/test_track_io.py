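"""Binned-track data model and bedGraph/BED round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cohesin_occupancy.track_io import (BinnedTrack, Feature, FeatureSet,
                                        TrackIOError, read_bed, read_bedgraph,
                                        read_chrom_sizes, write_bed,
                                        write_bedgraph, write_chrom_sizes)

from conftest import make_track


class TestBinnedTrack:
    def test_bin_vector_length_must_match_ceil_rule(self):
        with pytest.raises(ValueError):
            BinnedTrack(50, {"c": 120}, {"c": np.zeros(2)})  # needs 3 bins
        t = BinnedTrack(50, {"c": 120}, {"c": np.zeros(3)})
        assert t.bin_capacity("c", 2) == 20
        assert t.bin_capacity("c", 0) == 50

    def test_default_values_are_zero(self):
        t = BinnedTrack(10, {"c": 100})
        assert t.all_values().sum() == 0.0


class TestBedgraph:
    def test_full_bin_coverage(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\t2.0\n")
        t = read_bedgraph(p, 50, {"chr1": 200})
        assert list(t.values["chr1"]) == [2.0, 2.0, 0.0, 0.0]

    def test_partial_coverage_is_length_weighted(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t25\t75\t4.0\n")
        t = read_bedgraph(p, 50, {"chr1": 100})
        assert list(t.values["chr1"]) == [2.0, 2.0]

    def test_empty_file_gives_zero_track(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("")
        t = read_bedgraph(p, 50, {"chr1": 100})
        assert not t.all_values().any()

    def test_overlapping_intervals_rejected(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t60\t1.0\nchr1\t50\t100\t2.0\n")
        with pytest.raises(TrackIOError, match="overlap"):
            read_bedgraph(p, 50, {"chr1": 100})

    def test_interval_beyond_chromosome_rejected(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t50\t150\t1.0\n")
        with pytest.raises(TrackIOError, match="outside"):
            read_bedgraph(p, 50, {"chr1": 100})

    def test_writer_merges_equal_runs_and_groups_chromosomes(self, tmp_path):
        t = make_track({"c1": [1.0, 1.0, 0.0], "c2": [2.0]})
        p = tmp_path / "t.bedgraph"
        write_bedgraph(t, p)
        lines = p.read_text().splitlines()
        assert lines == ["c1\t0\t100\t1", "c1\t100\t150\t0", "c2\t0\t50\t2"]

    def test_zero_suppression(self, tmp_path):
        t = make_track({"c1": [0.0, 3.0, 0.0]})
        p = tmp_path / "t.bedgraph"
        write_bedgraph(t, p, suppress_zeros=True)
        assert p.read_text().splitlines() == ["c1\t50\t100\t3"]

    @settings(max_examples=50, deadline=None)
    @given(values=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1,
                           max_size=60),
           trim=st.integers(0, 49))
    def test_round_trip_is_exact(self, tmp_path_factory, values, trim):
        # chromosome length deliberately not always a bin multiple
        tmp = tmp_path_factory.mktemp("rt")
        length = len(values) * 50 - trim  # last bin may be partial
        t = make_track({"c": values}, lengths={"c": length})
        p = tmp / "t.bedgraph"
        write_bedgraph(t, p)
        back = read_bedgraph(p, 50, {"c": length})
        np.testing.assert_allclose(back.values["c"], t.values["c"],
                                   rtol=0, atol=1e-12)


class TestBed:
    def test_promoter_anchor_follows_strand(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t100\t600\tp1\t0\t+\nchr1\t100\t600\tp2\t0\t-\n")
        fs = read_bed(p, "promoter")
        assert fs[0].anchor == 100
        assert fs[1].anchor == 599

    def test_bed3_gets_midpoint_anchor_and_dot_strand(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("chr1\t100\t600\n")
        fs = read_bed(p, "enhancer")
        assert fs[0].anchor == 350
        assert fs[0].strand == "."

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\tnope\t100\n")
        with pytest.raises(TrackIOError, match=":2"):
            read_bed(p, "enhancer")

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(TrackIOError):
            read_bed(p, "enhancer")

    def test_write_read_round_trip_preserves_features(self, tmp_path):
        feats = [Feature("c", 10, 510, "+", "promoter", "p1"),
                 Feature("c", 700, 1200, "-", "promoter", "p2"),
                 Feature("c", 2000, 2500, ".", "enhancer", "e1")]
        p = tmp_path / "f.bed"
        write_bed(feats, p)
        back = read_bed(p, "promoter", {"c": 5000})
        assert [(f.start, f.end, f.strand) for f in back] == \
            [(10, 510, "+"), (700, 1200, "-"), (2000, 2500, ".")]
        # strand-aware anchors reconstructed from coordinates alone
        assert back[0].anchor == 10
        assert back[1].anchor == 1199

    def test_feature_outside_declared_genome_rejected(self):
        with pytest.raises(TrackIOError):
            FeatureSet([Feature("c", 0, 100)], {"c": 50})
        with pytest.raises(TrackIOError):
            FeatureSet([Feature("missing", 0, 100)], {"c": 500})


def test_chrom_sizes_round_trip(tmp_path):
    p = tmp_path / "g.sizes"
    write_chrom_sizes({"chr2L": 123, "chr2R": 456}, p)
    assert read_chrom_sizes(p) == {"chr2L": 123, "chr2R": 456}
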