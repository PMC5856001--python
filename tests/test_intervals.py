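"""Interval model, BED I/O, overlap arithmetic, binning and profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsbpred import (
    Genome,
    GenomicInterval,
    IntervalSet,
    average_profile,
    bin_genome,
    intersect_replicates,
    label_intervals,
    overlap_fraction,
    read_bed,
    write_bed,
)
from dsbpred.intervals import BedParseError


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def per_base_coverage_fraction(site, track):
    """Oracle: boolean per-base coverage count."""
    covered = np.zeros(site.length, dtype=bool)
    for t in track:
        if t.chrom != site.chrom:
            continue
        lo, hi = max(t.start, site.start), min(t.end, site.end)
        if hi > lo:
            covered[lo - site.start : hi - site.start] = True
    return covered.mean()


class TestGenomicInterval:
    def test_valid_interval_has_positive_length(self):
        x = iv(100, 600)
        assert x.length == 500

    @pytest.mark.parametrize("start,end", [(600, 100), (100, 100), (-5, 10)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            iv(start, end)


class TestReadBed:
    def test_basic_parse_and_header_skip(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nchr1\t100\t600\nchr2\t0\t50\tpeak2\t7.5\n")
        s = read_bed(p)
        assert len(s) == 2
        assert s[0].length == 500
        assert s[1].name == "peak2" and s[1].score == 7.5

    def test_reversed_coordinates_raise_with_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t600\t100\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_bed(p)

    def test_non_integer_coordinate_raises(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\tx\t100\n")
        with pytest.raises(BedParseError):
            read_bed(p)

    def test_unknown_chromosome_rejected_when_genome_given(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t0\t10\n")
        genome = Genome({"chr1": 1000})
        with pytest.raises(BedParseError, match="chrZ"):
            read_bed(p, genome)

    def test_roundtrip_via_writer(self, tmp_path):
        s = IntervalSet([iv(5, 10), iv(100, 200, "chr2")])
        path = tmp_path / "out.bed"
        write_bed(s, path)
        assert read_bed(path) == s


class TestCanonicalization:
    def test_sorted_and_deduplicated(self):
        s = IntervalSet([iv(50, 60), iv(10, 20), iv(50, 60), iv(5, 8, "chr0")])
        coords = [(x.chrom, x.start, x.end) for x in s]
        assert coords == [("chr0", 5, 8), ("chr1", 10, 20), ("chr1", 50, 60)]


class TestIntersectReplicates:
    def test_identical_sets_returned_unchanged(self):
        a = IntervalSet([iv(100, 600), iv(1000, 1400)])
        assert intersect_replicates(a, a) == a

    def test_disjoint_sets_empty(self):
        a = IntervalSet([iv(0, 100)])
        b = IntervalSet([iv(500, 600)])
        assert len(intersect_replicates(a, b)) == 0

    def test_partial_overlap_keep_vs_clip(self):
        rep1 = IntervalSet([iv(100, 600)])
        rep2 = IntervalSet([iv(500, 800)])
        keep = intersect_replicates(rep1, rep2, clip=False)
        assert [(x.start, x.end) for x in keep] == [(100, 600)]
        clip = intersect_replicates(rep1, rep2, clip=True)
        assert [(x.start, x.end) for x in clip] == [(500, 600)]

    def test_result_never_larger_than_rep1(self, rng):
        rep1 = IntervalSet([iv(int(s), int(s) + 50) for s in rng.integers(0, 5000, 40)])
        rep2 = IntervalSet([iv(int(s), int(s) + 30) for s in rng.integers(0, 5000, 40)])
        assert len(intersect_replicates(rep1, rep2)) <= len(rep1)


class TestOverlapFraction:
    def test_sixty_percent_coverage(self):
        assert overlap_fraction(iv(100, 600), IntervalSet([iv(200, 500)])) == 0.6

    def test_extremes(self):
        site = iv(100, 600)
        assert overlap_fraction(site, IntervalSet()) == 0.0
        assert overlap_fraction(site, IntervalSet([iv(0, 1000)])) == 1.0

    def test_split_invariance(self):
        site = iv(100, 600)
        split = IntervalSet([iv(200, 350), iv(350, 500)])
        assert overlap_fraction(site, split) == 0.6

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        start=st.integers(0, 500),
        length=st.integers(1, 400),
        pieces=st.lists(st.tuples(st.integers(0, 900), st.integers(1, 200)), max_size=12),
    )
    def test_matches_per_base_oracle(self, start, length, pieces):
        site = iv(start, start + length)
        track = IntervalSet([iv(s, s + l) for s, l in pieces])
        assert overlap_fraction(site, track) == pytest.approx(
            per_base_coverage_fraction(site, track)
        )


class TestBinGenome:
    def test_exact_tiling(self):
        g = Genome({"chr1": 1000})
        bins = bin_genome(g, 250)
        assert len(bins) == 4
        assert all(b.length == 250 for b in bins)

    def test_trailing_partial_bin_truncated(self):
        g = Genome({"chr1": 1001})
        bins = bin_genome(g, 250)
        assert len(bins) == 5
        assert bins[-1].length == 1

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            bin_genome(Genome({"chr1": 100}), 0)

    def test_total_bin_length_conserves_genome_size(self):
        g = Genome({"chr1": 1234, "chr2": 777})
        assert bin_genome(g, 250).total_length == g.total_size


class TestLabelIntervals:
    def test_fully_covered_bins_all_positive(self):
        bins = bin_genome(Genome({"chr1": 1000}), 250)
        labels = label_intervals(bins, IntervalSet([iv(0, 1000)]))
        assert labels.tolist() == [1, 1, 1, 1]

    def test_disjoint_all_negative(self):
        bins = bin_genome(Genome({"chr1": 1000}), 250)
        labels = label_intervals(bins, IntervalSet([iv(0, 10, "chr2")]))
        assert labels.tolist() == [0, 0, 0, 0]

    def test_boundary_straddling_dsb_hits_two_bins(self):
        bins = bin_genome(Genome({"chr1": 1000}), 250)
        labels = label_intervals(bins, IntervalSet([iv(240, 260)]))
        assert labels.tolist() == [1, 1, 0, 0]

    def test_agrees_with_all_pairs_bruteforce(self, rng):
        regions = IntervalSet(
            [iv(int(s), int(s) + int(l)) for s, l in
             zip(rng.integers(0, 9000, 200), rng.integers(1, 300, 200))]
        )
        dsb = IntervalSet(
            [iv(int(s), int(s) + int(l)) for s, l in
             zip(rng.integers(0, 9000, 50), rng.integers(1, 500, 50))]
        )
        brute = np.array(
            [int(any(r.overlaps(d) for d in dsb)) for r in regions], dtype=np.int8
        )
        assert label_intervals(regions, dsb).tolist() == brute.tolist()


class TestAverageProfile:
    def test_signal_at_centers_peaks_centrally(self, flat_genome):
        sites = IntervalSet([iv(c - 200, c + 200) for c in (5000, 10000, 15000)])
        signal = IntervalSet([iv(c - 10, c + 10) for c in (5000, 10000, 15000)])
        prof = average_profile(signal, sites, flat_genome, flank=1000, bin=100)
        center_bins = np.abs(prof.bin_offsets) < 100
        assert prof.values[center_bins].sum() > 0
        assert prof.values[~center_bins].sum() == 0

    def test_uniform_signal_gives_flat_profile(self, flat_genome):
        sites = IntervalSet([iv(5000, 5400), iv(12000, 12400)])
        signal = IntervalSet([iv(0, 20_000)])
        prof = average_profile(signal, sites, flat_genome, flank=1000, bin=100)
        assert np.allclose(prof.values, 1.0)

    def test_shifted_signal_moves_argmax(self, flat_genome):
        centers = (5000, 10000, 15000)
        sites = IntervalSet([iv(c - 200, c + 200) for c in centers])
        signal = IntervalSet([iv(c + 90, c + 110) for c in centers])
        prof = average_profile(signal, sites, flat_genome, flank=1000, bin=50)
        assert prof.bin_offsets[np.argmax(prof.values)] == pytest.approx(100, abs=50)

    def test_offsets_symmetric_about_zero(self, flat_genome):
        sites = IntervalSet([iv(5000, 5400)])
        prof = average_profile(IntervalSet([iv(0, 100)]), sites, flat_genome, 1000, 100)
        assert np.allclose(prof.bin_offsets, -prof.bin_offsets[::-1])
        assert np.all(np.diff(prof.bin_offsets) > 0)

    def test_all_sites_dropped_raises(self, flat_genome):
        sites = IntervalSet([iv(0, 100)])  # window exceeds chromosome start
        with pytest.raises(ValueError, match="dropped"):
            average_profile(IntervalSet([iv(0, 10)]), sites, flat_genome, 1000, 100)
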