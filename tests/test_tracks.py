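"""Coverage-track numerics: bedGraph I/O, normalization, smoothing,
pile-ups, window statistics, percentile partitions and correlations."""

import numpy as np
import pytest
from scipy import stats

from loopaxis.genome import GenomeLayout
from loopaxis.intervals import FeatureSet
from loopaxis.tracks import (BinnedTrack, background_correct, hann_kernel,
                             hann_smooth, normalize_rpkm,
                             partition_by_percentile, pileup_profile,
                             profile_matrix, read_bedgraph, window_correlation,
                             window_signal, write_bedgraph)


@pytest.fixture
def genome_1kb():
    return GenomeLayout([("chrI", 1000)])


def make_track(genome, bin_size, **chrom_values):
    tr = BinnedTrack(genome, bin_size)
    for c, v in chrom_values.items():
        tr.data[c][:] = v
    return tr


class TestBedGraphIO:
    def test_constant_record_fills_bins(self, genome_1kb, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chrI\t0\t1000\t5.0\n")
        tr = read_bedgraph(p, genome_1kb, 100)
        assert np.allclose(tr.data["chrI"], 5.0)

    def test_partial_bin_length_weighted(self, genome_1kb, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chrI\t0\t50\t10\n")
        tr = read_bedgraph(p, genome_1kb, 100)
        assert tr.data["chrI"][0] == pytest.approx(5.0)
        assert tr.data["chrI"][1] == 0.0

    def test_round_trip_values(self, tmp_path):
        g = GenomeLayout([("chrI", 5000), ("chrII", 1230)])
        rng = np.random.default_rng(3)
        tr = BinnedTrack(g, 10)
        for c in tr.data:
            tr.data[c][:] = rng.integers(0, 5, len(tr.data[c])).astype(float)
        p = tmp_path / "t.bedgraph"
        write_bedgraph(tr, p)
        tr2 = read_bedgraph(p, g, 10)
        for c in tr.data:
            assert np.allclose(tr.data[c], tr2.data[c])

    def test_overlapping_records_rejected(self, genome_1kb, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chrI\t0\t500\t1\nchrI\t400\t600\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_bedgraph(p, genome_1kb, 100)

    def test_unknown_chromosome_rejected(self, genome_1kb, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chrX\t0\t10\t1\n")
        with pytest.raises(ValueError, match="chrX"):
            read_bedgraph(p, genome_1kb, 100)


class TestNormalization:
    def test_rpkm_formula(self, genome_1kb):
        tr = make_track(genome_1kb, 100, chrI=10.0)
        out = normalize_rpkm(tr, 1_000_000)
        # 10 counts / (1e6 reads * 100 bp) * 1e9 = 100 RPKM
        assert np.allclose(out.data["chrI"], 100.0)

    def test_rpkm_homogeneous_in_library_size(self, genome_1kb):
        tr = make_track(genome_1kb, 100, chrI=7.0)
        a = normalize_rpkm(tr, 1e6).data["chrI"]
        b = normalize_rpkm(tr, 2e6).data["chrI"]
        assert np.allclose(a, 2 * b)

    def test_rpkm_rejects_nonpositive_library(self, genome_1kb):
        with pytest.raises(ValueError):
            normalize_rpkm(make_track(genome_1kb, 100), 0)

    def test_background_subtraction_and_replicate_mean(self, genome_1kb):
        sample = make_track(genome_1kb, 100, chrI=10.0)
        untagged = make_track(genome_1kb, 100, chrI=3.0)
        t0 = make_track(genome_1kb, 100, chrI=2.0)
        out = background_correct([sample], [untagged, t0])
        assert np.allclose(out.data["chrI"], 5.0)
        rep1 = make_track(genome_1kb, 100, chrI=5.0)
        rep2 = make_track(genome_1kb, 100, chrI=7.0)
        out = background_correct([rep1, rep2])
        assert np.allclose(out.data["chrI"], 6.0)

    def test_background_floor_at_zero(self, genome_1kb):
        sample = make_track(genome_1kb, 100, chrI=1.0)
        ctl = make_track(genome_1kb, 100, chrI=3.0)
        assert np.allclose(background_correct([sample], [ctl]).data["chrI"], -2.0)
        out = background_correct([sample], [ctl], floor_at_zero=True)
        assert np.allclose(out.data["chrI"], 0.0)

    def test_mismatched_binning_rejected(self, genome_1kb):
        with pytest.raises(ValueError):
            background_correct([make_track(genome_1kb, 100)],
                               [BinnedTrack(genome_1kb, 50)])


class TestHannSmoothing:
    def test_constant_track_fixed_point(self):
        g = GenomeLayout([("chrI", 10_000)])
        tr = make_track(g, 100, chrI=3.25)
        out = hann_smooth(tr, 2500)
        assert np.allclose(out.data["chrI"], 3.25)

    def test_three_tap_kernel_preserves_impulse(self):
        # Hann endpoints are exactly zero, so a 3-tap kernel is an identity
        g = GenomeLayout([("chrI", 2000)])
        tr = BinnedTrack(g, 100)
        tr.data["chrI"][10] = 1.0
        out = hann_smooth(tr, 300)
        assert np.allclose(out.data["chrI"], tr.data["chrI"])

    def test_impulse_response_is_normalized_kernel(self):
        g = GenomeLayout([("chrI", 10_000)])
        tr = BinnedTrack(g, 100)
        tr.data["chrI"][50] = 1.0
        out = hann_smooth(tr, 500)
        k = hann_kernel(5)
        expect = np.zeros_like(tr.data["chrI"])
        expect[48:53] = k
        assert np.allclose(out.data["chrI"], expect, atol=1e-12)
        assert out.data["chrI"].sum() == pytest.approx(1.0, abs=1e-12)
        assert out.data["chrI"].argmax() == 50

    def test_edge_kernel_renormalized(self):
        g = GenomeLayout([("chrI", 1000)])
        tr = make_track(g, 100, chrI=2.0)
        out = hann_smooth(tr, 500)
        # truncation at the edges renormalizes, so a constant stays constant
        assert np.allclose(out.data["chrI"], 2.0)

    def test_window_below_bin_rejected(self):
        g = GenomeLayout([("chrI", 1000)])
        with pytest.raises(ValueError):
            hann_smooth(BinnedTrack(g, 100), 50)


class TestPileup:
    def test_flat_track_flat_profile(self):
        g = GenomeLayout([("chrI", 100_000)])
        tr = make_track(g, 20, chrI=4.0)
        centers = FeatureSet.from_records([("chrI", 30_000, 30_200),
                                           ("chrI", 60_000, 60_100)])
        prof = pileup_profile(tr, centers, flank=2000, bin=20)
        assert np.allclose(prof.values, 4.0)
        assert (prof.n_features == 2).all()
        assert prof.offsets[0] == -1990 and prof.offsets[-1] == 1990

    def test_gaussian_bump_recovered_with_max_at_zero(self):
        g = GenomeLayout([("chrI", 200_000)])
        tr = BinnedTrack(g, 20)
        x = (np.arange(len(tr.data["chrI"])) + 0.5) * 20
        centers_bp = [50_000, 100_000, 150_000]
        for c in centers_bp:
            tr.data["chrI"] += np.exp(-0.5 * ((x - c) / 300) ** 2)
        centers = FeatureSet.from_records(
            [("chrI", c - 95, c + 95) for c in centers_bp])
        prof = pileup_profile(tr, centers, flank=3000, bin=20)
        assert abs(prof.offsets[np.nanargmax(prof.values)]) <= 10
        mid = np.nanmax(prof.values)
        assert mid == pytest.approx(1.0, rel=0.01)

    def test_feature_at_chromosome_start_missing_left_flank(self):
        g = GenomeLayout([("chrI", 100_000)])
        tr = make_track(g, 20, chrI=1.0)
        centers = FeatureSet.from_records([("chrI", 0, 200)])  # midpoint 100
        prof = pileup_profile(tr, centers, flank=2000, bin=20)
        left = prof.offsets < -100
        assert (prof.n_features[left] == 0).all()
        assert np.isnan(prof.values[left]).all()

    def test_matrix_rows_sorted_and_column_means_match_profile(self):
        g = GenomeLayout([("chrI", 100_000)])
        rng = np.random.default_rng(5)
        tr = BinnedTrack(g, 20)
        tr.data["chrI"][:] = rng.poisson(3.0, len(tr.data["chrI"]))
        recs = [("chrI", 5000 + 4000 * i, 5200 + 4000 * i, float(i % 7))
                for i in range(20)]
        centers = FeatureSet.from_records(recs)
        mat = profile_matrix(tr, centers, flank=1000, bin=20, descending=True)
        assert mat.matrix.shape == (20, 100)
        row_scores = centers.scores[mat.row_order]
        assert (np.diff(row_scores) <= 0).all()
        prof = pileup_profile(tr, centers, flank=1000, bin=20)
        assert np.allclose(mat.column_means(), prof.values)

    def test_matrix_rows_match_independent_slicing(self):
        g = GenomeLayout([("chrI", 50_000)])
        tr = BinnedTrack(g, 20)
        tr.data["chrI"][:] = np.arange(len(tr.data["chrI"]), dtype=float)
        centers = FeatureSet.from_records([("chrI", 10_000, 10_040, 1.0)])
        mat = profile_matrix(tr, centers, flank=100, bin=20)
        mid = 10_020
        expect = tr.data["chrI"][(mid - 100) // 20:(mid + 100) // 20]
        assert np.allclose(mat.matrix[0], expect)

    def test_missing_score_rejected(self):
        g = GenomeLayout([("chrI", 10_000)])
        tr = BinnedTrack(g, 20)
        centers = FeatureSet.from_records([("chrI", 100, 200)])
        with pytest.raises(ValueError):
            profile_matrix(tr, centers, flank=100, bin=20)


class TestWindowSignal:
    def test_flat_track_mean(self):
        g = GenomeLayout([("chrI", 100_000)])
        tr = make_track(g, 20, chrI=2.5)
        feats = FeatureSet.from_records([("chrI", 10_000, 10_100)])
        out = window_signal(tr, feats, 600)
        assert out["value"].iloc[0] == pytest.approx(2.5)

    def test_summed_count(self):
        g = GenomeLayout([("chrI", 100_000)])
        tr = make_track(g, 20, chrI=2.0)  # 2 counts per 20-bp bin
        feats = FeatureSet.from_records([("chrI", 10_000, 10_100)])
        out = window_signal(tr, feats, 600, stat="summed_count")
        assert out["value"].iloc[0] == pytest.approx(2.0 * 30)

    def test_axis_overlap_exclusion_at_ten_percent(self):
        g = GenomeLayout([("chrI", 100_000)])
        tr = make_track(g, 20, chrI=1.0)
        # windows are 1500 bp centered on the feature midpoint
        feats = FeatureSet.from_records([("chrI", 9_900, 10_100),
                                         ("chrI", 49_900, 50_100)])
        axis = FeatureSet.from_records(
            [("chrI", 10_550, 10_750),    # 200/1500 = 13.3% of window 1
             ("chrI", 50_650, 50_750)])   # 100/1500 = 6.7% of window 2
        out = window_signal(tr, feats, 1500,
                            exclude_overlap=(axis, 0.10))
        assert bool(out["excluded"].iloc[0]) is True
        assert np.isnan(out["value"].iloc[0])
        assert bool(out["excluded"].iloc[1]) is False
        assert out["value"].iloc[1] == pytest.approx(1.0)


class TestPercentilePartition:
    def test_deciles_of_1_to_100(self):
        bins = partition_by_percentile(np.arange(1, 101), 10)
        counts = np.bincount(bins)
        assert (counts == 10).all()
        assert (bins[80:] >= 8).all()  # scores 81..100 in the top 20%

    def test_ties_stable_and_balanced(self):
        bins = partition_by_percentile(np.ones(100), 10)
        assert (np.bincount(bins) == 10).all()
        # stable: assignment follows input order under total ties
        assert (np.diff(bins) >= 0).all()

    def test_uneven_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(7)
        bins = partition_by_percentile(rng.normal(size=103), 10)
        counts = np.bincount(bins, minlength=10)
        assert counts.max() - counts.min() <= 1

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            partition_by_percentile([1.0, 2.0], 10)


class TestWindowCorrelation:
    def test_identical_tracks(self):
        g = GenomeLayout([("chrI", 10_000)])
        rng = np.random.default_rng(11)
        a = BinnedTrack(g, 100)
        a.data["chrI"][:] = rng.normal(size=100)
        r, rho, r2 = window_correlation(a, a, window=100)
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_negated_track(self):
        g = GenomeLayout([("chrI", 10_000)])
        rng = np.random.default_rng(13)
        a = BinnedTrack(g, 100)
        a.data["chrI"][:] = rng.normal(size=100)
        b = a.copy()
        b.data["chrI"] *= -1
        r, _, r2 = window_correlation(a, b, window=100)
        assert r == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_affine_invariance_positive_scale(self):
        g = GenomeLayout([("chrI", 10_000)])
        rng = np.random.default_rng(17)
        a = BinnedTrack(g, 100)
        a.data["chrI"][:] = rng.normal(size=100)
        b = a.copy()
        b.data["chrI"] = 3.0 * b.data["chrI"] + 2.0
        r, rho, _ = window_correlation(a, b, window=100)
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_independent_tracks_near_zero(self):
        g = GenomeLayout([("chrI", 1_000_000)])
        rng = np.random.default_rng(19)
        a, b = BinnedTrack(g, 100), BinnedTrack(g, 100)
        a.data["chrI"][:] = rng.normal(size=10_000)
        b.data["chrI"][:] = rng.normal(size=10_000)
        r, _, _ = window_correlation(a, b, window=100)
        assert abs(r) < 0.05  # 99% bound for n = 1e4 is ~0.026

    def test_too_few_windows_rejected(self):
        g = GenomeLayout([("chrI", 150)])
        with pytest.raises(ValueError):
            window_correlation(BinnedTrack(g, 50), BinnedTrack(g, 50),
                               window=100)
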