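"""Summit-window scoring, IgG filtering, correlation matrices, FRiP."""

import numpy as np
import pytest

from carrycal.core_io import (
    FragmentRecord,
    FragmentSet,
    GenomeSpec,
    GenomicInterval,
    PeakRecord,
)
from carrycal.coverage import CoverageTrack, fragment_depth
from carrycal.peakqc import (
    QCConfig,
    ScoreMatrix,
    build_score_matrix,
    correlation_matrix,
    frip,
    frip_series,
    igg_peak_filter,
    peak_summit_scores,
)

from conftest import overlap_oracle, pearson_oracle, random_fragment_set


def _track(runs, genome="g", chrom="chr1"):
    starts = np.array([r[0] for r in runs])
    ends = np.array([r[1] for r in runs])
    values = np.array([r[2] for r in runs], dtype=float)
    return CoverageTrack(genome, {chrom: (starts, ends, values)})


def _peak(summit, chrom="chr1", half=500):
    start = max(0, summit - half)
    return PeakRecord(GenomicInterval(chrom, start, summit + half), summit)


class TestSummitScores:
    def test_constant_track(self):
        track = _track([(0, 10_000, 3.5)])
        scores = peak_summit_scores(track, [_peak(5000)], flank=150)
        assert scores[0] == pytest.approx(3.5)

    def test_implicit_zeros_count_in_mean(self):
        # value 3 on part of the 301 bp window, 0 elsewhere
        track = _track([(5000, 5100, 3.0)])
        scores = peak_summit_scores(track, [_peak(5000)], flank=150)
        # window [4850, 5151); covered bp = 100
        assert scores[0] == pytest.approx(3.0 * 100 / 301)

    def test_matches_per_bp_oracle(self):
        rng = np.random.default_rng(6)
        genome = GenomeSpec("g", {"chr1": 20_000})
        fs = random_fragment_set(rng, genome, 500, max_len=200)
        track = fragment_depth(fs, genome)
        dense = track.to_array("chr1", 20_000)
        summits = rng.integers(0, 20_000, size=50)
        peaks = [PeakRecord(GenomicInterval("chr1", 0, 20_000), int(s)) for s in summits]
        scores = peak_summit_scores(track, peaks, flank=150, genome=genome)
        for s, got in zip(summits, scores):
            lo, hi = max(0, s - 150), min(20_000, s + 151)
            assert got == pytest.approx(dense[lo:hi].mean(), abs=1e-12)

    def test_window_truncated_at_chromosome_start(self):
        genome = GenomeSpec("g", {"chr1": 10_000})
        track = _track([(0, 10_000, 2.0)])
        p = PeakRecord(GenomicInterval("chr1", 0, 500), 0)
        scores = peak_summit_scores(track, [p], flank=150, genome=genome)
        # window truncated to [0, 151), still mean 2.0 on constant track
        assert scores[0] == pytest.approx(2.0)

    def test_summit_off_genome_errors(self):
        genome = GenomeSpec("g", {"chr1": 100})
        track = _track([(0, 100, 1.0)])
        p = PeakRecord(GenomicInterval("chrX", 0, 10), 5)
        with pytest.raises(ValueError, match="unknown chromosome"):
            peak_summit_scores(track, [p], genome=genome)


class TestIggFilter:
    def test_scores_1_to_100_removes_only_max(self):
        scores = np.arange(1, 101, dtype=float)
        kept = igg_peak_filter(scores, percentile=99)
        # linear-interpolation 99th percentile of 1..100 is 99.01;
        # only the score-100 peak is strictly greater
        assert np.percentile(scores, 99) == pytest.approx(99.01)
        assert len(kept) == 99
        assert 99 not in kept  # index of score 100

    def test_all_equal_removes_none(self):
        kept = igg_peak_filter(np.full(50, 7.0), percentile=99)
        assert len(kept) == 50

    def test_retained_fraction_bound(self):
        rng = np.random.default_rng(44)
        for _ in range(20):
            n = int(rng.integers(2, 300))
            scores = rng.random(n)
            kept = igg_peak_filter(scores, percentile=99)
            assert len(kept) >= int(np.floor(0.99 * n))

    def test_percentile_extremes(self):
        scores = np.array([1.0, 2.0, 3.0, 3.0])
        assert len(igg_peak_filter(scores, percentile=99.999)) == 4
        # tiny percentile retains only minimum-score ties
        kept = igg_peak_filter(scores, percentile=1e-9)
        assert set(scores[kept]) == {1.0}

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            igg_peak_filter(np.array([]))


class TestScoreMatrix:
    def test_single_entry_equals_summit_score(self):
        track = _track([(0, 1000, 2.0)])
        peak = _peak(500, half=400)
        m = build_score_matrix({"a": track}, [peak], flank=150)
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == pytest.approx(
            peak_summit_scores(track, [peak], flank=150)[0]
        )

    def test_duplicated_sample_identical_columns(self):
        rng = np.random.default_rng(1)
        genome = GenomeSpec("g", {"chr1": 10_000})
        fs = random_fragment_set(rng, genome, 200)
        track = fragment_depth(fs, genome)
        peaks = [_peak(s, half=300) for s in (1000, 5000, 9000)]
        m = build_score_matrix({"a": track, "b": track}, peaks, flank=150)
        assert np.array_equal(m.values[:, 0], m.values[:, 1])

    def test_columns_match_per_peak_recomputation(self):
        rng = np.random.default_rng(23)
        genome = GenomeSpec("g", {"chr1": 30_000})
        tracks = {
            f"s{i}": fragment_depth(random_fragment_set(rng, genome, 300), genome)
            for i in range(3)
        }
        peaks = [_peak(int(s), half=400) for s in rng.integers(500, 29_500, size=20)]
        m = build_score_matrix(tracks, peaks, flank=150)
        for j, sid in enumerate(m.samples):
            expected = peak_summit_scores(tracks[sid], peaks, flank=150)
            assert np.allclose(m.values[:, j], expected)


class TestCorrelationMatrix:
    def _matrix(self, values, samples=None):
        n_peaks, n_samples = values.shape
        peaks = [_peak(1000 + 2000 * i) for i in range(n_peaks)]
        return ScoreMatrix(
            peaks, samples or [f"s{j}" for j in range(n_samples)], values
        )

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        v = rng.random((30, 2))
        v[:, 1] = v[:, 0]
        cm = correlation_matrix(self._matrix(v))
        assert cm.iloc[0, 1] == pytest.approx(1.0)

    def test_affine_column_gives_r2_one(self):
        rng = np.random.default_rng(1)
        x = rng.random(40)
        v = np.column_stack([x, 2 * x + 3])
        cm = correlation_matrix(self._matrix(v))
        assert cm.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        v = rng.random((100, 4))
        cm = correlation_matrix(self._matrix(v), squared=True)
        for i in range(4):
            for j in range(4):
                r = pearson_oracle(v[:, i], v[:, j])
                assert cm.iloc[i, j] == pytest.approx(r**2, abs=1e-12)

    def test_complete_rows_policy(self):
        # a NaN anywhere in a row drops that row for every pair
        rng = np.random.default_rng(9)
        v = rng.random((50, 3))
        v[7, 2] = np.nan
        cm = correlation_matrix(self._matrix(v))
        sub = np.delete(v, 7, axis=0)
        expected = pearson_oracle(sub[:, 0], sub[:, 1]) ** 2
        assert cm.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_warns_nan(self):
        v = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.warns(UserWarning, match="zero variance"):
            cm = correlation_matrix(self._matrix(v))
        assert np.isnan(cm.iloc[0, 1])

    def test_invariant_to_positive_affine_rescaling(self):
        # calibration scaling of a sample cannot change R^2
        rng = np.random.default_rng(12)
        v = rng.random((60, 3))
        w = v.copy()
        w[:, 1] = 5.0 * w[:, 1]
        a = correlation_matrix(self._matrix(v)).to_numpy()
        b = correlation_matrix(self._matrix(w)).to_numpy()
        assert np.allclose(a, b)


class TestFrip:
    def _fs(self, pairs):
        return FragmentSet(
            "s", "g",
            [FragmentRecord(GenomicInterval("chr1", a, b)) for a, b in pairs],
        )

    def test_all_in_peaks(self):
        fs = self._fs([(10, 20), (30, 40)])
        peaks = [_peak(25, half=25)]
        assert frip(fs, peaks) == 1.0

    def test_none_in_peaks(self):
        fs = self._fs([(10, 20)])
        peaks = [_peak(1500, half=100)]
        assert frip(fs, peaks) == 0.0

    def test_partial_overlap_fraction(self):
        fs = self._fs([(i * 100, i * 100 + 10) for i in range(10)])
        peaks = [PeakRecord(GenomicInterval("chr1", 0, 350), 100)]
        assert frip(fs, peaks) == pytest.approx(0.4)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(77)
        genome = GenomeSpec("g", {"chr1": 20_000})
        fs = random_fragment_set(rng, genome, 1000, max_len=150)
        peaks = [
            PeakRecord(GenomicInterval("chr1", int(s), int(s) + 400), int(s) + 200)
            for s in rng.integers(0, 19_600, size=15)
        ]
        expected = sum(
            any(overlap_oracle(f.interval, p.interval) for p in peaks) for f in fs
        ) / len(fs)
        assert frip(fs, peaks) == pytest.approx(expected)

    def test_invariant_to_peak_order_and_merging(self):
        rng = np.random.default_rng(55)
        genome = GenomeSpec("g", {"chr1": 10_000})
        fs = random_fragment_set(rng, genome, 300)
        peaks = [
            PeakRecord(GenomicInterval("chr1", 100, 600), 300),
            PeakRecord(GenomicInterval("chr1", 400, 900), 500),  # overlaps previous
            PeakRecord(GenomicInterval("chr1", 5000, 5500), 5100),
        ]
        assert frip(fs, peaks) == frip(fs, peaks[::-1])
        merged = [
            PeakRecord(GenomicInterval("chr1", 100, 900), 300),
            PeakRecord(GenomicInterval("chr1", 5000, 5500), 5100),
        ]
        assert frip(fs, peaks) == frip(fs, merged)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            frip(self._fs([]), [_peak(500)])


class TestFripSeries:
    def _setup(self):
        rng = np.random.default_rng(2)
        genome = GenomeSpec("g", {"chr1": 50_000})
        fs = random_fragment_set(rng, genome, 4000, max_len=150)
        peaks = [
            PeakRecord(GenomicInterval("chr1", int(s), int(s) + 500), int(s) + 250)
            for s in range(0, 50_000, 5000)
        ]
        return fs, peaks

    def test_full_depth_equals_plain_frip(self):
        fs, peaks = self._setup()
        series = frip_series(fs, peaks, depths=[len(fs)], seed=0)
        assert series[len(fs)] == pytest.approx(frip(fs, peaks))

    def test_deterministic(self):
        fs, peaks = self._setup()
        a = frip_series(fs, peaks, depths=[2000, 1000, 500], seed=5)
        b = frip_series(fs, peaks, depths=[2000, 1000, 500], seed=5)
        assert a.equals(b)

    def test_excess_depth_skipped_with_warning(self):
        fs, peaks = self._setup()
        with pytest.warns(UserWarning, match="skipped"):
            series = frip_series(fs, peaks, depths=[10_000, 1000], seed=0)
        assert list(series.index) == [1000]

    def test_within_binomial_bound_of_true_fraction(self):
        fs, peaks = self._setup()
        p = frip(fs, peaks)
        series = frip_series(fs, peaks, depths=[2000, 1000, 500, 250], seed=3)
        for depth, value in series.items():
            se = np.sqrt(p * (1 - p) / depth)
            assert abs(value - p) <= 3 * se


class TestQCConfig:
    def test_depths_must_strictly_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            QCConfig(downsample_depths=(100, 100, 50))

    def test_defaults_are_halving_series(self):
        cfg = QCConfig()
        assert cfg.flank == 150
        assert cfg.igg_percentile == 99.0
        depths = cfg.downsample_depths
        assert all(a == 2 * b for a, b in zip(depths, depths[1:]))
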