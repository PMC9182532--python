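"""Baseline estimation and burst detection, against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccscore import DetectionParams, TimeTrace, detect_peaks, estimate_baseline
from ccscore.exceptions import ValidationError

from .oracles import brute_force_peaks


def as_trace(counts, bin_ms=1.0):
    counts = np.asarray(counts)
    return TimeTrace(bin_ms=bin_ms, green=counts, red=np.zeros_like(counts))


class TestBaseline:
    def test_constant_series(self):
        baseline, sigma = estimate_baseline(np.full(100, 3))
        assert baseline == 3.0
        assert sigma == pytest.approx(np.sqrt(3.0))  # MAD 0, Poisson floor

    def test_median_ignores_single_burst(self):
        baseline, _ = estimate_baseline(np.array([0, 0, 0, 0, 100]))
        assert baseline == 0.0

    def test_poisson_series_recovers_rate_and_noise_scale(self):
        """On integer Poisson data the MAD quantises; the estimate still
        tracks the true spread to within the MAD/floor discretisation."""
        from .oracles import brute_force_baseline

        rng = np.random.default_rng(31)
        counts = rng.poisson(5.0, size=100_000)
        baseline, sigma = estimate_baseline(counts)
        assert baseline == 5.0
        # Population MAD of Poisson(5) is 2, so the scaled estimate is 2.9652.
        assert sigma == pytest.approx(1.4826 * 2)
        oracle_base, oracle_sigma = brute_force_baseline(counts.tolist())
        assert (baseline, sigma) == pytest.approx((oracle_base, oracle_sigma))

    def test_poisson_floor_engages_when_mad_underestimates_shot_noise(self):
        # Poisson(3): MAD is 1, scaled 1.4826 < sqrt(3), so the floor wins.
        rng = np.random.default_rng(32)
        counts = rng.poisson(3.0, size=100_000)
        baseline, sigma = estimate_baseline(counts)
        assert baseline == 3.0
        assert sigma == pytest.approx(np.sqrt(3.0))

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            estimate_baseline(np.array([]))


class TestDetectPeaks:
    def test_background_only_trace_yields_no_peaks(self):
        assert detect_peaks(as_trace(np.full(1000, 2)), "green") == []

    def test_single_peak_span_apex_and_intensity(self):
        counts = [2, 2, 2, 50, 60, 50, 2, 2]
        (peak,) = detect_peaks(as_trace(counts), "green")
        assert (peak.start_bin, peak.end_bin, peak.apex_bin) == (3, 5, 4)
        assert peak.max_intensity == 60.0
        assert peak.integrated_photons == pytest.approx(160 - 3 * 2)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValidationError):
            detect_peaks(as_trace([1, 2, 3]), "blue")

    def test_min_width_discards_narrow_runs(self):
        counts = [2, 2, 50, 2, 50, 50, 2, 2]
        params = DetectionParams(min_width_bins=2)
        peaks = detect_peaks(as_trace(counts), "green", params)
        assert [(p.start_bin, p.end_bin) for p in peaks] == [(4, 5)]

    def test_merge_gap_joins_adjacent_runs(self):
        counts = [2, 50, 50, 2, 2, 50, 2, 2, 2, 2, 50, 2]
        params = DetectionParams(merge_gap_bins=2)
        peaks = detect_peaks(as_trace(counts), "green", params)
        assert [(p.start_bin, p.end_bin) for p in peaks] == [(1, 5), (10, 10)]

    @pytest.mark.parametrize("k_sigma,min_width,merge_gap",
                             [(5.0, 1, 0), (3.0, 2, 1), (8.0, 1, 3)])
    def test_matches_brute_force_scanner_on_random_traces(
        self, k_sigma, min_width, merge_gap
    ):
        rng = np.random.default_rng(17)
        params = DetectionParams(k_sigma=k_sigma, min_width_bins=min_width,
                                 merge_gap_bins=merge_gap)
        for _ in range(25):
            counts = rng.poisson(3.0, size=1500)
            spikes = rng.integers(0, 1500, size=rng.integers(0, 20))
            counts[spikes] += rng.integers(20, 200, size=spikes.size)
            peaks = detect_peaks(as_trace(counts), "green", params)
            expected = brute_force_peaks(counts.tolist(), 1.0, k_sigma,
                                         min_width, merge_gap)
            got = [
                (p.start_bin, p.end_bin, p.apex_bin, p.max_intensity,
                 p.integrated_photons)
                for p in peaks
            ]
            assert got == pytest.approx(expected)

    def test_peaks_sorted_and_disjoint(self, hetero_trace):
        peaks = detect_peaks(hetero_trace, "green")
        assert len(peaks) > 10
        for prev, cur in zip(peaks, peaks[1:]):
            assert prev.end_bin < cur.start_bin

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(2.0, 10.0), st.floats(2.0, 10.0))
    def test_raising_threshold_never_adds_peaks(self, seed, k_lo, k_extra):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, size=800)
        counts[rng.integers(0, 800, size=5)] += 50
        trace = as_trace(counts)
        lo = detect_peaks(trace, "green", DetectionParams(k_sigma=k_lo))
        hi = detect_peaks(trace, "green", DetectionParams(k_sigma=k_lo + k_extra))
        assert len(hi) <= len(lo)


class TestDetectionOnSimulation:
    def test_recall_on_bright_simulated_bursts(self, hetero_trace):
        """Ground-truth apexes with amplitude far above threshold are found."""
        peaks = detect_peaks(hetero_trace, "green")
        spans = [(p.start_bin, p.end_bin) for p in peaks]
        truth = [b.apex_bin for b in hetero_trace.ground_truth
                 if b.species != "red_only"]
        found = sum(any(s <= apex <= e for s, e in spans) for apex in truth)
        assert found / len(truth) >= 0.99

    def test_false_positive_rate_on_pure_background(self):
        """Supra-threshold bin fraction is bounded by the Poisson tail."""
        from scipy import stats

        rng = np.random.default_rng(23)
        rate = 2.0
        counts = rng.poisson(rate, size=200_000)
        baseline, sigma = estimate_baseline(counts)
        threshold = baseline + 5.0 * sigma
        observed = float(np.mean(counts > threshold))
        expected = float(stats.poisson.sf(np.floor(threshold), rate))
        assert observed <= expected + 3 * np.sqrt(expected / counts.size) + 1e-6
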