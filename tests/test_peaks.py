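"""Peak detection, width measurement and base attribution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covhap import (
    CoverageHistogram,
    PeakDetectionParams,
    assign_regions,
    detect_peaks,
    filter_tail,
    measure_widths,
    smooth,
)
from conftest import make_curve
from oracles import brute_force_peaks, brute_force_width_crossings


def gaussian(x, mu, sigma, amp=1.0):
    return amp * np.exp(-0.5 * ((np.asarray(x, float) - mu) / sigma) ** 2)


class TestDetectPeaks:
    def test_single_gaussian_mode_found(self):
        x = np.arange(201)
        curve = make_curve(1000 * gaussian(x, 100, 15))
        peaks = detect_peaks(curve)
        assert len(peaks) == 1
        assert abs(peaks[0].position - 100) <= 1

    def test_two_bumps_found_sorted(self):
        x = np.arange(161)
        curve = make_curve(800 * gaussian(x, 50, 6) + 1000 * gaussian(x, 100, 8))
        peaks = detect_peaks(curve)
        assert [round(p.position, 0) for p in peaks] == [50, 100]
        assert peaks[0].position < peaks[1].position

    def test_constant_curve_has_no_strict_maximum(self):
        assert detect_peaks(make_curve(np.full(50, 7.0))) == []

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            detect_peaks(make_curve([1.0, 2.0]))

    def test_low_peaks_filtered_by_height(self):
        x = np.arange(161)
        y = 1000 * gaussian(x, 100, 8) + 10 * gaussian(x, 30, 3)  # 1% of max
        peaks = detect_peaks(make_curve(y), PeakDetectionParams(min_height_frac=0.05))
        assert [p.position for p in peaks] == [100]

    def test_plateau_reports_midpoint(self):
        y = np.array([0, 1, 5, 5, 5, 1, 0], dtype=float)
        peaks = detect_peaks(make_curve(y))
        assert peaks[0].position == 3

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=200))
    def test_matches_brute_force_oracle(self, values):
        """Detected maxima and prominences agree with exhaustive scanning."""
        y = np.array(values, dtype=float)
        if y.max() <= 0:
            return
        params = PeakDetectionParams(0.05, 0.05, 0.5)
        got = detect_peaks(make_curve(y), params)
        want = brute_force_peaks(y, 0.05 * y.max(), 0.05 * y.max())
        assert [(p.position, p.height) for p in got] == [(m, h) for m, h, _ in want]
        assert np.allclose([p.prominence for p in got], [pr for _, _, pr in want])


class TestMeasureWidths:
    def test_triangle_half_prominence_closed_form(self):
        # symmetric triangle peaking at 100 over base [0, 200]
        y = np.concatenate([np.linspace(0, 100, 101), np.linspace(99, 0, 100)])
        peaks = detect_peaks(make_curve(y))
        peaks = measure_widths(make_curve(y), peaks, PeakDetectionParams(rel_height=0.5))
        left, right = peaks[0].width_interval
        assert left == pytest.approx(50.0, abs=0.5)
        assert right == pytest.approx(150.0, abs=0.5)

    def test_rel_height_one_spans_full_base(self):
        x = np.arange(201)
        y = 1000 * gaussian(x, 100, 10)
        curve = make_curve(y)
        peaks = measure_widths(curve, detect_peaks(curve), PeakDetectionParams(rel_height=1.0))
        left, right = peaks[0].width_interval
        assert right - left > 100  # essentially the whole support

    @pytest.mark.parametrize("seed", range(20))
    def test_crossings_match_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        x = np.arange(200)
        mus = rng.uniform(30, 170, size=2)
        y = 1000 * gaussian(x, mus[0], rng.uniform(5, 15)) + 1000 * gaussian(
            x, mus[1], rng.uniform(5, 15)
        )
        curve = make_curve(y)
        params = PeakDetectionParams(rel_height=0.5)
        peaks = measure_widths(curve, detect_peaks(curve, params), params)
        for p in peaks:
            eval_h = p.height - 0.5 * p.prominence
            # brute-force scan from the mode sample for the same crossing
            left, right = brute_force_width_crossings(y, p.position, eval_h)
            assert p.width_interval[0] == pytest.approx(left, abs=1e-6)
            assert p.width_interval[1] == pytest.approx(right, abs=1e-6)


class TestAssignRegions:
    def test_single_peak_gets_everything(self, gaussian_histogram):
        filtered = filter_tail(gaussian_histogram)
        curve = smooth(filtered)
        peaks = measure_widths(curve, detect_peaks(curve))
        peaks = assign_regions(filtered, peaks, curve)
        lo, hi = peaks[0].region
        assert lo == min(filtered.counts) and hi == max(filtered.counts)
        assert peaks[0].area == filtered.total_bases

    def test_two_separated_peaks_split_exactly(self):
        # zero-count gap between the modes: boundary must fall inside it
        counts = {c: 100 for c in range(40, 61)} | {c: 150 for c in range(100, 121)}
        hist = CoverageHistogram(counts)
        curve = smooth(hist)
        peaks = measure_widths(curve, detect_peaks(curve))
        assert len(peaks) == 2
        peaks = assign_regions(hist, peaks, curve)
        assert peaks[0].area == 100 * 21
        assert peaks[1].area == 150 * 21
        assert peaks[0].area + peaks[1].area == hist.total_bases

    def test_boundary_between_half_and_full_coverage_modes(self, bimodal_histogram):
        """Modes like the 100X/210X pattern: boundary strictly between them."""
        filtered = filter_tail(bimodal_histogram)
        curve = smooth(filtered)
        peaks = measure_widths(curve, detect_peaks(curve))
        peaks = assign_regions(filtered, peaks, curve)
        b = peaks[0].region[1]
        assert peaks[0].position < b < peaks[1].position

    def test_empty_peak_list_rejected(self, gaussian_histogram):
        with pytest.raises(ValueError, match="no peaks"):
            assign_regions(gaussian_histogram, [])

    @pytest.mark.parametrize("seed", range(15))
    def test_partition_conserves_total(self, seed):
        """Region areas always sum to the filtered histogram total."""
        rng = np.random.default_rng(seed)
        n_modes = rng.integers(1, 4)
        x = np.arange(250)
        y = np.zeros_like(x, dtype=float)
        for _ in range(n_modes):
            y += rng.uniform(200, 1000) * gaussian(x, rng.uniform(20, 230), rng.uniform(4, 20))
        counts = {int(c): int(v) + 1 for c, v in zip(x, y)}
        hist = filter_tail(CoverageHistogram(counts))
        curve = smooth(hist)
        peaks = measure_widths(curve, detect_peaks(curve))
        if not peaks:
            return
        peaks = assign_regions(hist, peaks, curve)
        assert sum(p.area for p in peaks) == hist.total_bases
        regions = [p.region for p in peaks]
        for (al, ah), (bl, bh) in zip(regions, regions[1:]):
            assert ah + 1 == bl  # disjoint, ordered, contiguous

    def test_scale_invariance(self, bimodal_histogram):
        """Scaling counts leaves positions/boundaries fixed, scales areas."""
        def run(hist):
            f = filter_tail(hist)
            c = smooth(f)
            return assign_regions(f, measure_widths(c, detect_peaks(c)), c)

        base = run(bimodal_histogram)
        scaled_hist = CoverageHistogram(
            {c: 7 * n for c, n in bimodal_histogram.counts.items()}
        )
        scaled = run(scaled_hist)
        assert [p.position for p in base] == [p.position for p in scaled]
        assert [p.region for p in base] == [p.region for p in scaled]
        assert [7 * p.area for p in base] == [p.area for p in scaled]
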