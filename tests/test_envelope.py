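"""Tests for edge detection, spline refinement, quality rules and timing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrlap.envelope import (
    EnvelopeTrace,
    Spectrogram,
    ThresholdPolicy,
    assess_quality,
    calibrate_pixels,
    detect_raw_edge,
    extract_descent_times,
    refine_edge_polynomial,
)
from mrlap.errors import (
    CalibrationError,
    EmptySignalError,
    RefinementError,
    RuleViolationError,
)
from mrlap.hemo import forward_descent_intervals, solve_lap_eq
from mrlap.synth import NoiseConfig, render_spectrogram, simulate_envelope

from conftest import make_truth


def band_spectrogram(heights_mps, dv=0.02, dt=0.001, n_extra_rows=5):
    """Columns filled from the baseline up to the requested speeds."""
    heights = np.asarray(heights_mps, dtype=float)
    n_rows = int(np.ceil(heights.max() / dv)) + n_extra_rows + 1
    grid = np.zeros((n_rows, heights.size))
    for j, h in enumerate(heights):
        grid[: int(h / dv) + 1, j] = 1.0
    return Spectrogram(grid, dt=dt, dv=dv, baseline_row=0, jet_side="below")


class TestDetect:
    def test_recovers_band_heights_within_one_pixel(self):
        heights = 2.0 + 1.5 * np.sin(np.linspace(0, np.pi, 80))
        spec = band_spectrogram(heights)
        env = detect_raw_edge(spec)
        assert env.column_valid.all()
        assert np.max(np.abs(env.velocity - heights)) <= spec.dv

    def test_all_zero_grid_raises(self):
        spec = Spectrogram(np.zeros((40, 30)), dt=0.001, dv=0.02, baseline_row=0)
        with pytest.raises(EmptySignalError):
            detect_raw_edge(spec)

    def test_uniform_saturated_grid_flagged_invalid(self):
        spec = Spectrogram(np.ones((40, 30)), dt=0.001, dv=0.02, baseline_row=0)
        env = detect_raw_edge(spec)
        assert not env.column_valid.any()
        # the outermost row is reported, so the condition is visible downstream
        assert np.allclose(env.velocity, (39 + 0.5) * 0.02)

    def test_absolute_threshold_policy(self):
        heights = np.full(20, 1.0)
        spec = band_spectrogram(heights)
        env = detect_raw_edge(spec, ThresholdPolicy(method="absolute", value=0.5))
        assert np.max(np.abs(env.velocity - 1.0)) <= spec.dv

    def test_columns_without_signal_flagged(self):
        heights = np.full(20, 2.0)
        spec = band_spectrogram(heights)
        grid = spec.intensity.copy()
        grid[:, 7] = 0.0
        spec = Spectrogram(grid, dt=spec.dt, dv=spec.dv, baseline_row=0)
        env = detect_raw_edge(spec, ThresholdPolicy(method="absolute", value=0.5))
        assert not env.column_valid[7]
        assert env.column_valid[[0, 1, 19]].all()


class TestRefine:
    def cubic_trace(self, n=300, dt=0.001):
        t = np.arange(n) * dt
        v = 1.0 + 10 * t - 40 * t**2 + 30 * t**3
        v = v - v.min() + 0.1
        return EnvelopeTrace(t, v, np.ones(n, dtype=bool))

    def test_polynomial_is_fixed_point(self):
        raw = self.cubic_trace()
        out = refine_edge_polynomial(raw, degree=4)
        assert np.max(np.abs(out.velocity - raw.velocity)) < 1e-9

    def test_single_column_spike_removed(self):
        raw = self.cubic_trace()
        spiked = raw.velocity.copy()
        spiked[150] += 2.0
        out = refine_edge_polynomial(EnvelopeTrace(raw.time, spiked, raw.column_valid))
        assert np.max(np.abs(out.velocity - raw.velocity)) < 0.05
        assert not out.column_valid[150]

    def test_gap_columns_filled_from_fit(self):
        raw = self.cubic_trace()
        rng = np.random.default_rng(0)
        valid = np.ones(len(raw), dtype=bool)
        gaps = rng.choice(len(raw), size=len(raw) // 10, replace=False)
        valid[gaps] = False
        noisy = np.maximum(raw.velocity + rng.normal(0, 0.01, len(raw)), 0.0)
        noisy[~valid] = 0.0
        out = refine_edge_polynomial(EnvelopeTrace(raw.time, noisy, valid))
        assert np.max(np.abs(out.velocity[gaps] - raw.velocity[gaps])) < 0.05

    def test_idempotent_on_noisy_detection(self, noisy_spectrogram):
        raw = detect_raw_edge(noisy_spectrogram)
        once = refine_edge_polynomial(raw)
        twice = refine_edge_polynomial(once)
        assert np.max(np.abs(twice.velocity - once.velocity)) < 1e-9
        assert np.array_equal(once.column_valid, twice.column_valid)

    def test_too_few_valid_columns(self):
        t = np.arange(10) * 0.001
        v = np.linspace(3, 1, 10)
        valid = np.zeros(10, dtype=bool)
        valid[:3] = True
        with pytest.raises(RefinementError):
            refine_edge_polynomial(EnvelopeTrace(t, v, valid), degree=4)


class TestQualityRules:
    def test_full_decay_is_calculable(self):
        env = simulate_envelope(make_truth(lap=10.0, tau=0.05), dt=0.001)
        q = assess_quality(env)
        assert q.calculable and q.has_complete_descent
        assert q.peak_velocity == pytest.approx(np.sqrt(95) / 2, abs=0.01)

    def test_low_peak_not_calculable(self):
        t = np.arange(200) * 0.001
        v = 2.8 * np.exp(-(((t - 0.1) / 0.08) ** 2))
        q = assess_quality(EnvelopeTrace(t, v, np.ones(200, bool)))
        assert not q.calculable
        assert any("peak" in r for r in q.failure_reasons)

    def test_truncated_descent_not_calculable(self):
        env = simulate_envelope(make_truth(lap=10.0, tau=0.05), dt=0.001)
        cut = np.searchsorted(-env.velocity[np.argmax(env.velocity):], -1.5) + np.argmax(env.velocity)
        q = assess_quality(
            EnvelopeTrace(env.time[:cut], env.velocity[:cut], env.column_valid[:cut])
        )
        assert not q.calculable and not q.has_complete_descent

    def test_extraction_refuses_uncalculable_naming_rule(self):
        t = np.arange(200) * 0.001
        v = np.maximum(2.5 - 5 * np.abs(t - 0.1), 0.01)
        with pytest.raises(RuleViolationError, match="peak"):
            extract_descent_times(EnvelopeTrace(t, v, np.ones(200, bool)))

    @settings(derandomize=True, max_examples=40)
    @given(peak=st.floats(0.5, 2.99), tau=st.floats(0.02, 0.1))
    def test_no_times_from_sub3_peaks(self, peak, tau):
        t = np.arange(300) * 0.001
        v = peak * np.exp(-np.maximum(t - 0.05, 0) / tau) * np.minimum(t / 0.05, 1.0)
        with pytest.raises(RuleViolationError):
            extract_descent_times(EnvelopeTrace(t, np.maximum(v, 0), np.ones(300, bool)))


class TestDescentTimes:
    def test_noiseless_render_matches_forward_model(self, noiseless_spectrogram):
        raw = detect_raw_edge(noiseless_spectrogram)
        env = refine_edge_polynomial(raw)
        times = extract_descent_times(env)
        d12, d13 = forward_descent_intervals(10.0, 0.05)
        dt = noiseless_spectrogram.dt
        assert times.t1 - times.t2 == pytest.approx(d12, abs=dt)
        assert times.t1 - times.t3 == pytest.approx(d13, abs=dt)

    def test_linear_descent_crossings_exact(self):
        # v(t) = 4 - 10 t: crossings of 3/2/1 m/s at t = 0.1, 0.2, 0.3
        t = np.arange(0, 0.4, 0.001)
        v = 4.0 - 10.0 * t
        times = extract_descent_times(EnvelopeTrace(t, np.maximum(v, 0), np.ones(t.size, bool)))
        assert times.t3 == pytest.approx(0.1, abs=0.001)
        assert times.t2 == pytest.approx(0.2, abs=0.001)
        assert times.t1 == pytest.approx(0.3, abs=0.001)

    def test_first_crossing_taken_when_noise_recrosses(self):
        t = np.arange(0, 0.5, 0.001)
        v = np.interp(
            t,
            [0.0, 0.05, 0.3, 0.35, 0.4, 0.45],
            [0.0, 4.0, 0.9, 1.05, 0.5, 0.2],
        )
        env = EnvelopeTrace(t, v, np.ones(t.size, bool))
        times = extract_descent_times(env, assess_quality(env, monotone_tol=0.2))
        # brute-force scan of every downward 1 m/s crossing after the peak
        ipk = int(np.argmax(v))
        all_crossings = [
            t[i] + (v[i] - 1.0) / (v[i] - v[i + 1]) * 0.001
            for i in range(ipk, t.size - 1)
            if v[i] >= 1.0 > v[i + 1]
        ]
        assert len(all_crossings) == 2
        assert times.t1 == pytest.approx(min(all_crossings), abs=1e-9)


class TestCalibration:
    def test_velocity_axis_span(self):
        spec = calibrate_pixels(np.zeros((100, 200)) + 0.1, 0.001, 0.05, 0, "below")
        rows = spec.jet_rows_outward()
        assert (rows[-1] - spec.baseline_row) * spec.dv == pytest.approx(4.95)

    def test_baseline_outside_grid(self):
        with pytest.raises(CalibrationError):
            calibrate_pixels(np.zeros((100, 50)), 0.001, 0.02, 150)

    def test_time_scale_changes_tau_not_lap(self, reference_truth):
        env = simulate_envelope(reference_truth, dt=0.002)
        spec = render_spectrogram(env, dv=0.02, noise=NoiseConfig.none())
        results = {}
        for dt in (0.002, 0.004):
            rescaled = calibrate_pixels(spec.intensity, dt, spec.dv, spec.baseline_row)
            times = extract_descent_times(detect_raw_edge(rescaled))
            results[dt] = (times.t1 - times.t3, solve_lap_eq(times))
        assert results[0.004][0] == pytest.approx(2 * results[0.002][0], rel=1e-9)
        assert results[0.004][1].lap == pytest.approx(results[0.002][1].lap, abs=1e-6)
        assert results[0.004][1].tau == pytest.approx(2 * results[0.002][1].tau, rel=1e-6)
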