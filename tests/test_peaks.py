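"""Peak rules: averaging, detection thresholds/windows, onset interpolation."""

import numpy as np
import pytest

from optolfp import (
    StimCondition,
    condition_average,
    detect_peaks,
    interpolate_onset,
    session_peak_table,
    simulate_session,
    single_trial_n1,
)
from optolfp.preprocess import preprocess_session

from conftest import gaussian_trough, make_epoch


class TestConditionAverage:
    def test_single_epoch_is_returned_verbatim(self):
        e = make_epoch(np.sin(np.linspace(0, 5, 400)))
        avg = condition_average([e])
        np.testing.assert_array_equal(avg.trace_mV, e.trace_mV)
        assert avg.n_trials == 1

    def test_opposite_epochs_cancel(self):
        x = np.sin(np.linspace(0, 5, 400))
        avg = condition_average([make_epoch(x), make_epoch(-x)])
        np.testing.assert_allclose(avg.trace_mV, 0.0, atol=1e-12)

    def test_mixed_conditions_rejected(self):
        a = make_epoch(np.zeros(400), condition=StimCondition(1, 1))
        b = make_epoch(np.zeros(400), condition=StimCondition(2, 1))
        with pytest.raises(ValueError, match="mixed"):
            condition_average([a, b])

    def test_baseline_sd_shrinks_as_one_over_sqrt_k(self):
        # k noisy copies of the same trace: SD of the mean ~ sigma/sqrt(k)
        rng = np.random.default_rng(7)
        fs, sigma, k = 1000.0, 1.0, 25
        base = np.zeros(600)
        epochs = [
            make_epoch(base + rng.normal(0, sigma, base.size), fs=fs, pre_ms=500)
            for _ in range(k)
        ]
        avg = condition_average(epochs, baseline_sd_ms=(-500.0, 0.0))
        assert avg.baseline_sd_mV == pytest.approx(sigma / np.sqrt(k), rel=0.15)


class TestDetection:
    def _avg(self, trace, fs=1000.0):
        return condition_average([make_epoch(trace, fs=fs)])

    def test_clean_trough_detected_at_injected_latency(self):
        fs = 1000.0
        t = (np.arange(400) - 150) / fs * 1000.0
        avg = self._avg(gaussian_trough(t, depth=0.5, latency_ms=10.0))
        p1, n1 = detect_peaks(avg)
        assert n1.detected
        assert n1.amplitude_mV == pytest.approx(-0.5, rel=1e-6)
        assert abs(n1.latency_ms - 10.0) <= 1000.0 / fs
        assert not p1.detected

    def test_trough_outside_window_not_detected(self):
        t = (np.arange(400) - 150)  # 1 kHz -> ms
        # compact-support trough strictly outside the 5-20 ms window
        avg = self._avg(np.where((t >= 24) & (t <= 26), -0.5, 0.0))
        _, n1 = detect_peaks(avg)
        assert not n1.detected

    def test_subthreshold_trough_not_detected(self):
        rng = np.random.default_rng(3)
        t = (np.arange(400) - 150)
        noise = rng.normal(0, 0.1, t.size)
        trace = noise.copy()
        avg = self._avg(trace)
        depth = 0.8 * avg.baseline_sd_mV
        # place a trough shallower than the threshold; the pre-stimulus noise
        # fixes the threshold, the window minimum stays above it
        trace2 = np.where((t >= 5) & (t <= 20), -depth * 0.999, 0.0)
        trace2[t < 0] = noise[t < 0]
        avg2 = self._avg(trace2)
        _, n1 = detect_peaks(avg2)
        assert not n1.detected

    def test_flat_trace_detects_nothing(self):
        avg = self._avg(np.zeros(400))
        p1, n1 = detect_peaks(avg)
        assert not p1.detected and not n1.detected

    def test_zero_sd_threshold_admits_any_nonzero_extremum(self):
        t = (np.arange(400) - 150)
        trace = np.where((t >= 9) & (t <= 11), -1e-6, 0.0)
        _, n1 = detect_peaks(self._avg(trace))
        assert n1.detected

    def test_detection_is_monotone_in_trough_depth(self):
        rng = np.random.default_rng(5)
        t = (np.arange(400) - 150)
        noise = np.where(t < 0, rng.normal(0, 0.05, t.size), 0.0)
        was_detected = False
        for depth in np.linspace(0.0, 0.5, 26):
            trace = noise + gaussian_trough(t, depth=depth)
            _, n1 = detect_peaks(self._avg(trace))
            assert n1.detected or not was_detected   # never flips back off
            was_detected = n1.detected
        assert was_detected


class TestOnset:
    def _avg_from(self, t, trace):
        return condition_average([make_epoch(trace, time_ms=t)])

    def _linear_flank(self, dt_ms=0.1):
        # 0 until 8 ms, then linear to -1 mV at 10 ms, constant after
        t = np.arange(-150, 21, dt_ms)
        trace = np.where(t <= 8.0, 0.0, np.where(t < 10.0, -(t - 8.0) / 2.0, -1.0))
        return t, trace

    def test_linear_flank_onset_is_exact(self):
        t, trace = self._linear_flank()
        avg = self._avg_from(t, trace)
        _, n1 = detect_peaks(avg)
        assert n1.detected
        onset = interpolate_onset(avg, n1)
        assert onset == pytest.approx(8.0, abs=1e-6)

    def test_onset_is_scale_invariant(self):
        t, trace = self._linear_flank()
        for a in (0.2, 3.0, 40.0):
            avg = self._avg_from(t, a * trace)
            _, n1 = detect_peaks(avg)
            assert interpolate_onset(avg, n1) == pytest.approx(8.0, abs=1e-6)

    def test_onset_shifts_with_the_flank(self):
        t, trace = self._linear_flank()
        shifted = self._avg_from(t + 2.0, trace)
        _, n1 = detect_peaks(shifted)
        assert interpolate_onset(shifted, n1) == pytest.approx(10.0, abs=1e-6)

    def test_band_widens_when_sampling_is_coarse(self):
        # 0.4 ms sampling puts one sample in the 45-55% band (frac 0.5) but
        # two in the first widened band (frac 0.4, 0.6): onset still exact
        t, trace = self._linear_flank(dt_ms=0.4)
        avg = self._avg_from(t, trace)
        _, n1 = detect_peaks(avg)
        onset = interpolate_onset(avg, n1)
        assert onset == pytest.approx(8.0, abs=1e-6)

    def test_unusable_flank_is_an_error(self):
        # instantaneous step: no sample ever lies strictly inside any band
        t = np.arange(-150.0, 21.0)
        trace = np.where(t >= 10.0, -1.0, 0.0)
        trace[t < 0] = 0.0
        avg = self._avg_from(t, trace)
        _, n1 = detect_peaks(avg)
        with pytest.raises(ValueError, match="band"):
            interpolate_onset(avg, n1)

    def test_onset_precedes_peak_on_simulated_average(self, clean_cfg):
        sess = simulate_session(clean_cfg, seed=8)
        table = session_peak_table(preprocess_session(sess).epochs, "s")
        n_checked = 0
        for row in table.rows:
            if row.n1.detected and row.n1.onset_latency_ms is not None:
                assert row.n1.onset_latency_ms < row.n1.latency_ms
                n_checked += 1
        assert n_checked > 0


class TestSingleTrialN1:
    def test_matches_average_for_identical_trials(self):
        t = (np.arange(400) - 150)
        trace = gaussian_trough(t)
        e = make_epoch(trace, time_ms=t)
        avg = condition_average([e, e])
        _, n1 = detect_peaks(avg)
        assert single_trial_n1(e) == pytest.approx(n1.amplitude_mV)

    def test_windowed_minimum_of_positive_trace(self):
        t = (np.arange(400) - 150)
        e = make_epoch(np.full(t.size, 0.3), time_ms=t)
        assert single_trial_n1(e) == pytest.approx(0.3)

    def test_constant_offset_shifts_the_minimum(self):
        t = (np.arange(400) - 150.0)
        trace = gaussian_trough(t)
        e0 = make_epoch(trace, time_ms=t)
        e1 = make_epoch(trace - 0.2, time_ms=t)
        assert single_trial_n1(e1) == pytest.approx(single_trial_n1(e0) - 0.2)
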