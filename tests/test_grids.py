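"""Grid summaries: CoV, robustness counts, inclusion rule, I/O curves, irradiance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optolfp import (
    PeakMeasurement,
    PeakRow,
    SessionPeakTable,
    StimCondition,
    condition_cov,
    detectability_grid,
    io_curves,
    irradiance,
    median_amplitude_grid,
    normalize_sessions,
    robustness_grids,
)
from optolfp.grids import count_robust


def make_table(subject_id, cells):
    """cells: {(dur, int): (n1_amp or None, per-trial amplitude list)}."""
    table = SessionPeakTable(subject_id=subject_id)
    for (d, i), (amp, trials) in cells.items():
        detected = amp is not None
        n1 = PeakMeasurement(
            kind="N1", detected=detected,
            amplitude_mV=amp if detected else None,
            latency_ms=10.0 if detected else None,
            threshold_mV=0.01,
        )
        p1 = PeakMeasurement(kind="P1", detected=False, threshold_mV=0.01)
        table.rows.append(
            PeakRow(
                condition=StimCondition(d, i), p1=p1, n1=n1,
                trial_n1_mV=np.asarray(trials, dtype=float),
                n_trials=len(trials),
            )
        )
    return table


class TestCov:
    def test_constant_trials_have_zero_cov(self):
        assert condition_cov([-1.0, -1.0, -1.0]) == 0.0

    def test_frozen_example(self):
        # sample SD of {1,2,3} is 1, mean 2 -> CoV 0.5
        assert condition_cov([-1.0, -2.0, -3.0]) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        scale=st.floats(0.01, 100.0),
        sign=st.sampled_from([-1.0, 1.0]),
        amps=st.lists(st.floats(0.1, 10.0), min_size=2, max_size=20),
    )
    def test_scale_invariance(self, scale, sign, amps):
        a = -np.asarray(amps)
        assert condition_cov(sign * scale * a) == pytest.approx(
            condition_cov(a), rel=1e-9
        )

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="2 trials"):
            condition_cov([-1.0])

    def test_zero_mean_is_infinite(self):
        assert condition_cov([0.0, 0.0]) == math.inf

    def test_threshold_is_strict(self):
        assert count_robust(np.array([1.0, 0.99, 1.01]), 1.0) == 1


class TestRobustnessGrids:
    def test_constant_trials_make_every_session_robust(self):
        tables = [
            make_table(f"s{k}", {(1.0, 1.0): (-0.5, [-0.5, -0.5, -0.5])})
            for k in range(4)
        ]
        cov_grid, robust_grid = robustness_grids(tables)
        assert cov_grid.values[0, 0] == 0.0
        assert robust_grid.values[0, 0] == 4

    def test_undetected_sessions_do_not_contribute(self):
        tables = [
            make_table("a", {(1.0, 1.0): (-0.5, [-0.4, -0.5, -0.6])}),
            make_table("b", {(1.0, 1.0): (None, [-0.1, 0.1, -0.2])}),
        ]
        cov_grid, robust_grid = robustness_grids(tables)
        assert cov_grid.counts[0, 0] == 1      # only the detected session
        assert robust_grid.values[0, 0] == 1

    def test_high_jitter_weak_condition_is_never_robust(self, calib_cfg):
        # lognormal trial amplitudes with CoV 2 essentially never yield a
        # sample CoV below 1 over 150 trials
        rng = np.random.default_rng(12)
        sigma = math.sqrt(math.log1p(4.0))
        tables = []
        for k in range(6):
            trials = -rng.lognormal(-0.5 * sigma**2, sigma, 150)
            tables.append(make_table(f"s{k}", {(0.1, 0.25): (-0.01, trials)}))
        _, robust_grid = robustness_grids(tables)
        assert robust_grid.values[0, 0] == 0


class TestMedianAmplitudeGrid:
    def _tables(self, n_robust, n_sessions=15):
        tables = []
        for k in range(n_sessions):
            if k < n_robust:
                cell = (-0.4 - 0.01 * k, [-0.4, -0.41, -0.39])   # CoV ~ 0
            else:
                cell = (None, [0.0, 0.0])
            tables.append(make_table(f"s{k:02d}", {(1.0, 1.0): cell}))
        return tables

    def test_three_of_fifteen_is_included(self):
        grid = median_amplitude_grid(self._tables(3))
        assert grid.included[0, 0]
        assert np.isfinite(grid.values[0, 0])

    def test_two_of_fifteen_is_excluded(self):
        grid = median_amplitude_grid(self._tables(2))
        assert not grid.included[0, 0]
        assert np.isnan(grid.values[0, 0])

    def test_median_of_three_magnitudes(self):
        tables = [
            make_table(s, {(1.0, 1.0): (a, [a, a, a])})
            for s, a in [("a", -0.2), ("b", -0.4), ("c", -0.9)]
        ]
        grid = median_amplitude_grid(tables)
        assert grid.values[0, 0] == pytest.approx(0.4)

    def test_even_count_median_uses_midpoint(self):
        tables = [
            make_table(s, {(1.0, 1.0): (a, [a, a])})
            for s, a in [("a", -0.2), ("b", -0.4), ("c", -0.6), ("d", -1.0)]
        ]
        grid = median_amplitude_grid(tables)
        assert grid.values[0, 0] == pytest.approx(0.5)

    def test_robust_count_bounded_by_detect_count(self):
        tables = self._tables(5)
        cov_grid, robust_grid = robustness_grids(tables)
        assert robust_grid.values[0, 0] <= cov_grid.counts[0, 0] <= len(tables)


class TestDetectability:
    def test_fraction_and_count(self):
        tables = [
            make_table("a", {(1.0, 1.0): (-0.5, [-0.5, -0.5])}),
            make_table("b", {(1.0, 1.0): (None, [0.0, 0.0])}),
        ]
        grid = detectability_grid(tables, "N1")
        assert grid.values[0, 0] == pytest.approx(0.5)
        assert grid.counts[0, 0] == 1


class TestIOCurves:
    def _tables(self):
        cells = {
            (1.0, 1.0): (-0.2, [-0.2, -0.2]),
            (1.0, 10.0): (-0.8, [-0.8, -0.8]),
        }
        return [make_table(f"s{k}", dict(cells)) for k in range(5)]

    def test_session_maximum_normalises_to_one(self):
        norm = normalize_sessions(self._tables())
        assert (norm.groupby("subject_id")["amplitude"].max() == 1.0).all()
        assert norm["amplitude"].between(0, 1).all()

    def test_identical_sessions_have_zero_bootstrap_se(self):
        curves = io_curves(self._tables(), n_boot=200, seed=0)
        assert (curves["se_median"] == 0.0).all()
        assert curves.loc[curves.intensity_mW == 10.0, "median"].iloc[0] == 1.0

    def test_session_without_detection_is_skipped(self):
        tables = self._tables() + [
            make_table("empty", {(1.0, 1.0): (None, [0.0, 0.0])})
        ]
        norm = normalize_sessions(tables)
        assert "empty" not in set(norm["subject_id"])


class TestIrradiance:
    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            irradiance(0.0)
        with pytest.raises(ValueError):
            irradiance(1.0, -5.0)

    def test_quarter_with_doubled_diameter(self):
        assert irradiance(2.0, 110.0) == pytest.approx(irradiance(2.0, 55.0) / 4.0)
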