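"""Self-validation studies: filter metrics, recovery, statistical calibration.

These functions re-derive, at run time, the quantities that certify the
pipeline: the filter chain's frequency-response figures, noise-free
peak/onset recovery against the analytic template, type-I error and power
of the within-subject permutation test under the generator's null and
graded effect sizes, and end-to-end recovery of a known gain surface from
simulated sessions.  The reduced study sizes used here (3 x 3 or 5 x 4
grids, 8-12 subjects, 2-3 kHz sampling) are the package's scaled-down
standard conditions; docs/methods.md states them.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.stats

from . import grids as grids_mod
from .peaks import detect_peaks, interpolate_onset, session_peak_table
from .preprocess import apply_filters, preprocess_session
from .simulate import (
    SimulationConfig,
    evoked_template,
    simulate_response_table,
    simulate_study,
)
from .stats import permutation_test

#: condition-level generator settings for the statistical calibration studies
CALIBRATION_CONFIG = SimulationConfig(
    durations_ms=(1.0, 2.0, 5.0),
    intensities_mW=(0.5, 2.0, 10.0),
    n_trials_per_condition=12,
    subject_sd=0.2,
    trial_jitter_cv=0.5,
)

#: full-signal generator settings for the end-to-end recovery study
RECOVERY_CONFIG = SimulationConfig(
    durations_ms=(0.5, 1.0, 2.0, 5.0, 10.0),
    intensities_mW=(0.25, 1.0, 2.0, 10.0),
    n_trials_per_condition=16,
    sampling_rate_Hz=2000.0,
    noise_sd_mV=0.02,
    line_amp_mV=0.03,
    trial_jitter_cv=0.3,
    subject_sd=0.2,
    block_size=8,
    gain_factor=100,
)

#: intensity-effect weights of the power curve (null-adjacent to full effect)
POWER_EFFECT_WEIGHTS = (0.1, 0.3, 1.0)


def filter_metrics(sampling_rate_Hz: float = 3000.0) -> dict:
    """Measured frequency-response figures of the default zero-phase chain.

    Sinusoid attenuation at 50 Hz (notch) and gain at 30 Hz (the geometric
    centre of the 3-300 Hz band), DC residual, and the peak shift of a
    symmetric Gaussian pulse (zero-phase check).
    """
    fs = sampling_rate_Hz
    t = np.arange(int(10 * fs)) / fs
    mid = slice(int(2 * fs), int(8 * fs))

    def sine_gain(freq):
        x = np.sin(2 * math.pi * freq * t)
        y = apply_filters(x, fs)
        return float(np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2)))

    g50 = sine_gain(50.0)
    g30 = sine_gain(30.0)
    dc = apply_filters(np.ones(t.size), fs)
    pulse = np.exp(-((t - 5.0) ** 2) / (2 * 0.0015**2))
    shift = int(np.argmax(apply_filters(pulse, fs)) - np.argmax(pulse))
    return dict(
        notch_attenuation_db=float(-20.0 * math.log10(g50)),
        gain_30hz=g30,
        dc_residual=float(np.abs(dc[mid]).max()),
        pulse_peak_shift_samples=shift,
    )


def template_recovery(sampling_rate_Hz: float = 3000.0) -> dict:
    """Noise-free pipeline vs analytic template: latency/amplitude errors.

    Simulates a noise-free session, runs the full preprocessing and peak
    chain, and compares the measured N1 against the injected template per
    condition.  Errors are worst-case across conditions.
    """
    cfg = SimulationConfig(
        durations_ms=(1.0, 5.0),
        intensities_mW=(2.0, 10.0),
        n_trials_per_condition=2,
        sampling_rate_Hz=sampling_rate_Hz,
        noise_sd_mV=0.0,
        line_amp_mV=0.0,
        trial_jitter_cv=0.0,
        subject_sd=0.0,
        block_size=2,
        gain_factor=100,
    )
    sess = simulate_study(cfg, 1, seed=0)[0]
    prep = preprocess_session(sess)
    table = session_peak_table(prep.epochs, sess.subject_id)
    lat_err = 0.0
    amp_err = 0.0
    trace_dev = 0.0
    for row in table.rows:
        assert row.n1.detected
        t_ms = prep.epochs[0].time_ms
        tmpl = evoked_template(t_ms, row.condition, cfg)
        true_amp = tmpl.min()
        true_lat = t_ms[np.argmin(tmpl)]
        lat_err = max(lat_err, abs(row.n1.latency_ms - true_lat))
        amp_err = max(amp_err, abs(row.n1.amplitude_mV - true_amp) / abs(true_amp))
        epochs = [e for e in prep.epochs if e.condition == row.condition]
        window = (t_ms >= 0) & (t_ms <= 20)
        trace_dev = max(
            trace_dev,
            float(np.max(np.abs(epochs[0].trace_mV[window] - tmpl[window])))
            / abs(true_amp),
        )
    return dict(
        n1_latency_error_ms=float(lat_err),
        n1_amplitude_rel_error=float(amp_err),
        trace_rel_deviation=float(trace_dev),
        sample_period_ms=1000.0 / sampling_rate_Hz,
    )


def onset_recovery() -> dict:
    """Analytic linear-flank onset: exact recovery plus equivariances."""
    from .core import StimCondition, TrialEpoch
    from .peaks import condition_average

    t = np.arange(-150.0, 21.0, 0.1)
    trace = np.where(t <= 8.0, 0.0, np.where(t < 10.0, -(t - 8.0) / 2.0, -1.0))

    def onset_of(tr, time):
        avg = condition_average(
            [TrialEpoch(StimCondition(1, 1), time, tr)]
        )
        _, n1 = detect_peaks(avg)
        return interpolate_onset(avg, n1)

    base = onset_of(trace, t)
    scaled = onset_of(3.7 * trace, t)
    shifted = onset_of(trace, t + 2.0)
    return dict(
        onset_error_ms=float(abs(base - 8.0)),
        scale_equivariance_error_ms=float(abs(scaled - base)),
        shift_equivariance_error_ms=float(abs(shifted - (base + 2.0))),
    )


def type_i_error(
    effect: str = "intensity",
    n_runs: int = 200,
    n_permutations: int = 500,
    n_subjects: int = 8,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical rejection rate under the generator's null for one factor.

    The gain surface is made flat in the tested factor (effect weight 0);
    each run draws a fresh response table and runs the permutation test.
    """
    weights = {"intensity_weight": 1.0, "duration_weight": 1.0}
    weights[f"{effect}_weight"] = 0.0
    root = np.random.SeedSequence(seed)
    rejections = 0
    for k, child in enumerate(root.spawn(n_runs)):
        s1, s2 = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in child.spawn(2))
        tab = simulate_response_table(
            CALIBRATION_CONFIG, n_subjects, seed=s1, **weights
        )
        res = permutation_test(
            tab, effect, n_permutations=n_permutations, seed=s2, engine="fast",
            alpha=alpha,
        )
        rejections += res.significant
    rate = rejections / n_runs
    # 95% binomial interval around alpha for this n_runs
    half = 1.96 * math.sqrt(alpha * (1 - alpha) / n_runs)
    return dict(
        rate=rate,
        n_runs=n_runs,
        n_permutations=n_permutations,
        interval=(alpha - half, alpha + half),
    )


def power_curve(
    effect: str = "intensity",
    weights: tuple[float, ...] = POWER_EFFECT_WEIGHTS,
    n_runs: int = 60,
    n_permutations: int = 300,
    n_subjects: int = 8,
    seed: int = 0,
) -> dict:
    """Rejection rate at graded effect sizes of the tested factor."""
    root = np.random.SeedSequence(seed)
    powers = {}
    for w, branch in zip(weights, root.spawn(len(weights))):
        hits = 0
        for child in branch.spawn(n_runs):
            s1, s2 = (
                int(c.generate_state(1)[0] % (2**31 - 1)) for c in child.spawn(2)
            )
            tab = simulate_response_table(
                CALIBRATION_CONFIG, n_subjects, seed=s1,
                **{f"{effect}_weight": w},
            )
            res = permutation_test(
                tab, effect, n_permutations=n_permutations, seed=s2, engine="fast"
            )
            hits += res.significant
        powers[w] = hits / n_runs
    return dict(effect=effect, powers=powers, n_runs=n_runs)


def recovery_study(n_sessions: int = 12, seed: int = 0) -> dict:
    """End-to-end parameter recovery from full simulated sessions.

    Simulates sessions with the known gain surface, runs the complete
    pipeline, and compares the included-cell median amplitude grid against
    the true A(I, d) surface (Spearman rank correlation); also measures the
    largest decrease of the group-median I/O curve along increasing
    intensity at fixed duration (0 for a perfectly monotone curve).
    """
    from .simulate import n1_gain

    cfg = RECOVERY_CONFIG
    sessions = simulate_study(cfg, n_sessions, seed=seed)
    tables = [
        session_peak_table(preprocess_session(s).epochs, s.subject_id)
        for s in sessions
    ]
    grid = grids_mod.median_amplitude_grid(tables)
    est, true = [], []
    for i, d in enumerate(grid.durations_ms):
        for j, inten in enumerate(grid.intensities_mW):
            if grid.included[i, j]:
                est.append(grid.values[i, j])
                true.append(float(n1_gain(inten, d, cfg)))
    rho = float(scipy.stats.spearmanr(est, true).statistic)

    curves = grids_mod.io_curves(tables, n_boot=200, seed=seed)
    violation = 0.0
    for d, g in curves.groupby("duration_ms"):
        med = g.sort_values("intensity_mW")["median"].to_numpy()
        if med.size > 1:
            violation = max(violation, float(np.max(-np.diff(med), initial=0.0)))
    return dict(
        spearman_rho=rho,
        n_included_cells=len(est),
        io_monotonicity_violation=violation,
        n_sessions=n_sessions,
    )
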