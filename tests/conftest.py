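"""Shared fixtures: reduced-scale simulation configs and epoch builders.

Tests run the generator at 2-3 kHz with small grids and trial counts; the
config defaults themselves stay at full study scale (30 kHz, 7x6 grid,
150 trials).
"""

import numpy as np
import pytest

from optolfp import SimulationConfig, StimCondition, TrialEpoch


@pytest.fixture
def clean_cfg():
    """Noise-free generator: every epoch of a condition is identical."""
    return SimulationConfig(
        durations_ms=(1.0, 5.0),
        intensities_mW=(2.0, 10.0),
        n_trials_per_condition=2,
        sampling_rate_Hz=3000.0,
        noise_sd_mV=0.0,
        line_amp_mV=0.0,
        trial_jitter_cv=0.0,
        subject_sd=0.0,
        block_size=2,
        gain_factor=100,
    )


@pytest.fixture
def noisy_cfg():
    """Small noisy session for end-to-end smoke paths."""
    return SimulationConfig(
        durations_ms=(0.5, 5.0),
        intensities_mW=(1.0, 10.0),
        n_trials_per_condition=6,
        sampling_rate_Hz=3000.0,
        noise_sd_mV=0.02,
        line_amp_mV=0.03,
        trial_jitter_cv=0.3,
        subject_sd=0.1,
        block_size=3,
        gain_factor=100,
    )


@pytest.fixture
def calib_cfg():
    """Condition-level calibration config for the statistics suites."""
    return SimulationConfig(
        durations_ms=(1.0, 2.0, 5.0),
        intensities_mW=(0.5, 2.0, 10.0),
        n_trials_per_condition=12,
        subject_sd=0.2,
        trial_jitter_cv=0.5,
    )


def make_epoch(trace, time_ms=None, condition=None, fs=1000.0, pre_ms=150.0):
    """Build a TrialEpoch from a trace; default axis covers [-150, ...] ms."""
    trace = np.asarray(trace, dtype=float)
    if time_ms is None:
        n = trace.size
        time_ms = (np.arange(n) - int(round(pre_ms / 1000.0 * fs))) / fs * 1000.0
    if condition is None:
        condition = StimCondition(1.0, 1.0)
    return TrialEpoch(condition=condition, time_ms=np.asarray(time_ms), trace_mV=trace)


def gaussian_trough(time_ms, depth=0.5, latency_ms=10.0, sigma_ms=1.5):
    """Analytic N1-like trough used to probe the peak rules."""
    t = np.asarray(time_ms, dtype=float)
    return -depth * np.exp(-((t - latency_ms) ** 2) / (2.0 * sigma_ms**2))
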