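"""Synthetic multi-session LFP generator.

No public recordings accompany the study design this package implements, so
every downstream stage is exercised on synthetic sessions that reproduce the
statistical structure the analysis assumes:

* a biphasic evoked template (positive P1 bump, negative N1 trough) whose N1
  magnitude follows a saturating gain surface A(I, d) = A_max * I/(I + I50)
  * (1 - exp(-d / tau_d)) -- Michaelis-Menten in intensity (no plateau over
  the tested 0.25-10 mW range when I50 is of that order) and exponential
  saturation in duration (plateau at 5-10 ms);
* 50 Hz line noise whose starting phase advances from trial to trial by
  2*pi*50*T mod 2*pi -- zero for T = 1.000 s, ~2.2614 rad for T = pi/3 s,
  the trial-length trick used to decorrelate mains noise from the stimulus;
* broadband background noise (white by default, 1/f optionally);
* multiplicative lognormal trial-to-trial amplitude jitter (controls the
  coefficient of variation of single-trial N1 amplitudes);
* a multiplicative Gaussian between-subject random effect.

All signal components are synthesised on a common mV scale referenced to the
x1000 amplifier setting; the recorded trace is that signal scaled by
gain_factor/1000, so downstream gain compensation recovers the template in
mV for either gain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import SessionRecording, StimCondition

logger = logging.getLogger("optolfp")

#: mains frequency emulated by the generator (Hz)
LINE_FREQ_HZ = 50.0


@dataclass
class SimulationConfig:
    """Study-design and generator parameters.

    The defaults are the full study conditions: a 7 x 6 duration-intensity
    grid, 150 trials per condition (6,300 trials per session), pi/3 s trials
    digitised at 30 kHz.  Tests and examples pass reduced sampling rates,
    grids and trial counts; the defaults stay at study scale.
    """

    durations_ms: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)
    intensities_mW: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 5.0, 10.0)
    n_trials_per_condition: int = 150
    sampling_rate_Hz: float = 30_000.0
    trial_length_s: float = math.pi / 3
    gain_factor: int = 100
    # evoked-template gain surface
    A_max_mV: float = 0.5
    I50_mW: float = 10.0
    tau_d_ms: float = 2.0
    # template morphology
    p1_fraction: float = 0.4
    p1_latency_ms: float = 4.0
    n1_latency_ms: float = 10.0
    peak_width_ms: float = 1.5          # Gaussian sigma of each deflection
    # noise model
    noise_sd_mV: float = 0.05
    line_amp_mV: float = 0.05
    trial_jitter_cv: float = 0.5
    subject_sd: float = 0.2
    channel_noise_frac: float = 0.2     # per-channel noise SD as fraction of noise_sd
    noise_color: str = "white"          # "white" or "pink"
    # session layout
    block_size: int = 25                # trials per intermingled block
    pad_s: float = 1.0                  # noise-only padding at both ends
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("durations_ms", "intensities_mW"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size == 0 or np.any(vals <= 0) or np.any(np.diff(vals) <= 0):
                raise ValueError(
                    f"{name} must be strictly positive and strictly increasing"
                )
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if int(self.gain_factor) not in (100, 1000):
            raise ValueError("gain_factor must be 100 or 1000")
        if self.noise_color not in ("white", "pink"):
            raise ValueError("noise_color must be 'white' or 'pink'")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        span_ms = self.template_span_ms
        if span_ms > self.trial_length_s * 1000.0:
            raise ValueError(
                f"evoked-template span ({span_ms:.1f} ms) exceeds the trial "
                f"length ({self.trial_length_s * 1000.0:.1f} ms)"
            )
        if self.trial_length_s * self.sampling_rate_Hz < 2:
            raise ValueError("trial too short for the sampling rate")

    @property
    def template_span_ms(self) -> float:
        """Support of the evoked template after stimulus onset."""
        return max(self.p1_latency_ms, self.n1_latency_ms) + 4.0 * self.peak_width_ms

    @property
    def conditions(self) -> list[StimCondition]:
        """All grid cells, sorted by (duration, intensity)."""
        return [
            StimCondition(d, i) for d in self.durations_ms for i in self.intensities_mW
        ]

    @property
    def n_conditions(self) -> int:
        return len(self.durations_ms) * len(self.intensities_mW)

    @property
    def n_trials_total(self) -> int:
        return self.n_conditions * self.n_trials_per_condition

    def with_(self, **kwargs) -> "SimulationConfig":
        """Copy with selected fields replaced (re-validated)."""
        return replace(self, **kwargs)


def n1_gain(
    intensity_mW: float | np.ndarray,
    duration_ms: float | np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """N1 magnitude (mV, positive) of the gain surface A(I, d).

    A = A_max * I/(I + I50) * (1 - exp(-d/tau_d)).  Vanishes at I = 0; at
    I = I50 and d >> tau_d it equals A_max/2; saturates in duration but, for
    I50 comparable to the largest tested intensity, not in intensity.
    """
    I = np.asarray(intensity_mW, dtype=float)
    d = np.asarray(duration_ms, dtype=float)
    denom = I + config.I50_mW
    with np.errstate(invalid="ignore", divide="ignore"):
        sat_i = np.where(denom > 0, I / np.where(denom > 0, denom, 1.0), 0.0)
    sat_d = -np.expm1(-d / config.tau_d_ms) if config.tau_d_ms > 0 else np.ones_like(d)
    return config.A_max_mV * sat_i * sat_d


def evoked_template(
    t_ms: np.ndarray, condition: StimCondition, config: SimulationConfig
) -> np.ndarray:
    """Noise-free evoked waveform (mV) at times `t_ms` after stimulus onset.

    A positive Gaussian bump at p1_latency_ms (amplitude p1_fraction of the
    N1 magnitude) plus a negative Gaussian trough at n1_latency_ms whose
    depth follows the gain surface.  Pure and deterministic.
    """
    t = np.asarray(t_ms, dtype=float)
    a_n1 = float(n1_gain(condition.intensity_mW, condition.duration_ms, config))
    w2 = 2.0 * config.peak_width_ms**2
    p1 = config.p1_fraction * a_n1 * np.exp(-((t - config.p1_latency_ms) ** 2) / w2)
    n1 = -a_n1 * np.exp(-((t - config.n1_latency_ms) ** 2) / w2)
    return p1 + n1


def line_noise_phase(trial_index: int, trial_length_s: float) -> float:
    """Starting phase (rad) of the 50 Hz mains at the onset of a trial.

    Phase advances by 2*pi*50*T per trial; an integer number of mains cycles
    per trial (T = 1.000 s) locks the phase, T = pi/3 s scrambles it.
    """
    if trial_index < 0:
        raise ValueError("trial_index must be >= 0")
    cycles = LINE_FREQ_HZ * trial_index * trial_length_s
    return 2.0 * math.pi * (cycles - math.floor(cycles))


def line_noise(trial_index: int, n_samples: int, config: SimulationConfig) -> np.ndarray:
    """50 Hz sinusoid (mV) for one trial with the trial's mains phase."""
    phase0 = line_noise_phase(trial_index, config.trial_length_s)
    t = np.arange(n_samples) / config.sampling_rate_Hz
    return config.line_amp_mV * np.sin(2.0 * math.pi * LINE_FREQ_HZ * t + phase0)


def condition_schedule(
    config: SimulationConfig, rng: np.random.Generator
) -> list[StimCondition]:
    """Per-trial condition sequence: intermingled blocks of `block_size` trials.

    Each condition contributes ceil(n/block) blocks (the last possibly
    short) and the blocks are shuffled, mirroring the pseudo-randomly
    intermingled 25-trial blocks of the stimulation paradigm.
    """
    blocks: list[tuple[StimCondition, int]] = []
    for cond in config.conditions:
        remaining = config.n_trials_per_condition
        while remaining > 0:
            take = min(config.block_size, remaining)
            blocks.append((cond, take))
            remaining -= take
    order = rng.permutation(len(blocks))
    schedule: list[StimCondition] = []
    for k in order:
        cond, count = blocks[k]
        schedule.extend([cond] * count)
    return schedule


def _jitter_sigma(cv: float) -> float:
    """Lognormal sigma giving a unit-mean jitter with coefficient of variation cv."""
    return math.sqrt(math.log1p(cv**2))


def _trial_jitter(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = _jitter_sigma(cv)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _broadband_noise(
    rng: np.random.Generator, sd: float, n: int, color: str
) -> np.ndarray:
    if sd <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if color == "white":
        return sd * white
    # pink: shape the spectrum by 1/sqrt(f), renormalise to the requested SD
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n)
    pink *= sd / pink.std()
    return pink


def simulate_session(
    config: SimulationConfig,
    subject_id: str = "subj00",
    seed: int | None = None,
) -> SessionRecording:
    """Simulate one continuous two-channel session.

    Trials are laid back-to-back between `pad_s` of padding, so every event
    has at least `pad_s` of context on both sides in addition to the
    neighbouring trials (epoching with +/-900 ms margins works exactly as on
    a real continuous recording).  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sampling_rate_Hz
    n_trial = int(round(config.trial_length_s * fs))
    n_pad = int(round(config.pad_s * fs))
    schedule = condition_schedule(config, rng)
    n_trials = len(schedule)
    n_total = 2 * n_pad + n_trials * n_trial

    subject_effect = rng.normal(0.0, config.subject_sd) if config.subject_sd > 0 else 0.0
    jitter = _trial_jitter(rng, config.trial_jitter_cv, n_trials)

    events = n_pad + np.arange(n_trials, dtype=np.int64) * n_trial
    t_trial_ms = np.arange(n_trial) / fs * 1000.0

    signal = np.zeros(n_total)
    templates: dict[StimCondition, np.ndarray] = {}
    for i, (cond, ev) in enumerate(zip(schedule, events)):
        if cond not in templates:
            templates[cond] = evoked_template(t_trial_ms, cond, config)
        signal[ev : ev + n_trial] += (
            templates[cond] * (1.0 + subject_effect) * jitter[i]
        )

    if config.line_amp_mV > 0:
        # mains phase follows the nominal trial length exactly (the phase law
        # 2*pi*50*i*T is the design contract); trial boundaries fall on
        # integer samples, so per-trial synthesis keeps the law exact at the
        # cost of a sub-milliradian seam between consecutive trials
        line = np.empty(n_total)
        t_pad = (np.arange(n_pad) - n_pad) / fs
        line[:n_pad] = config.line_amp_mV * np.sin(2.0 * math.pi * LINE_FREQ_HZ * t_pad)
        for i in range(n_trials):
            start = n_pad + i * n_trial
            line[start : start + n_trial] = line_noise(i, n_trial, config)
        t_tail = np.arange(n_total - n_pad - n_trials * n_trial) / fs
        phase_end = line_noise_phase(n_trials, config.trial_length_s)
        line[n_pad + n_trials * n_trial :] = config.line_amp_mV * np.sin(
            2.0 * math.pi * LINE_FREQ_HZ * t_tail + phase_end
        )
        signal = signal + line

    shared = _broadband_noise(rng, config.noise_sd_mV, n_total, config.noise_color)
    ch_sd = config.channel_noise_frac * config.noise_sd_mV
    channels = np.empty((2, n_total))
    for c in range(2):
        per_channel = (
            rng.normal(0.0, ch_sd, n_total) if ch_sd > 0 else 0.0
        )
        channels[c] = signal + shared + per_channel

    channels *= config.gain_factor / 1000.0    # to recorded units

    return SessionRecording(
        subject_id=subject_id,
        channels=channels,
        sampling_rate_Hz=fs,
        gain_factor=config.gain_factor,
        events=events,
        conditions=schedule,
        trial_length_s=config.trial_length_s,
    )


def simulate_study(
    config: SimulationConfig, n_subjects: int, seed: int | None = None
) -> list[SessionRecording]:
    """Simulate one session per subject with independent per-subject streams."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(n_subjects)
    sessions = []
    for k, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        sessions.append(
            simulate_session(config, subject_id=f"s{k:02d}", seed=child_seed)
        )
    return sessions


def simulate_response_table(
    config: SimulationConfig,
    n_subjects: int,
    seed: int | None = None,
    intensity_weight: float = 1.0,
    duration_weight: float = 1.0,
) -> pd.DataFrame:
    """Condition-level response table for statistical calibration studies.

    Emulates what the full pipeline measures per (subject, condition) -- the
    N1 magnitude of a `n_trials_per_condition`-trial average -- without
    synthesising waveforms: amplitude = A(I, d) scaled by the subject effect
    and the mean of n lognormal jitters, plus averaged broadband noise.

    `intensity_weight` / `duration_weight` in [0, 1] interpolate the gain
    surface between flat (0: the generator's null for that factor) and the
    full saturating dependence (1).  Columns: subject_id, duration_ms,
    intensity_mW, amplitude_raw (mV), amplitude (within-subject
    max-normalised).
    """
    for name, w in (("intensity_weight", intensity_weight), ("duration_weight", duration_weight)):
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_trials_per_condition
    recs = []
    for k in range(n_subjects):
        u = rng.normal(0.0, config.subject_sd) if config.subject_sd > 0 else 0.0
        amps = []
        conds = config.conditions
        for cond in conds:
            sat_i = cond.intensity_mW / (cond.intensity_mW + config.I50_mW)
            sat_d = -math.expm1(-cond.duration_ms / config.tau_d_ms)
            gain_i = (1.0 - intensity_weight) + intensity_weight * sat_i
            gain_d = (1.0 - duration_weight) + duration_weight * sat_d
            a = config.A_max_mV * gain_i * gain_d
            mean_jitter = float(np.mean(_trial_jitter(rng, config.trial_jitter_cv, n)))
            noise = rng.normal(0.0, config.noise_sd_mV / math.sqrt(n))
            amps.append(max(a * (1.0 + u) * mean_jitter + noise, 0.0))
        amps_arr = np.asarray(amps)
        top = amps_arr.max()
        for cond, raw in zip(conds, amps_arr):
            recs.append(
                dict(
                    subject_id=f"s{k:02d}",
                    duration_ms=cond.duration_ms,
                    intensity_mW=cond.intensity_mW,
                    amplitude_raw=raw,
                    amplitude=raw / top if top > 0 else 0.0,
                )
            )
    return pd.DataFrame.from_records(recs)
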