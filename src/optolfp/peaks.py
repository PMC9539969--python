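"""Condition averaging and P1/N1 peak measurement.

Peak rules: average the trials of a condition; a peak is detected if its
extremum exceeds one standard deviation of the averaged trace over the
100 ms preceding stimulus onset, searching 1-9 ms for P1 (maximum) and
5-20 ms for N1 (minimum).  The N1 onset latency is the intersection with
baseline (zero, after baseline correction) of a first-order regression line
fitted to the flank samples lying between 45 and 55% of the N1 magnitude.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import (
    EvokedAverage,
    PeakMeasurement,
    PeakRow,
    SessionPeakTable,
    TrialEpoch,
    window_mask,
)

logger = logging.getLogger("optolfp")

P1_WINDOW_MS = (1.0, 9.0)
N1_WINDOW_MS = (5.0, 20.0)
BASELINE_SD_MS = (-100.0, 0.0)
ONSET_BAND = (0.45, 0.55)
ONSET_BAND_MAX = (0.30, 0.70)
ONSET_BAND_STEP = 0.05


def condition_average(
    epochs: list[TrialEpoch],
    baseline_sd_ms: tuple[float, float] = BASELINE_SD_MS,
) -> EvokedAverage:
    """Point-wise mean of one condition's epochs plus its baseline SD.

    All epochs must share the condition and the time axis.  The baseline SD
    (detection threshold) is computed on the averaged trace over the 100 ms
    before stimulus onset.
    """
    if not epochs:
        raise ValueError("need at least one epoch to average")
    cond = epochs[0].condition
    time_ms = epochs[0].time_ms
    for e in epochs[1:]:
        if e.condition != cond:
            raise ValueError(
                f"mixed conditions in average: {e.condition} vs {cond}"
            )
        if e.time_ms.shape != time_ms.shape or not np.allclose(e.time_ms, time_ms):
            raise ValueError("epochs have differing time axes")
    trace = np.mean([e.trace_mV for e in epochs], axis=0)
    mask = window_mask(time_ms, baseline_sd_ms[0], baseline_sd_ms[1], closed="left")
    if mask.sum() < 2:
        raise ValueError(
            f"average does not cover the baseline-SD span {baseline_sd_ms} ms"
        )
    baseline_sd = float(np.std(trace[mask], ddof=1))
    return EvokedAverage(
        condition=cond,
        time_ms=time_ms,
        trace_mV=trace,
        n_trials=len(epochs),
        baseline_sd_mV=baseline_sd,
    )


def _extremum(
    avg: EvokedAverage, window_ms: tuple[float, float], polarity: int
) -> tuple[float, float]:
    mask = window_mask(avg.time_ms, window_ms[0], window_ms[1], closed="both")
    if not mask.any():
        raise ValueError(f"average does not cover the search window {window_ms} ms")
    seg = avg.trace_mV[mask]
    t_seg = avg.time_ms[mask]
    idx = int(np.argmax(seg)) if polarity > 0 else int(np.argmin(seg))
    return float(seg[idx]), float(t_seg[idx])


def detect_peaks(
    avg: EvokedAverage,
    p1_window_ms: tuple[float, float] = P1_WINDOW_MS,
    n1_window_ms: tuple[float, float] = N1_WINDOW_MS,
    threshold_sd: float = 1.0,
) -> tuple[PeakMeasurement, PeakMeasurement]:
    """Detect P1 (max in 1-9 ms) and N1 (min in 5-20 ms) on an average.

    Detection requires the extremum to exceed `threshold_sd` baseline
    standard deviations (strictly).  A degenerate flat baseline (SD = 0)
    leaves the threshold at zero, so any non-zero extremum of the right sign
    counts; an all-zero trace yields two undetected peaks.
    """
    thr = threshold_sd * avg.baseline_sd_mV
    p1_val, p1_lat = _extremum(avg, p1_window_ms, +1)
    n1_val, n1_lat = _extremum(avg, n1_window_ms, -1)

    p1_detected = p1_val > thr
    n1_detected = n1_val < -thr
    p1 = PeakMeasurement(
        kind="P1",
        detected=p1_detected,
        amplitude_mV=p1_val if p1_detected else None,
        latency_ms=p1_lat if p1_detected else None,
        threshold_mV=thr,
    )
    n1 = PeakMeasurement(
        kind="N1",
        detected=n1_detected,
        amplitude_mV=n1_val if n1_detected else None,
        latency_ms=n1_lat if n1_detected else None,
        threshold_mV=thr,
    )
    return p1, n1


def interpolate_onset(
    avg: EvokedAverage,
    n1: PeakMeasurement,
    band: tuple[float, float] = ONSET_BAND,
    band_max: tuple[float, float] = ONSET_BAND_MAX,
    band_step: float = ONSET_BAND_STEP,
) -> float:
    """N1 onset latency (ms) by mid-maximum flank regression.

    Takes the samples between stimulus onset and the N1 latency whose value
    lies between 45 and 55% of the N1 amplitude, fits a first-order
    regression of value on time, and returns the time where that line
    crosses zero (the post-baseline-correction baseline).  If fewer than two
    samples fall in the band, the band widens symmetrically in 5% steps up
    to 30-70% before giving up.
    """
    if not n1.detected:
        raise ValueError("N1 onset requires a detected N1 peak")
    flank = window_mask(avg.time_ms, 0.0, n1.latency_ms, closed="both")
    t = avg.time_ms[flank]
    v = avg.trace_mV[flank]
    frac = v / n1.amplitude_mV    # positive where the trace goes negative

    lo, hi = band
    while True:
        sel = (frac >= lo) & (frac <= hi)
        if sel.sum() >= 2:
            break
        lo_next = max(lo - band_step, band_max[0])
        hi_next = min(hi + band_step, band_max[1])
        if (lo_next, hi_next) == (lo, hi):
            raise ValueError(
                f"fewer than 2 flank samples even in the widened "
                f"{band_max[0]:.0%}-{band_max[1]:.0%} band"
            )
        lo, hi = lo_next, hi_next
    if (lo, hi) != band:
        logger.info(
            "onset band widened to %.0f-%.0f%% for condition %s",
            lo * 100, hi * 100, avg.condition,
        )
    slope, intercept = np.polyfit(t[sel], v[sel], 1)
    if slope == 0:
        raise ValueError("flat flank: onset regression line never crosses baseline")
    return float(-intercept / slope)


def single_trial_n1(
    epoch: TrialEpoch, window_ms: tuple[float, float] = N1_WINDOW_MS
) -> float:
    """Signed minimum of a single-trial trace in the N1 window."""
    mask = window_mask(epoch.time_ms, window_ms[0], window_ms[1], closed="both")
    if not mask.any():
        raise ValueError(f"epoch does not cover the N1 window {window_ms} ms")
    return float(np.min(epoch.trace_mV[mask]))


def single_trial_n1_adaptive(
    epoch: TrialEpoch, center_latency_ms: float, half_width_ms: float = 3.0
) -> float:
    """Variant: minimum in a +/-3 ms window around the condition-average latency."""
    return single_trial_n1(
        epoch, (center_latency_ms - half_width_ms, center_latency_ms + half_width_ms)
    )


def session_peak_table(
    epochs: list[TrialEpoch],
    subject_id: str,
    p1_window_ms: tuple[float, float] = P1_WINDOW_MS,
    n1_window_ms: tuple[float, float] = N1_WINDOW_MS,
    threshold_sd: float = 1.0,
    baseline_sd_ms: tuple[float, float] = BASELINE_SD_MS,
    adaptive_trial_window: bool = False,
) -> SessionPeakTable:
    """Measure P1/N1 per condition for one session's epochs.

    Per-trial N1 amplitudes use the fixed 5-20 ms window by default; with
    `adaptive_trial_window` they use +/-3 ms around the condition-average N1
    latency instead.  Onset interpolation failures are logged, not fatal.
    """
    by_cond: dict = {}
    for e in epochs:
        by_cond.setdefault(e.condition, []).append(e)

    table = SessionPeakTable(subject_id=subject_id)
    for cond in sorted(by_cond):
        trials = by_cond[cond]
        avg = condition_average(trials, baseline_sd_ms=baseline_sd_ms)
        p1, n1 = detect_peaks(
            avg, p1_window_ms=p1_window_ms, n1_window_ms=n1_window_ms,
            threshold_sd=threshold_sd,
        )
        if n1.detected:
            try:
                onset = interpolate_onset(avg, n1)
            except ValueError as exc:
                logger.warning("onset interpolation failed for %s: %s", cond, exc)
            else:
                # a physical onset precedes the peak; regression on a noisy
                # flank can extrapolate anywhere, so nonsense is discarded
                if 0.0 <= onset < n1.latency_ms:
                    n1.onset_latency_ms = onset
                else:
                    logger.warning(
                        "implausible onset %.2f ms for %s (peak at %.2f ms); "
                        "discarded", onset, cond, n1.latency_ms,
                    )
        if adaptive_trial_window and n1.detected:
            trial_amps = np.array(
                [single_trial_n1_adaptive(e, n1.latency_ms) for e in trials]
            )
        else:
            trial_amps = np.array([single_trial_n1(e, n1_window_ms) for e in trials])
        table.rows.append(
            PeakRow(
                condition=cond, p1=p1, n1=n1,
                trial_n1_mV=trial_amps, n_trials=len(trials),
            )
        )
    return table
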