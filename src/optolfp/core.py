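"""Core data containers shared across the pipeline.

The pipeline analyses transcallosal evoked local field potentials (LFPs):
a brief optogenetic light pulse delivered to one motor cortex evokes, via
the corpus callosum, a field response in the contralateral cortex.  The
response is characterised by an early positive deflection (P1) and a more
prominent negative deflection (N1).  Every stage of the analysis passes
these containers around; they are deliberately thin (dataclasses wrapping
numpy arrays) so that each stage stays independently testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("optolfp")


@dataclass(frozen=True, order=True)
class StimCondition:
    """One cell of the duration x intensity stimulation grid.

    Identity is the (duration_ms, intensity_mW) pair; ordering sorts by
    duration first, then intensity, which is the layout used for grids.
    """

    duration_ms: float
    intensity_mW: float

    def __post_init__(self) -> None:
        if not (self.duration_ms > 0 and self.intensity_mW > 0):
            raise ValueError(
                f"stimulation duration and intensity must be positive, got "
                f"({self.duration_ms} ms, {self.intensity_mW} mW)"
            )


@dataclass
class SessionRecording:
    """Continuous two-channel recording of one animal session.

    channels are in *recorded* units (amplifier output); `gain_factor`
    states the amplifier gain (x100 or x1000) needed to bring them to the
    common analysis scale.  `events` are stimulus-onset sample indices and
    `conditions` labels each event with its grid cell.
    """

    subject_id: str
    channels: np.ndarray            # shape (2, n_samples)
    sampling_rate_Hz: float
    gain_factor: int
    events: np.ndarray              # int sample indices, strictly increasing
    conditions: list[StimCondition]
    trial_length_s: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 2:
            raise ValueError(
                f"channels must have shape (2, n_samples), got {self.channels.shape}"
            )
        self.events = np.asarray(self.events, dtype=np.int64)
        if self.events.size and np.any(np.diff(self.events) <= 0):
            raise ValueError("events must be strictly increasing")
        if len(self.conditions) != self.events.size:
            raise ValueError(
                f"every event needs a condition label: {self.events.size} events, "
                f"{len(self.conditions)} labels"
            )
        if int(self.gain_factor) not in (100, 1000):
            raise ValueError(f"gain_factor must be 100 or 1000, got {self.gain_factor}")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_Hz


@dataclass
class TrialEpoch:
    """A single trial, time-locked to stimulus onset (t = 0 ms).

    `trace_mV` is the channel-averaged, filtered, gain-compensated and
    baseline-corrected trace on the `time_ms` axis.
    """

    condition: StimCondition
    time_ms: np.ndarray
    trace_mV: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.trace_mV = np.asarray(self.trace_mV, dtype=float)
        if self.time_ms.shape != self.trace_mV.shape:
            raise ValueError("time_ms and trace_mV must have identical shapes")


@dataclass
class EvokedAverage:
    """Condition average of trial epochs plus its pre-stimulus noise level.

    `baseline_sd_mV` is the standard deviation of the *averaged* trace over
    the 100 ms preceding stimulus onset; it sets the detection threshold.
    """

    condition: StimCondition
    time_ms: np.ndarray
    trace_mV: np.ndarray
    n_trials: int
    baseline_sd_mV: float

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("an evoked average needs at least one trial")
        if self.baseline_sd_mV < 0:
            raise ValueError("baseline SD cannot be negative")


@dataclass
class PeakMeasurement:
    """Detected (or not) P1/N1 peak of one condition average.

    Amplitude is signed (P1 > 0, N1 < 0).  `onset_latency_ms` is the
    mid-maximum flank interpolation and is computed for N1 only.
    `threshold_mV` records the detection threshold in force, so QC reports
    can state every detection's margin.
    """

    kind: str                           # "P1" or "N1"
    detected: bool
    amplitude_mV: float | None = None
    latency_ms: float | None = None
    onset_latency_ms: float | None = None
    threshold_mV: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("P1", "N1"):
            raise ValueError(f"kind must be 'P1' or 'N1', got {self.kind!r}")
        if self.detected and (self.amplitude_mV is None or self.latency_ms is None):
            raise ValueError("a detected peak must carry amplitude and latency")


@dataclass
class PeakRow:
    """Per-condition peak measurements of one session."""

    condition: StimCondition
    p1: PeakMeasurement
    n1: PeakMeasurement
    trial_n1_mV: np.ndarray       # signed single-trial N1 minima
    n_trials: int


@dataclass
class SessionPeakTable:
    """All per-condition peak measurements of one session."""

    subject_id: str
    rows: list[PeakRow] = field(default_factory=list)

    def conditions(self) -> list[StimCondition]:
        return [r.condition for r in self.rows]

    def row_for(self, condition: StimCondition) -> PeakRow | None:
        for r in self.rows:
            if r.condition == condition:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        """Long-format summary, one row per condition."""
        recs = []
        for r in self.rows:
            recs.append(
                dict(
                    subject_id=self.subject_id,
                    duration_ms=r.condition.duration_ms,
                    intensity_mW=r.condition.intensity_mW,
                    n_trials=r.n_trials,
                    p1_detected=r.p1.detected,
                    p1_amplitude_mV=r.p1.amplitude_mV,
                    p1_latency_ms=r.p1.latency_ms,
                    n1_detected=r.n1.detected,
                    n1_amplitude_mV=r.n1.amplitude_mV,
                    n1_latency_ms=r.n1.latency_ms,
                    n1_onset_ms=r.n1.onset_latency_ms,
                    threshold_mV=r.n1.threshold_mV,
                )
            )
        return pd.DataFrame.from_records(recs)


@dataclass
class ConditionGrid:
    """A duration x intensity grid of one per-condition statistic.

    `values[i, j]` corresponds to durations[i] x intensities[j] (the layout
    of the published grids: durations as rows, intensities as columns).
    `counts` carries a supporting integer per cell (e.g. number of sessions
    contributing) and `included` an optional inclusion mask.
    """

    name: str
    durations_ms: np.ndarray
    intensities_mW: np.ndarray
    values: np.ndarray
    counts: np.ndarray | None = None
    included: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.durations_ms = np.asarray(self.durations_ms, dtype=float)
        self.intensities_mW = np.asarray(self.intensities_mW, dtype=float)
        expected = (self.durations_ms.size, self.intensities_mW.size)
        if self.values.shape != expected:
            raise ValueError(f"grid shape {self.values.shape} != axes shape {expected}")

    @property
    def n_cells(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: durations as rows, intensities as columns."""
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.durations_ms, name="duration_ms"),
            columns=pd.Index(self.intensities_mW, name="intensity_mW"),
        )


def window_mask(
    time_ms: np.ndarray, lo: float, hi: float, closed: str = "both"
) -> np.ndarray:
    """Boolean mask selecting samples with lo..hi ms.

    closed="left" gives [lo, hi) (used for the baseline windows), "both"
    gives [lo, hi] (used for the peak-search windows).
    """
    t = np.asarray(time_ms)
    if closed == "left":
        return (t >= lo) & (t < hi)
    if closed == "both":
        return (t >= lo) & (t <= hi)
    raise ValueError(f"closed must be 'left' or 'both', got {closed!r}")


def grid_axes(
    tables: Sequence[SessionPeakTable],
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique durations and intensities present across sessions."""
    durs = sorted({r.condition.duration_ms for t in tables for r in t.rows})
    ints = sorted({r.condition.intensity_mW for t in tables for r in t.rows})
    if not durs or not ints:
        raise ValueError("no conditions present in the supplied peak tables")
    return np.asarray(durs), np.asarray(ints)
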