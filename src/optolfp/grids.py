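"""Dose-response summaries over the duration x intensity grid.

Builds the group-level descriptions of the stimulation-response mapping:
detectability grids (how many sessions show a peak per condition), CoV
robustness grids (coefficient of variation of single-trial N1 amplitudes,
threshold 1.0), median amplitude grids restricted to robust sessions with a
>=20%-of-sessions inclusion rule, normalized input/output curves, and the
fiber-tip irradiance helper.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .core import ConditionGrid, SessionPeakTable, StimCondition, grid_axes

logger = logging.getLogger("optolfp")

COV_THRESHOLD = 1.0
MIN_SESSION_FRACTION = 0.2
#: absolute slack protecting the >=20% inclusion rule from float round-off
_FRACTION_EPS = 1e-9


def condition_cov(per_trial_amplitudes: np.ndarray) -> float:
    """Coefficient of variation (sample SD / mean) of amplitude magnitudes.

    Signed N1 values are negative, so the CoV is computed on magnitudes,
    keeping it in [0, inf).  A zero mean magnitude yields +inf (treated as
    non-robust downstream).  Scale-invariant by construction.
    """
    amps = np.abs(np.asarray(per_trial_amplitudes, dtype=float))
    if amps.size < 2:
        raise ValueError("CoV needs at least 2 trials")
    mean = amps.mean()
    if mean == 0.0:
        return math.inf
    return float(np.std(amps, ddof=1) / mean)


def count_robust(covs: np.ndarray, threshold: float = COV_THRESHOLD) -> int:
    """Number of sessions with CoV strictly below the robustness threshold."""
    covs = np.asarray(covs, dtype=float)
    return int(np.sum(covs < threshold))


def _cell_iter(durations: np.ndarray, intensities: np.ndarray):
    for i, d in enumerate(durations):
        for j, inten in enumerate(intensities):
            yield i, j, StimCondition(float(d), float(inten))


def detectability_grid(
    tables: list[SessionPeakTable], kind: str = "N1"
) -> ConditionGrid:
    """Fraction (and count) of sessions with a detected peak per condition."""
    if kind not in ("P1", "N1"):
        raise ValueError("kind must be 'P1' or 'N1'")
    durations, intensities = grid_axes(tables)
    frac = np.full((durations.size, intensities.size), np.nan)
    counts = np.zeros_like(frac, dtype=int)
    n_sessions = len(tables)
    for i, j, cond in _cell_iter(durations, intensities):
        detected = 0
        present = 0
        for t in tables:
            row = t.row_for(cond)
            if row is None:
                continue
            present += 1
            peak = row.p1 if kind == "P1" else row.n1
            if peak.detected:
                detected += 1
        counts[i, j] = detected
        if present:
            frac[i, j] = detected / present
    return ConditionGrid(
        name=f"{kind}_detectability",
        durations_ms=durations,
        intensities_mW=intensities,
        values=frac,
        counts=counts,
    )


def session_covs(
    tables: list[SessionPeakTable], cond: StimCondition
) -> np.ndarray:
    """CoV per session with a detected N1 for one condition."""
    covs = []
    for t in tables:
        row = t.row_for(cond)
        if row is None or not row.n1.detected:
            continue
        covs.append(condition_cov(row.trial_n1_mV))
    return np.asarray(covs)


def robustness_grids(
    tables: list[SessionPeakTable], cov_threshold: float = COV_THRESHOLD
) -> tuple[ConditionGrid, ConditionGrid]:
    """Median CoV grid and robust-session count grid (CoV < threshold).

    Only sessions with a detected N1 contribute; empty cells are NaN with
    count zero.
    """
    if not tables:
        raise ValueError("need at least one session peak table")
    durations, intensities = grid_axes(tables)
    shape = (durations.size, intensities.size)
    median_cov = np.full(shape, np.nan)
    detect_count = np.zeros(shape, dtype=int)
    robust_count = np.zeros(shape, dtype=int)
    for i, j, cond in _cell_iter(durations, intensities):
        covs = session_covs(tables, cond)
        detect_count[i, j] = covs.size
        if covs.size:
            finite = covs[np.isfinite(covs)]
            median_cov[i, j] = np.median(finite) if finite.size else np.inf
            robust_count[i, j] = count_robust(covs, cov_threshold)
    grid_cov = ConditionGrid(
        name="median_cov",
        durations_ms=durations, intensities_mW=intensities,
        values=median_cov, counts=detect_count,
    )
    grid_robust = ConditionGrid(
        name="robust_count",
        durations_ms=durations, intensities_mW=intensities,
        values=robust_count.astype(float), counts=robust_count,
    )
    return grid_cov, grid_robust


def median_amplitude_grid(
    tables: list[SessionPeakTable],
    cov_threshold: float = COV_THRESHOLD,
    min_session_fraction: float = MIN_SESSION_FRACTION,
) -> ConditionGrid:
    """Median N1 magnitude across robust sessions, with inclusion mask.

    A cell is included only when robust sessions (CoV < threshold) make up
    at least `min_session_fraction` of all sessions (with 15 sessions the
    published rule: N >= 3).  Excluded cells keep their median as NaN.
    """
    if not tables:
        raise ValueError("need at least one session peak table")
    n_sessions = len(tables)
    durations, intensities = grid_axes(tables)
    shape = (durations.size, intensities.size)
    median_amp = np.full(shape, np.nan)
    robust_count = np.zeros(shape, dtype=int)
    included = np.zeros(shape, dtype=bool)
    for i, j, cond in _cell_iter(durations, intensities):
        mags = []
        for t in tables:
            row = t.row_for(cond)
            if row is None or not row.n1.detected:
                continue
            if condition_cov(row.trial_n1_mV) < cov_threshold:
                mags.append(abs(row.n1.amplitude_mV))
        robust_count[i, j] = len(mags)
        included[i, j] = (
            len(mags) + _FRACTION_EPS >= min_session_fraction * n_sessions
            and len(mags) > 0
        )
        if included[i, j]:
            median_amp[i, j] = float(np.median(mags))
    return ConditionGrid(
        name="median_n1_amplitude",
        durations_ms=durations, intensities_mW=intensities,
        values=median_amp, counts=robust_count, included=included,
    )


def normalize_sessions(tables: list[SessionPeakTable]) -> pd.DataFrame:
    """Within-session max-normalised N1 magnitudes, long format.

    Each session's detected |N1| values are divided by that session's
    maximum across all conditions, so each session's largest condition maps
    to exactly 1.  Sessions without any detected N1 are skipped with a
    warning.
    """
    recs = []
    for t in tables:
        detected = [
            (r.condition, abs(r.n1.amplitude_mV)) for r in t.rows if r.n1.detected
        ]
        if not detected:
            logger.warning("session %s has no detected N1; skipped", t.subject_id)
            continue
        top = max(a for _, a in detected)
        for cond, amp in detected:
            recs.append(
                dict(
                    subject_id=t.subject_id,
                    duration_ms=cond.duration_ms,
                    intensity_mW=cond.intensity_mW,
                    amplitude=amp / top,
                )
            )
    if not recs:
        raise ValueError("no session has a detected N1")
    return pd.DataFrame.from_records(recs)


def io_curves(
    tables: list[SessionPeakTable],
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized input/output curves: group median +/- bootstrap SE.

    Per condition: the group median of within-session max-normalised N1
    magnitudes, its standard error from a session-level bootstrap
    (`n_boot` resamples, seeded), and the number of contributing sessions.
    """
    norm = normalize_sessions(tables)
    subjects = norm["subject_id"].unique()
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, subjects.size, size=(n_boot, subjects.size))

    by_subject = {
        s: g.set_index(["duration_ms", "intensity_mW"])["amplitude"]
        for s, g in norm.groupby("subject_id")
    }
    conds = sorted(
        {(d, i) for d, i in zip(norm["duration_ms"], norm["intensity_mW"])}
    )
    recs = []
    for d, inten in conds:
        vals = np.array(
            [
                by_subject[s].get((d, inten))
                for s in subjects
                if (d, inten) in by_subject[s].index
            ],
            dtype=float,
        )
        boot_medians = np.full(n_boot, np.nan)
        for b in range(n_boot):
            sample = [
                by_subject[subjects[k]].get((d, inten))
                for k in boot_idx[b]
                if (d, inten) in by_subject[subjects[k]].index
            ]
            if sample:
                boot_medians[b] = np.median(sample)
        ok = np.isfinite(boot_medians)
        se = float(np.std(boot_medians[ok], ddof=1)) if ok.sum() > 1 else np.nan
        recs.append(
            dict(
                duration_ms=d,
                intensity_mW=inten,
                median=float(np.median(vals)),
                se_median=se,
                n_sessions=int(vals.size),
            )
        )
    return pd.DataFrame.from_records(recs)


def irradiance(power_mW: float, core_diameter_um: float = 55.0) -> float:
    """Irradiance (mW/mm^2) at the tip of a multimode fiber core.

    Optical power divided by the circular core cross-section; for the 55 um
    core used here, 0.25-10 mW spans roughly 105-4,209 mW/mm^2.
    """
    if power_mW <= 0 or core_diameter_um <= 0:
        raise ValueError("power and core diameter must be positive")
    radius_mm = core_diameter_um / 2.0 / 1000.0
    return power_mW / (math.pi * radius_mm**2)
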