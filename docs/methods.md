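# Methods

This note documents the models, parameter choices and numerical decisions
behind `optolfp`, and what the synthetic-data studies do and do not show.

## Analysis chain

The pipeline reproduces a standard evoked-LFP dose-response analysis for a
duration × intensity stimulation design (defaults: 7 durations 0.1–10 ms ×
6 intensities 0.25–10 mW, 150 trials per condition, 30 kHz sampling,
π/3 ≈ 1.0472 s trials).

**Gain compensation.** Recordings are acquired at amplifier gain ×1000 or
×100; ×100 traces are multiplied by 10 so all sessions share one scale.
Any other gain value is a hard error — silent mis-scaling would corrupt
every downstream amplitude. No conversion to physical volts at the
electrode is attempted; "mV" throughout means compensated recorded units.

**Filtering.** A 50 Hz IIR notch (quality factor 30, ≈1.7 Hz width —
narrow enough to spare the 3–300 Hz band) followed by a 2nd-order
Butterworth band-pass, 3–300 Hz. Both are applied forward–backward
(zero-phase) on the *continuous* traces so that (a) detected latencies are
not biased by group delay and (b) filter edge transients never touch the
analysis windows. Causality was an open choice; the causal variant is
available via `zero_phase=False`. Notch-then-band-pass order follows the
processing description; for LTI filters the order is immaterial.

**Epoching and baseline.** ±900 ms around each stimulus onset; events
lacking the full margin are dropped, counted and logged. The two
stereotrode channels are averaged per trial, then each trial is baseline
corrected by the mean of its samples in [−10, 0) ms. The whole chain is
linear in the input trace.

**Peak rules.** Trials are averaged per condition. P1 is the maximum in
1–9 ms, N1 the minimum in 5–20 ms; a peak is detected when its extremum
strictly exceeds 1 standard deviation of the averaged trace over
[−100, 0) ms. With a degenerate flat baseline (SD = 0) the threshold is
zero, so any non-zero extremum of the right sign counts. N1 onset latency
is the zero crossing (the post-baseline-correction baseline) of a
first-order regression line fitted to the flank samples between stimulus
onset and the N1 latency whose value lies in 45–55 % of the N1 magnitude;
if fewer than two samples fall in the band it widens symmetrically in 5 %
steps to at most 30–70 %, then errors. "Peak maximum" is read as the N1
extremum magnitude — the mid-maximum rule applied to a negative peak. A
computed onset must precede the peak and be non-negative; a regression
line through a noisy flank can extrapolate anywhere, so implausible onsets
are discarded with a warning rather than reported. Latency resolution is
one sample (33 µs at 30 kHz); sub-sample peak localisation is pointless at
the effect scales of interest. Automatic detections are summarised in a
machine-readable QC report (per-detection threshold margins, drop and
redraw counts) instead of a manual verification step.

**Grids.** The CoV of a condition is the sample (n−1) standard deviation
over the mean of single-trial N1 *magnitudes* (signed values are negative,
which would flip the sign of SD/mean; magnitudes keep CoV in [0, ∞), with
+∞ for a zero mean). Per-trial N1 uses the same fixed 5–20 ms window as
the average; a ±3 ms window around the condition-average latency is
available via `adaptive_trial_window`. A session is robust in a cell when
CoV < 1.0 (strict). The median amplitude grid includes a cell only when
robust sessions reach ≥ 20 % of all sessions; the comparison adds an
absolute 1e-9 slack because 0.2 × 15 exceeds 3 by one float ulp, which
would otherwise exclude the intended N ≥ 3-of-15 boundary case. Session
medians use the midpoint convention for even counts. The input/output
curves normalise each session's detected N1 magnitudes by that session's
maximum; the standard error of the group median — not a standard textbook
quantity — is estimated by a session-level bootstrap (2,000 resamples,
seeded).

**Inference.** Normalised N1 amplitude ~ intensity + duration +
intensity:duration with a random intercept per subject. Predictors are
continuous and standardized; continuous coding matches a single
z-statistic per effect, which the permutation machinery requires
(categorical coding would need an omnibus statistic and is deliberately
not offered through this interface). Because normalised amplitudes are
bounded and non-normal, significance comes from within-subject
permutation: for a main effect the tested factor's labels are shuffled
among each subject's rows within each level of the other factor (the most
conservative stratification; the unstratified variant is available and
flagged in the result metadata); for the interaction the
(duration, intensity) pair is shuffled jointly within subject. Labels
never cross subjects. Extremeness is counted two-sided on |z| and the
add-one convention p = (count + 1)/(n_perm + 1) guarantees p > 0 — with
10,000 permutations the floor is 1/10,001, which prints as 0.0001 at four
decimals. The observed z is also reported normalised by the permutation
distribution's mean and SD. Significance is declared at p < α = 0.05
(0.025 per tail via the |z| counting). Permutations whose refit fails are
logged and redrawn.

**Mixed-model engines.** `fit_model` offers two REML engines for the same
model: statsmodels `MixedLM` (using the Powell optimiser — the gradient
optimisers stall or go singular on these small boundary-prone problems)
and an internal profiled-REML solver specialised to the single
random-intercept structure, where each group's covariance
σ²(I + λJ) inverts in closed form and the REML criterion reduces to a 1-D
search over λ. The fast solver is what the permutation loop uses
(~3 ms per fit, ~50× faster than MixedLM here); the two engines agree on z
to about five significant digits and the test suite asserts their
agreement, keeping an independent cross-check on the hand-written solver.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes; no
raw recordings are publicly deposited for this design, so it is the test
bed for every stage.

* **Evoked template**: a positive Gaussian bump (P1, latency 4 ms,
  amplitude 0.4 of N1) plus a negative Gaussian trough (N1, latency 10 ms,
  σ = 1.5 ms), both inside the detection windows by construction. The N1
  magnitude follows A(I, d) = A_max · I/(I + I50) · (1 − e^(−d/τ_d)) with
  A_max = 0.5 mV, I50 = 10 mW, τ_d = 2 ms: Michaelis–Menten in intensity
  with I50 at the top of the tested range (no intensity plateau over
  0.25–10 mW) and exponential saturation in duration (plateau by 5–10 ms),
  the qualitative pattern the analysis is meant to resolve. The waveform
  family and gain form are modelling choices, not measured facts.
* **Line noise**: 50 Hz sinusoid whose starting phase at trial i is
  2π·50·i·T mod 2π — identically zero for T = 1.000 s and advancing
  ≈ 2.2612 rad per trial for T = π/3 s (the trial-length trick that
  decorrelates mains noise from the stimulus). Within a session the noise
  is synthesised per trial so this law is exact; trial boundaries fall on
  integer samples, leaving a sub-milliradian seam per trial.
* **Noise and variability**: white Gaussian broadband noise
  (SD 0.05 mV; 1/f "pink" available via `noise_color`, not default — the
  band-pass dominates the spectral shape downstream), an additional small
  independent per-channel component (20 % of the shared SD) so channel
  averaging has something to average away, multiplicative lognormal
  trial-amplitude jitter with unit mean and CoV `trial_jitter_cv`
  (default 0.5 — strong conditions end well below the CoV-1.0 robustness
  threshold, weak ones above it), and a multiplicative Gaussian
  between-subject effect (SD 0.2).
* **Units and gain**: all components are synthesised on the common
  (×1000-referenced) mV scale and the recorded trace is that signal scaled
  by gain/1000, so gain compensation recovers the template in mV exactly
  for either hardware gain — the noise parameters keep their meaning
  regardless of gain.
* **Session layout**: trials are laid back-to-back (blocks of 25 per
  condition, blocks shuffled, mirroring the intermingled-block paradigm)
  between 1 s noise-only padding. Epochs span ±900 ms while trials last
  ≈1.047 s, so neighbouring trials overlap each epoch's outer flanks — as
  in a real continuous recording; the evoked template itself must fit
  inside one trial and the generator validates this.
* **Reduced generator for calibration**: `simulate_response_table` draws
  per-(subject, condition) N1 amplitudes directly from the same model
  (gain surface × subject effect × mean of n jitters + averaged noise),
  skipping waveform synthesis. The statistical calibration studies use it
  because they need thousands of model fits, not thousands of filtered
  traces. Effect-size weights in [0, 1] interpolate each factor's gain
  between flat (the null for that factor) and the full surface.

Not emulated: anesthesia-depth drift, seizure-like events, photoelectric
artifacts, laminar polarity reversal, non-stationary line-noise amplitude.
Passing tests therefore certify the *analysis* under the assumed
statistical structure, not robustness to every artifact of real
recordings. A per-trial artifact-rejection hook exists in the design but
ships disabled: the source protocol discarded a handful of trials "for
technical reasons" without stating a rule, so there is no criterion to
implement.

## Frozen numerical bounds and study sizes

* **Filter distortion bound (5 %).** The zero-phase chain attenuates a
  noise-free Gaussian N1 (σ = 1.5 ms) by ≈ 4.7 %: ≈ 1.7 % from the notch
  (the trough's spectrum peaks near 50 Hz) and ≈ 3 % low-frequency loss at
  the 3 Hz high-pass edge. This was measured directly by filtering the
  analytic template and is frozen as `FILTER_DISTORTION_BOUND = 0.05`; the
  noise-free recovery tests assert amplitude agreement within this bound
  (latency agreement is within one sample, since zero-phase filtering
  preserves the extremum location).
* **Calibration studies** (reduced standard conditions, stated here as the
  package's own choices): type-I error — 3 × 3 grid, 8 subjects, 12 trials
  per condition, 200 null draws × 500 permutations, α = 0.05 checked
  against the 95 % binomial interval; power — the same design at
  intensity-effect weights 0.1 / 0.3 / 1.0, 60 draws × 300 permutations,
  asserted non-decreasing with full-effect power ≥ 0.9. The permutation
  test is exact under within-stratum exchangeability, which the null
  generator satisfies by construction, so the type-I check is a
  calibration of the whole machinery (normalisation included), not of the
  theory alone.
* **End-to-end recovery** — 12 sessions, 5 × 4 grid, 16 trials per
  condition at 2 kHz; the included-cell median amplitude grid must rank-
  correlate with the true A(I, d) surface at Spearman ρ ≥ 0.9 and the
  group-median I/O curves must be non-decreasing in intensity at fixed
  duration (tolerance 0.02 on the normalised scale for median noise).

## Known limitations

* The onset interpolation needs ≥ 2 flank samples between 45–55 % (up to
  30–70 %) of the N1 magnitude; at low sampling rates or on shallow noisy
  flanks it fails or widens, and failures are reported rather than
  imputed.
* The fast REML solver covers exactly one random intercept per subject —
  the model used here; anything richer (random slopes, crossed effects)
  must go through statsmodels.
* CoV is undefined for a zero mean magnitude and reported as +∞
  (non-robust), which is the intended reading but means the median-CoV
  grid can be +∞ in empty-signal cells.
* File formats are the package's own (flat binary/HDF5 + JSON sidecar,
  schema version 1); native acquisition-system formats would need an
  adapter at the `SessionRecording` boundary.
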