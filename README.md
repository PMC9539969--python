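# optolfp

Dose-response analysis of optogenetically evoked transcallosal local field
potentials (LFPs).

## The problem

Optogenetic stimulation of excitatory neurons in one primary motor cortex
(M1) evokes, via the corpus callosum, a field response in the contralateral
M1: typically a small positive deflection (P1) followed by a prominent
negative deflection (N1). How reliably that response appears — and how
large it is — depends on the stimulation "dose": light-pulse duration and
optical intensity. This package implements a complete, tested pipeline for
characterising that dose-response relationship from continuous two-channel
intracortical recordings with stimulus-onset events, covering:

* **Signal preparation** — amplifier-gain compensation (×10 for ×100
  recordings), 50 Hz notch plus 2nd-order Butterworth 3–300 Hz band-pass
  (zero-phase), ±900 ms epoching, stereotrode channel averaging, baseline
  correction by the mean of the 10 ms before stimulus onset.
* **Peak measurement** — per-condition trial averaging; P1 = maximum in
  1–9 ms and N1 = minimum in 5–20 ms, detected when the extremum exceeds
  1 SD of the 100 ms pre-stimulus baseline of the average; N1 onset latency
  by intersecting a regression line through the 45–55 % mid-maximum flank
  samples with baseline.
* **Dose-response summaries** — detectability grids over the
  duration × intensity design; robustness grids from the coefficient of
  variation (CoV = SD/mean of single-trial N1 magnitudes, threshold 1.0,
  strict); median amplitude grids restricted to cells robust in ≥ 20 % of
  sessions; within-session max-normalised input/output curves with
  session-bootstrap standard errors of the median; a fiber-tip irradiance
  helper (power / core cross-section).
* **Inference** — a linear mixed-effects model, normalised N1 amplitude ~
  intensity + duration + intensity:duration (continuous, standardized) with
  a random intercept per subject, tested by **within-subject permutation**:
  labels are shuffled only among each subject's rows (stratified by the
  other factor for a main effect, the condition pair jointly for the
  interaction), the model is refitted per permutation, and the two-sided
  add-one p-value is p = (#{|z*| ≥ |z|} + 1)/(n_perm + 1), so the smallest
  attainable p with 10,000 permutations is 1/10,001 ≈ 0.0001.
* **Synthetic sessions** — no public recordings exist for this design, so a
  first-class generator produces multi-subject sessions with the assumed
  structure: a biphasic template whose N1 magnitude follows
  A(I, d) = A_max · I/(I + I50) · (1 − e^(−d/τ_d)), 50 Hz line noise whose
  phase advances by 2π·50·T per trial (locked for T = 1 s, scrambled for
  T = π/3 s), broadband noise, lognormal trial-amplitude jitter and
  Gaussian between-subject effects.

## Worked example

`examples/` contains one short script per capability. Permutation
inference on a simulated 10-subject study
(`python examples/04_permutation_stats.py`):

```text
intensity    z=  25.29  normalized z= 20.75  p=0.0005  (significant at alpha=0.05)
duration     z=  11.30  normalized z=  9.68  p=0.0005  (significant at alpha=0.05)
interaction  z=   8.12  normalized z=  7.64  p=0.0005  (significant at alpha=0.05)
```

`z` is the Wald statistic of each fixed effect in the unpermuted fit;
`normalized z` rescales it by the mean and SD of the 2,000-permutation null
distribution; `p` sits at its floor 1/2001 because no permuted statistic
reached the observed one — with this generator both stimulation factors
genuinely drive the N1 amplitude. Peak tables and condition grids are shown
in `examples/02_peak_detection.py` and `examples/03_dose_response_grids.py`;
the grid example also prints the irradiance span of a 55 µm fiber core
(0.25 mW → 105 mW/mm², 10 mW → 4209 mW/mm²).

The same stages are available from the shell:

```sh
optolfp simulate --out raw/ --n-subjects 3
optolfp preprocess --sessions raw/ --out epochs/
optolfp peaks --epochs epochs/ --out peaks/
optolfp grids --peaks-dir peaks/ --out grids/
optolfp stats --peaks-dir peaks/ --out stats.json
# or everything at once: optolfp all --out results/
```

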