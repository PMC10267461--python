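# Methods

## Overview

`coldwave` analyses how the morphology of the photoplethysmogram (PPG)
changes under a cold pressor test (CPT): a hand immersed in ice water
triggers a sympathetic response — blood pressure rises, peripheral vessels
constrict — and the pulse wave recorded optically at different body sites
reshapes in site-specific ways. The package implements the full chain from
raw signals to effect sizes:

1. **Signal formation.** Contact PPG arrives as 2000 Hz waveforms. Imaging
   PPG (iPPG) arrives as video frames: each frame is spatially smoothed with
   a 10-pixel box filter, all pixels inside a region-of-interest polygon
   (forehead, cheeks, or their union — the "super" ROI) are averaged, the
   trace is inverted to match contact-PPG polarity, and linearly
   interpolated to 2000 Hz.
2. **Analysis windows.** Three 10 s windows around the immersion time
   `t_CPT`: baseline `BL` at `t_CPT − 30 s`, stimulation windows `ST1` at
   `+20 s` and `ST2` at `+40 s`.
3. **Beat templates.** Signals are bandpassed (fifth-order Butterworth,
   0.4–8 Hz, applied forward-backward so the phase — and with it the beat
   morphology — is untouched). Beats are detected at the steepest ascent;
   each detection spawns a segment over `[t_i − 0.45·BBI~, t_i + BBI~]`,
   where `BBI~` is the window's median beat-to-beat interval. Segments whose
   mean pairwise Pearson correlation with the others falls below 0.3 are
   discarded; the survivors are ensemble-averaged and linearly detrended
   into one template per (subject, site, window).
4. **Pulse wave decomposition.** Each template is fitted with a two-kernel
   model — a scaled Gamma density for the systolic wave plus a Gaussian for
   the diastolic wave:

   ```
   y(t) = s1 · β1^α1/Γ(α1) · t^(α1−1) e^(−β1 t)
        + a2 · exp(−(t − μ2)² / (2 σ2²))
   ```

   subject to the constraints that the Gamma kernel peaks first
   (`μ1 = (α1−1)/β1 < μ2`) and higher (`a1 > a2`, `a1` being the Gamma
   kernel's peak value). The fitted model re-evaluated on the template grid
   is the denoised beat.
5. **Features.** From the denoised beat: amplitude (maximum above the beat
   minimum), slope (maximum of the first derivative), area (trapezoidal
   integral above the minimum) and PWHA (pulse width at half amplitude,
   from the last half-amplitude crossing before the global maximum to the
   first one after it).
6. **Statistics.** Per site and feature, a one-way repeated-measures ANOVA
   across the three windows gates (α = 0.05) paired t-tests for the three
   contrasts, Holm–Bonferroni-adjusted within each triple (k = 3). Hedges'
   g with a 95% CI is reported for every contrast regardless of
   significance. Reference parameters (SBP, DBP, HR, and pulse pressure
   computed beat-wise as SBP − DBP) are reduced to per-window medians over
   beats and run through the same chain.

## Parameters that matter

| Parameter | Default | Units | Why |
|---|---|---|---|
| bandpass corners | 0.4 / 8 | Hz | removes baseline wander and high-frequency noise while keeping ~10 pulse harmonics at rest |
| filter order | 5 | — | standard steepness/ringing compromise for pulse morphology |
| segment window | −0.45·BBI~ … +BBI~ | s | covers the full beat plus pre-upstroke context |
| correlation threshold | 0.3 | — | discards segments that do not share the window's dominant beat shape |
| detector threshold | 0.5 × rolling derivative max | — | scale-free; detection is invariant to amplitude |
| refractory period | 0.3 × autocorrelation period | s | suppresses double-firing on the diastolic wave |
| fit constraints margin | 10⁻³ × (amplitude, duration) | — | keeps the inequality constraints strictly feasible |
| fit grid | ≤ 400 points | — | the model is smooth at the beat time scale; decimation changes nothing but cost |
| g confidence level | 0.95 | — | normal approximation `var(g) ≈ (nx+ny)/(nx·ny) + g²/(2df)`; a noncentral-t inversion is available via `ci_method="noncentral-t"` |

## The synthetic study generator

The recordings behind the method are not deposited, so `synthgen` emulates
a multi-site CPT study with known ground truth. Its defaults are the
emulated study conditions and are not meant to be tuned per run:

- 35 analyzable subjects; sites finger, earlobe (contact, 2000 Hz),
  forehead and super (video-rate, 25 Hz); `t_CPT = 40 s` in a 95 s record;
  mean BBI 0.85 s with 0.04 s beat-to-beat jitter and a ±0.07 s
  between-subject spread.
- Beats are drawn from the same two-kernel model the decomposition fits, so
  ground-truth features are recomputable from the generating parameters.
  Site-typical resting shapes sit in `BASE_PARAMS`; subjects get a shared
  lognormal "perfusion" factor (sd 0.30) on both kernel scales and small
  (sd 0.05) lognormal jitter on timing parameters.
- Stimulus effects are multiplicative shifts on kernel parameters, not on
  features — this keeps truth self-consistent with the model. Defaults:
  finger `s1, a2 × 0.5`, `β1 × 0.85`, `σ2 × 1.25` (large amplitude drop,
  widening pulse, persisting at ST2); earlobe/forehead/super
  `× 0.82 / 1.05 / 0.82` (small drop, narrowing pulse), with the iPPG sites
  drifting back toward baseline at ST2. These magnitudes are free choices —
  no numeric kernel-level effect sizes exist to copy — picked once to
  produce a large finger effect (g ≈ −2), small head-site effects
  (g ≈ −0.5) and the finger-vs-head PWHA sign inversion. Per-subject effect
  depth is lognormal (sd 0.30), floored so multiplicative shifts stay
  positive.
- Noise: white noise per site (sd 0.02 contact, 0.12 iPPG in signal units
  of beats with ≈1.3–1.9 amplitude), sinusoidal baseline wander at 0.2 Hz
  (amplitude 0.3) — deliberately below the 0.4 Hz high-pass corner so the
  filter has something to remove.
- Reference series: per-beat SBP/DBP/HR = subject baseline + phase shift +
  noise; default shifts +8/+15 mmHg (SBP), +5/+10 (DBP), +4/+3 bpm (HR) at
  ST1/ST2, in the range reported for cold-pressor responses.
- Video: frames embed `offset − signal` inside an ROI polygon on a constant
  background with i.i.d. pixel noise, clipped to the 12-bit range.
  Quantisation, skin optics, motion and face geometry are *not* emulated:
  passing tests show the signal-processing chain is correct, not that the
  method survives real video artifacts.

All randomness flows from a single seed; identical config + seed reproduces
a study bit for bit (sites share one onset sequence per subject — one
heart — with independent noise).

## Numerical choices

- **Fit.** Constrained SLSQP on the sum of squares with analytic gradients,
  inequality constraints `a1 > a2`, `μ1 < μ2` (margins above), bounds
  `α1 ∈ (1, 50]`, `σ2 ∈ [10⁻⁴, duration]`, up to 10 starts: one
  landmark-based guess (systolic kernel at the template argmax, Gaussian at
  the most prominent post-peak hump of a lightly smoothed copy), a
  deterministic sweep of three diastolic-position candidates, then jittered
  copies. The search stops early when the residual reaches the template's
  estimated white-noise floor (from the high-frequency residual of a
  9-sample box smooth). The best solution is polished by bounded
  least-squares (trust-region reflective, analytic Jacobian): the valley
  around the optimum is extremely flat along correlated
  Gamma-versus-Gaussian directions and SLSQP alone stalls a few percent
  short.
- **Baseline anchoring.** Detrended templates sit around zero; the fit and
  the features measure above the beat minimum. The anchor uses a smoothed
  minimum (noise would otherwise bias it ≈3σ low), and a template that is
  already non-negative is fitted without shifting — subtracting the raw
  minimum of a strictly positive beat would push the target outside the
  model family.
- **PWHA ties.** The width runs to the *first* crossing after the global
  maximum, so a diastolic wave that re-crosses half amplitude does not
  inflate the width. When the half-amplitude level grazes the diastolic
  wave, PWHA is inherently discontinuous: arbitrarily small perturbations
  flip which crossing is found. Robustness statements about PWHA under
  noise are therefore made on the Monte-Carlo median, not the worst case.
- **RM-ANOVA.** Plain within-subject sums of squares; no sphericity
  correction. Zero error variance reports F = ∞, p = 0 rather than NaN.
- **Hedges' g on paired data.** g uses the independent-groups pooled-sd
  formula (with nx, ny and df = nx + ny − 2) even though the interval
  design is paired: the standardizer is the between-subject spread. This is
  deliberate fidelity to the method being reimplemented, not the textbook
  paired-design estimator; the paired t-tests, by contrast, are genuinely
  paired.
- **Quantiles.** Tukey fences use linearly interpolated quartiles
  (`numpy.percentile` default); quartile conventions differ enough across
  software to matter for outlier counts.
- **Holm.** The step-down factor (k − i + 1) is followed by the running-max
  monotonicity enforcement and a cap at 1 — required for a valid adjustment
  even though only the factor is usually quoted.
- **iPPG pixels.** A pixel belongs to an ROI iff its centre lies inside the
  polygon (even-odd rule, 0-based coordinates, x right, y down); box-filter
  borders are reflected. Both conventions are arbitrary and fixed here for
  reproducibility.
- **~BBI scope.** The median beat-to-beat interval is computed per analysis
  window from that window's detections.

## Problem sizes

The default end-to-end check processes 35 subjects × 4 sites × 3 windows
(420 templates) per study; the replicated effect-recovery property uses 20
such studies, and the decomposition benchmark 100 random parameter sets.
Fits run on a ≤400-point grid. These sizes were chosen to make the
statistical properties (≥95% rates, family-wise error bounds) measurable
with conventional Monte-Carlo margins.

## Known limitations

- The generator's beats live exactly in the model family the decomposition
  fits; real beats do not, so residuals on real data will be larger and
  recovery statements do not transfer.
- No motion artifacts, arrhythmias, ROI tracking or face detection; ROIs
  are static polygon inputs.
- The slope feature is attenuated by the 8 Hz low-pass (the systolic
  upstroke has content above 8 Hz). Absolute slope values are therefore
  filter-dependent; within-subject contrasts are not materially affected.
- Subjects with any failed template are excluded wholesale (complete-case
  analysis), matching the method's exclusion rule; no imputation.
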