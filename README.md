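# coldwave

Morphological photoplethysmography (PPG) analysis under cold-pressor
stimulation.

## The problem

The cold pressor test (CPT) — immersing a hand in ice water — elicits a
sympathetic response: blood pressure rises, heart rate increases, and
peripheral vasoconstriction reshapes the optical pulse wave. How much the
pulse reshapes depends strongly on *where* and *how* it is recorded:
contact PPG at the finger responds very differently from contact PPG at the
earlobe or camera-based imaging PPG (iPPG) of the face. `coldwave`
implements the full analysis chain needed to quantify these site-specific
morphological responses, for researchers working with multi-site PPG/iPPG
protocols:

- iPPG signal formation from video frames and ROI polygons (10-pixel box
  smoothing, ROI-mean extraction, inversion, interpolation to 2000 Hz);
- zero-phase Butterworth bandpass (0.4–8 Hz, order 5), steepest-ascent beat
  detection, segmentation over `[t_i − 0.45·BBI~, t_i + BBI~]`, quality
  filtering at mean pairwise correlation ≥ 0.3, and ensemble-averaged,
  detrended beat templates per 10 s analysis window (`BL = t_CPT − 30 s`,
  `ST1 = +20 s`, `ST2 = +40 s`);
- pulse wave decomposition of each template into a Gamma plus a Gaussian
  kernel,

  ```
  y(t) = s₁ β₁^α₁/Γ(α₁) · t^(α₁−1) e^(−β₁ t) + a₂ e^(−(t−μ₂)²/(2σ₂²)),
  ```

  constrained so the systolic Gamma kernel peaks first and higher
  (μ₁ < μ₂, a₁ > a₂), and the four morphological features of the
  recomposed (denoised) beat: amplitude, slope, area, and pulse width at
  half amplitude (PWHA);
- the inference chain: repeated-measures ANOVA gate (α = 0.05), paired
  t-tests for the three interval contrasts, Holm–Bonferroni adjustment
  (factor k − i + 1), and Hedges' g

  ```
  g = J(df)·(x̄ − ȳ)/s,   s² = ((nₓ−1)sₓ² + (n_y−1)s_y²)/df,
  J(df) = Γ(df/2) / (√(df/2) Γ((df−1)/2)),   df = nₓ + n_y − 2
  ```

  with 95% confidence intervals, plus Tukey-fence outlier counts and
  per-subject normalization for plotting.

Because no multi-site CPT recording set is bundled, the package ships a
first-class synthetic study generator (`coldwave.synthgen`) that emulates
the whole protocol — beat trains from the same two-kernel model, video
frames with embedded iPPG traces, beat-wise blood-pressure references —
with known ground truth, so every stage is testable end to end.

## Worked example

Simulate a 35-subject, four-site study and run the complete pipeline:

```sh
coldwave simulate --seed 7 --out demo --no-export-signals
```

prints

```
analyzed 35 subjects (0 excluded), 420 templates built
  amplitude BL-ST1   earlobe: g = -0.55 [-1.03, -0.07] ***
  amplitude BL-ST1    finger: g = -1.79 [-2.35, -1.23] ***
  amplitude BL-ST1  forehead: g = -0.57 [-1.05, -0.09] ***
  amplitude BL-ST1     super: g = -0.44 [-0.92, +0.03] ***
```

Every subject yielded a template in all 12 (site × interval) cells, so none
were excluded. The pulse amplitude drops significantly from baseline to the
first stimulation window at every site, with the finger showing a large
effect (g ≈ −1.8: strong local vasoconstriction) and the head sites small
ones (|g| ≈ 0.5) — the injected ground-truth pattern, recovered through
beat detection, template construction, decomposition and statistics.
`demo/` contains `effects.csv` (one row per site, feature and contrast with
t, raw and Holm-adjusted p, g and its CI — e.g. the earlobe BL–ST1 row
holds t = −11.2, p_adj = 1.8e−12, g = −0.55 [−1.03, −0.07]), `anova.csv`,
`outliers.csv`, per-template QC in `qc.csv`, and `manifest.json` with
per-subject exclusion bookkeeping. `coldwave report --results demo` renders
boxplots over the three windows with significance stars;
`coldwave analyze --data <dir>` re-runs the pipeline on exported or
user-supplied signals (CSV + YAML sidecars).

From Python:

```python
from coldwave.synthgen import StudyConfig, generate_study
from coldwave.pipeline import run_study

study = generate_study(StudyConfig(n_subjects=35), seed=7)
result = run_study(study, seed=7)
print(result.effects.query("contrast == 'BL-ST1' and feature == 'pwha'")
      [["site", "g", "p_adj"]])
```

shows the PWHA inversion: positive g at the finger, negative at the head
sites.

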