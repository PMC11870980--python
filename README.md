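# linehrf

Estimation and comparison of hemodynamic response functions (HRFs)
from event-related fMRI, including cortical-depth-resolved
("line-scanning") acquisitions.  The package is aimed at fMRI
methodologists who want a tested, end-to-end reference pipeline for:

* optimized event-related **design generation** — jittered
  inter-stimulus intervals (ISIs) drawn from a truncated negative
  exponential, with a two-stage search that maximizes the variance of
  the predicted BOLD timecourse;
* **deconvolution** of the HRF with FIR and Fourier basis-set GLMs at
  both conventional (TR ≈ 1.32 s) and line-scanning (TR ≈ 0.105 s)
  sampling rates, with leave-one-run-out cross-validation of the
  Fourier order;
* **shape characterization** — amplitude, time-to-peak, FWHM, rising
  slope, positive area, post-stimulus undershoot area;
* **cortical-depth profiles** — per-depth parameters regressed on
  percent cortical depth (slope and the value at 50% depth);
* a **group-comparison battery** — Levene-gated Student's t /
  Mann–Whitney U tests side by side with default JZS Bayes factors,
  plus signal-detection d′ for task performance;
* a **synthetic-data generator** with known ground truth that stands
  in for raw scanner data, so every stage is testable end to end.

## Model

A run's percent-signal-change timecourse is modelled as a linear
superposition of one unknown peristimulus response *h*:

    y(t) = Σ_e h(t − onset_e) + β₀ + β₁ t + ε(t),

with *h* expanded over a window of −3 … 27 s around stimulus onset in
either FIR bins (one indicator per TR, floor(30/TR) bins) or a Fourier
set (a window-mean term plus *n*/2 sine–cosine harmonic pairs).
Coefficients are ordinary least squares; no shape assumptions beyond
the window and (for Fourier) the band limit.

Group differences in a parameter θ are assessed with a pooled-variance
t statistic and its default JZS Bayes factor

    BF₁₀ = ∫₀^∞ (1+Ng)^(−1/2) (1 + t²/((1+Ng)ν))^(−(ν+1)/2) π(g) dg
           ÷ (1 + t²/ν)^(−(ν+1)/2),

with N = n₁n₂/(n₁+n₂), ν = n₁+n₂−2 and π(g) the
inverse-gamma(1/2, r²/2) density (Cauchy prior scale r = 0.707),
evaluated by adaptive quadrature.

## Worked example

```python
import numpy as np
import linehrf as lh

# optimized event-related design: 8 trials, ISIs 3/18/6 s min/max/mean
cfg = lh.DesignConfig(n_trials=8, tr=1.32, seed=0)
isis = lh.optimize_isi_set(cfg, n_candidates=200, seed=0)
events = lh.build_event_table(lh.optimize_isi_order(isis, cfg, seed=1), cfg, seed=2)

# simulate a noisy run with known ground truth and deconvolve it
hrf = lh.GroundTruthHRF(peak_delay=4.5, amplitude=1.6)
noise = lh.NoiseModel(white_sd=0.6, ar1_coef=0.3, drift_slope=0.01)
duration = float(np.ceil((events["onset"].max() + 33) / cfg.tr) * cfg.tr)
raw, _ = lh.simulate_run(events, hrf, noise, cfg.tr, duration, seed=3)
psc = lh.percent_signal_change(raw, cfg.tr)
decon = lh.Deconvolver(kind="fourier", tr=cfg.tr, n_regressors=10).fit(events, psc)
params = lh.extract_parameters(decon.reconstruct(0.05))
print(f"R^2 = {decon.r_squared_:.3f}")
print(f"amplitude    = {params.amplitude:.2f} %  (truth 1.60)")
print(f"time to peak = {params.time_to_peak:.2f} s")
print(f"BF10(t=-0.287, 11 vs 11) = {lh.jzs_bf10(-0.287, 11, 11, 0.707):.3f}")
```

prints

```
R^2 = 0.642
amplitude    = 1.80 %  (truth 1.60)
time to peak = 5.25 s
BF10(t=-0.287, 11 vs 11) = 0.396
```

The deconvolved amplitude lands near the injected 1.6% (a single short
noisy run; averaging three runs tightens it), the response peaks
around 5 s, and a t statistic of −0.287 between two groups of 11
yields BF₁₀ = 0.396 — moderate evidence that the groups do not differ.

The same stages are scriptable from the shell (`linehrf design`,
`simulate`, `deconvolve`, `extract`, `depth`, `stats`, `run-all`);
`linehrf run-all --out results/ --seed 0` runs the full synthetic
cohort analysis and writes parameter tables, depth regressions, group
reports and a checksummed manifest.

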