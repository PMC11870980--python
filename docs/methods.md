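# Methods

## Scope and model

`linehrf` implements the analysis chain for event-related HRF
estimation: design generation → forward simulation (or measured
timecourses) → percent-signal-change conversion → run averaging →
basis-set deconvolution → shape parameterization → cortical-depth
regression → two-group statistics.  The core assumption throughout is
linear time-invariance of the BOLD response: responses to individual
trials superpose additively.  This is defensible for the designs the
package generates because the minimum gap between stimulus offset and
the next onset is 3 s, below which nonlinear (saturating) interactions
would start to bias shape estimates.

## Design generation

ISIs are drawn as `isi_min + X` with `X` exponential, truncated at
`isi_max − isi_min`.  The exponential scale is solved (Brent's method
on the closed-form truncated mean, using `expm1` for numerical
stability in the uniform limit) so that the **truncated** distribution
has exactly the requested mean; the mean of a truncated exponential is
confined to `(isi_min, (isi_min+isi_max)/2)`, and means outside this
interval raise a configuration error rather than silently
recalibrating.  The ISI convention is offset-to-onset: the quoted
3/18/6 s bounds apply to the gap between one stimulus ending and the
next beginning.  This convention is a deliberate choice (the
alternative, onset-to-onset, would allow gaps below 3 s and undermine
the linearity argument above).

Optimization is two-stage: stage 1 samples `n_candidates` (default
1000) ISI multisets and keeps the one whose predicted timecourse — the
stimulus boxcars convolved with a canonical double-gamma kernel (peak
delay 6 s, undershoot delay 16 s, dispersions 1, undershoot ratio 1/6,
the conventional default when no kernel is specified) — has the
largest unbiased sample variance; stage 2 reorders that multiset by
the same objective.  The reorder space is factorial, so it is searched
exhaustively only up to 8 ISIs (all distinct permutations, iterated in
sorted order so ties resolve deterministically to the
lexicographically first optimum); beyond 8, a pairwise-swap hill climb
with periodic random restarts runs for a fixed evaluation budget and
never returns an order predicting less variance than its input.

Targets (brief contrast inversions used to hold attention) are
sub-events inside a trial: `round(target_fraction × n_trials)` trials
get one, at a uniformly drawn frame index, with onset `trial_onset +
frame_index / flicker_rate`.  Targets do not enter the BOLD forward
model or the deconvolution design; they drive the behavioral
simulation only.

## Synthetic data

The generator emulates the study conditions the analysis was built
for: event-related runs with a 20 s gray-screen baseline, 3 s stimuli,
jittered ISIs; whole-brain sampling at TR = 1.32 s and line-scanning
sampling at TR = 0.105 s; a depth-resolved response whose amplitude
declines linearly from the pial surface (depth 0%) to the white-matter
boundary (100%), `amplitude_d = amplitude × (1 + slope × (50 − d))`;
two subject groups of 11 and 9; three runs per subject sharing one
design so they can be averaged sample-by-sample.

The raw series is `100 × (1 + response/100) + drift + AR(1) noise` in
arbitrary units — the baseline is fixed at 100 so percent-signal-change
conversion is exercised nontrivially.  The response is computed on an
internal grid oversampled to ≤ 0.05 s (an integer divisor of TR) and
decimated: simulating directly on a coarse TR grid would snap event
onsets to the grid and misrepresent designs whose onsets are
continuous.  The double-gamma kernel has finite support `[0, 24)` s so
that the response to a 3 s stimulus lies entirely inside the 30 s
estimation window; the kernel-and-boxcar convolution is rescaled so
that the **peak of an isolated single-trial response** equals the
subject's amplitude parameter, which makes amplitude directly
comparable between ground truth and deconvolved estimate.  AR(1) noise
is parameterized by its stationary marginal SD (innovation SD
`white_sd·√(1−a²)`, stationary first sample), plus a linear drift in
percent of baseline per second.  Defaults: white_sd 2% per depth bin,
a = 0.3, drift 0.01 %/s.

Population distributions of the ground-truth parameters are anchored
to the reported line-scanning statistics: amplitude ~ N(1.61, 0.37²) %
signal change, and peak delay ~ N(4.5, 0.55²) s so the response to a
3 s stimulus peaks at ≈ 5.3 ± 0.6 s.  Draws are lightly clamped to
keep the shape family valid (undershoot delay ≥ peak delay + 2 s,
undershoot ratio in [0, 0.9]).

Behavior follows an equal-variance Gaussian signal-detection model:
hit probability Φ(d′/2 − c), false-alarm probability Φ(−d′/2 − c),
lognormal reaction times matched to a requested mean and SD.

What the generator does **not** emulate: head motion, MR physics
(multi-echo decay, coil sensitivities), thermal-noise structure after
denoising, spatial correlations between depth bins (noise is
independent across depths), and nonlinear BOLD saturation.  Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated linear model, not robustness to every
artifact of real line-scanning data.

## Deconvolution

The peristimulus window is −3 … 27 s.  FIR uses `floor(window/TR)`
indicator bins (22 at TR 1.32 s, 285 at TR 0.105 s); the floor
convention drops a final partial bin rather than letting a regressor
extend past the window.  The Fourier set contains `n/2` sine and `n/2`
cosine harmonics of the window length **plus a window-boxcar DC
term**.  The DC term is not cosmetic: all harmonics integrate to zero
over the window, so without it no one-signed response is representable
— on noise-free data the DC-less model leaves ~28% of the signal
variance unexplained and biases amplitude by ~−19%.  The run-level
intercept cannot absorb this because the superposed per-event window
boxcars vary over the run.  `n_regressors` counts the harmonics (so
"10 regressors" means 5 sine/cosine pairs; 11 columns with DC).

Nuisance regressors are an intercept and a linear drift per run.
Estimation is plain OLS (`numpy.linalg.lstsq`); rank deficiency is
detected from the R diagonal of a QR factorization and reported with
the names of the offending columns.  The reported R² is incremental:
variance explained by the signal columns beyond the nuisance-only
model.  Reconstruction evaluates the Fourier expansion analytically on
a 0.05 s grid; FIR coefficients are placed at bin centers and linearly
interpolated.

The Fourier order is selected by leave-one-run-out cross-validation:
for each candidate order the model is fit on the remaining runs
stacked (shared signal coefficients, per-run nuisance blocks) and
scored on the held-out run by out-of-set R² after projecting the
held-out series and signal design onto the orthogonal complement of
that run's nuisance space.  Candidates within 1e−9 of the best mean
score tie toward the smaller order, so noise-free data select the most
parsimonious sufficient basis.  Note that the band limit of a
10-harmonic set over a 30 s window shaves 1–4% off the peak of narrow
responses; cross-validation on clean, well-sampled data accordingly
selects larger orders, and recovery tests that demand sub-percent
amplitude accuracy use 16 harmonics.

The block-design localizer GLM uses a single regressor (ON/OFF boxcar
convolved with a unit-area Gaussian kernel, mean 6 s, SD 2 s — a
reasonable default for a canonical response; configurable), plus
intercept and drift, and thresholds the regressor's t statistic at 2.3
to form the voxel mask.

## Shape parameters

From a reconstructed curve, with the peak searched over t ≥ 0 only:

* **amplitude** — curve maximum;
* **time-to-peak** — argmax, seconds from stimulus onset;
* **FWHM** — distance between linearly interpolated half-maximum
  crossings bracketing the peak; flagged undefined (NaN) when a
  crossing is missing on either side, never guessed;
* **rising slope** — maximum of the first-difference derivative
  between onset and the peak (the mean derivative is a documented
  alternative; the maximum is less sensitive to where exactly the rise
  begins);
* **positive area** — trapezoidal integral of the positive part over
  the whole window (all positive lobes, not just the first);
* **undershoot area** — absolute trapezoidal integral of the negative
  part from the first post-peak zero crossing (linearly interpolated)
  to the window end.  Starting at the first crossing keeps the measure
  stable when the tail wiggles around zero.  Per-depth curves are too
  noisy for this measure, so it is computed only on depth-averaged
  responses; profile extraction omits it.

An all-nonpositive curve raises an error (amplitude undefined) rather
than returning a degenerate parameter set.

## Depth profiles

A line of `n` voxels maps to equally spaced depths 0…100% (a single
voxel maps to 50%).  Depth 0 is the pial surface; with this convention
the simulated amplitude gradient is a negative regression slope,
matching the expected decline of BOLD amplitude toward the
white-matter boundary caused by pial draining veins.  Each parameter
profile is regressed on `depth − 50`, so the intercept is the value in
mid-cortex; 95% CIs come from the t distribution on n − 2 df
(`scipy.stats.linregress` standard errors).  Both per-subject
regressions (used for group comparisons of slopes and mid-depth
values) and pooled group fits are available.  The
most-perpendicular-vertex criterion selects, from a set of cortical
surface normals, the one with the smallest absolute angle to the line
direction (`arccos |n·d|`, sign-invariant).

## Statistics

The per-parameter protocol mirrors the study design: Levene's test
(mean-centered, α = 0.05) gates between the pooled-variance Student's
t test and the Mann–Whitney U test; the default JZS Bayes factor is
always computed from the pooled t statistic, so frequentist and
Bayesian summaries sit side by side even for Mann–Whitney-gated
parameters.  No multiple-comparison correction is applied — the six
parameters are strongly interdependent, so the number of effectively
independent comparisons is indeterminate.

The Bayes factor integrand (Zellner–Siow mixture of g-priors, Cauchy
prior scale 0.707 on the standardized effect) is integrated with
`scipy.integrate.quad` at relative tolerance 1e−8; the unit tests
cross-check against an independent implementation (pingouin).  The
Mann–Whitney p value is exact (full null distribution) for tie-free
samples with n₁+n₂ ≤ 12 and a tie-corrected normal approximation
otherwise; both the U and rank-sum W conventions are reported.  Paired
t tests report both `d_z` (mean difference / SD of differences) and
classical Cohen's d (mean difference / pooled condition SD), since
both conventions are common and they differ materially for correlated
conditions.  d′ applies the 1/(2N) correction to extreme hit and
false-alarm rates.

Degenerate inputs are handled explicitly: zero pooled variance with
equal means gives t = 0, p = 1 (with unequal means it is an error);
identical constant samples give a Levene statistic of 0.

## Problem sizes used by the test suite

Simulation-backed tests are scaled to run quickly while preserving the
statistical structure they probe.  The cohort calibration/power check
uses 200 replicates of an 11-vs-9 cohort analyzed exactly like the
depth-averaged arm: since the group statistics operate on the
depth-averaged series, the ~10 depth bins are collapsed analytically
into one series whose noise SD is the per-depth SD divided by √10,
with 3 runs averaged, 32 trials per run, at TR 1.32 s.  Depth-gradient
recovery uses 6 subjects × 10 depths at low noise.  Oracle-equivalence
tests (FIR vs ground truth) run a single noise-free 32-trial run at TR
0.105 s with onsets on the sampling grid, where the discrete forward
model is exactly representable and recovery is at machine precision.

## Known limitations

* Power and calibration statements transfer to real data only to the
  extent the noise model (AR(1) + drift, independent across depths)
  resembles denoised line-scanning noise; no empirical noise spectra
  were available to fit.
* In a linear forward model, amplitude, rising slope, positive area
  and undershoot area all scale together; group differences injected
  through amplitude are therefore genuinely present in those dependent
  parameters too, and detection specificity between them is limited in
  principle, not by implementation.
* FIR reconstruction interpolates bin values at bin centers; for
  events off the sampling lattice the bins mix neighbouring lags, so
  FIR/Fourier agreement is only expected to a fraction of the bin
  width.
* The exact Mann–Whitney branch enumerates the null distribution only
  for tie-free data; heavily tied small samples fall back to the
  approximation.
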