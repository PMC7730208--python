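# Methods

## Signal model and pipeline

A session is a dense time × channel matrix of hemoglobin concentration
changes (µM) sampled at `fs` (default 12.5 Hz), with an event schedule of
task onsets and durations. The emulated block design is: 60 s initial
rest, 20 trials of (2 s cue + 10 s task + 15–17 s rest, jitter uniform),
60 s final rest, 36 channels. The analysis chain is

1. band-pass 0.03–0.15 Hz, fourth-order Butterworth, applied
   forward–backward (zero phase, effective magnitude order 8);
2. Savitzky–Golay smoothing, 1.0 s window (forced odd in samples),
   polynomial order 3;
3. trial epoching over a half-open window relative to task onset and
   element-wise averaging per stimulus type;
4. channel selection (below);
5. spatio-temporal features from ΔHbO, min-max normalized;
6. Fisher LDA with leave-one-trial-out cross-validation.

Zero-phase filtering is deliberate: a causal pass would delay every
channel by the filter group delay and bias the cross-correlation lags the
z-score method inspects. The filter band and smoothing parameters are
config-overridable (`AnalysisConfig`).

The analysis epoch is (0, 24) s from task onset — 300 samples at 12.5 Hz —
so the per-channel regression has 299 degrees of freedom; the 2 s cue
precedes the onset and is excluded. The dHRF template for the averaged
trial is built from the same window: a 10 s boxcar at the epoch origin
convolved with the canonical HRF.

## Canonical HRF

Two-gamma form with the widespread canonical parameters: peak delay
α₁ = 6, undershoot delay α₂ = 16, dispersions β₁ = β₂ = 1 (1/s),
peak-to-undershoot ratio c = 1/6, amplitude A = 1. Time is in seconds on
the sampling grid; h_c(0) = 0 because both shape exponents exceed 1, and
the kernel is truncated at 32 s. The discrete convolution
`h_M[k] = Σ_{n≤k} h_c[n] s[k−n]` is evaluated with 0-based indices and
truncated to the boxcar's length; its raw amplitude therefore scales with
`fs`, which is irrelevant to correlation and regression up to scale.

## Channel selection

**z-score method.** Per channel the raw (unnormalized) sliding
cross-correlation with the template is maximized over every zero-padded
overlap lag τ ∈ [−(k−1), k−1]. The maximum is *signed* — an
anti-correlated channel scores low rather than high — and amplitude
contributes by construction; a unit-energy normalized variant exists
behind a flag. Lag ties break toward the smallest |τ|, then the negative
lag (a deterministic rule; ties occur for symmetric inputs). The
per-channel maxima are standardized across channels and `z > 0`
(strictly) selects. Because `z > 0 ⇔ r > r̄`, the population-vs-sample
standard-deviation convention cannot change the selected set; population
(ddof = 0) is the default. All-equal maxima leave z undefined — that is
raised as a degenerate-input error rather than silently selecting
nothing, since it indicates broken preprocessing.

**t-value method.** Per channel, bisquare IRLS (tuning constant 4.685,
convergence on coefficients at 1e-8, at most 50 iterations, MAD scale,
standard errors from the robust weighted covariance) fits the averaged
trial on the template plus an intercept absorbing baseline drift. The
test is one-tailed — activation is a positive-coefficient hypothesis,
consistent with 1.65 being the one-tailed 5% critical value at
df = 299 — with p from Student's t at k − 1 degrees of freedom. A
zero-residual fit reports t = sign(φ)·∞ with the matching p (0 for
positive, 1 for negative): the analytic limit as SE → 0, which keeps a
perfectly anti-correlated channel unselected. Both regression-based
methods operate on the *averaged* trial per stimulus type, which is what
makes df = 299 coherent with the 24 s epoch.

**Baseline correction.** Task-epoch peak vs rest-epoch peak of the
averaged response, strict inequality; ties do not select.

Note on bisquare IRLS vs OLS: on data without gross outliers the two
agree closely but not to machine precision — the bisquare weights vary
with the residuals, so exact equality holds only when residuals vanish or
all share one magnitude (equal weights make the weighted fit collapse to
OLS). The equivalence tests use exactly those constructions; with a
small, unstable sample (a handful of points) the robust fit can instead
interpolate a subset and legitimately diverge from OLS.

## Features and classification

Features are computed from ΔHbO only. Task-class rows use the (0, 10) s
task window; rest-class rows use an equally long (15, 25) s window — 5 s
after task offset, clear of the undershoot. Each trial is spatially
averaged over the selected channels, then summarised by the feature
statistics: mean, peak, least-squares slope in units/second
(fs-invariant), and optionally sample variance (n−1), bias-corrected
skewness and excess kurtosis. Min-max normalization is per feature column
over both classes jointly — the only scope that keeps classes comparable —
with constant columns mapped to zeros (guarded 0/0). With 20 trials and
3 features this yields the 20 × 3 per-class blocks of a 40 × 3 matrix.

Fisher LDA: within/between-class scatter matrices by direct summation,
projection from the closed form `S_W⁻¹(μ₁ − μ₂)` (a generalized
eigenvector route is available and agrees in direction); equal class
priors; decision threshold at the midpoint of the projected class means;
exact-threshold ties go to the first class in fit order. A singular `S_W`
is ridged with `1e-6·(trace/d + 1)·I` and retried — relevant for
perfectly separable synthetic features. Cross-validation is
leave-one-*trial*-out: each fold holds out one trial's task row together
with its paired rest row, trains on the remaining 2(n−1) rows and
classifies both held-out rows, so with 20 trials the classifier is
trained 20 times and accuracy is correct/(2n)·100, reported to one
decimal.

## Method comparison statistics

Per-subject accuracy vectors are compared with a two-tailed paired
Student's t-test using the sample (n−1) standard deviation of the
differences. The family of three comparison settings is Bonferroni
corrected: adjusted threshold 0.05/3 = 0.0167 (4 decimals). The bundled
29-subject benchmark table stores accuracies at the 5% granularity they
were published with; p-values recomputed from it are therefore of the
same order as, but not digit-identical to, values derived from unrounded
per-subject accuracies. All six recomputed comparisons fall one to three
orders of magnitude below the adjusted threshold.

## Synthetic sessions

The simulator's purpose is ground-truth evaluation: selection
sensitivity/specificity are unobservable on human data. Active channels
(default 8 of 36) carry the boxcar⊗HRF waveform normalized to unit peak
and scaled by `activation_amplitude` — so the amplitude parameter *is*
the peak ΔHbO response, default 1.0 µM, a typical task-evoked magnitude.
Every channel adds: cardiac 0.3 µM at 1.1 Hz, respiratory 0.2 µM at
0.25 Hz and Mayer-wave 0.1 µM at 0.1 Hz sinusoids with per-channel random
phases; a random-walk drift with 0.005 µM per-sample steps; and white
noise with σ = 0.15 µM. Cardiac and respiratory components fall outside
the 0.03–0.15 Hz passband, but the Mayer wave deliberately sits inside
it, so selection is always tested against an in-band confound. ΔHbR is
the anti-correlated activation scaled by 1/3 with independent noise
scaled likewise. All draws come from one seeded generator in a fixed
order: identical configs give bit-identical sessions.

What the simulator does *not* emulate: motion artifacts, superficial
(scalp) hemodynamics and short-channel physiology, spatially correlated
noise across neighbouring channels, subject-to-subject anatomical
variability, and amplitude/latency variability of the response across
trials. Passing ground-truth recovery here therefore demonstrates the
selection logic and pipeline plumbing under realistic in-band noise — not
performance on real recordings, where those unmodelled components
dominate the difficulty. At the default amplitude the task response is
strong (peak SNR ≈ 6 against the white-noise floor), and both the
selected-channels and all-channels classification arms sit at ceiling;
the selection metrics, not accuracy, separate the methods there.

## Problem sizes and determinism

Default test and reproduction runs use the full 36-channel, 20-trial
session (~680 s at 12.5 Hz). Property checks that repeat the pipeline
many times (amplitude monotonicity across seeds) use reduced sessions
(12 channels, 10 trials), chosen as the smallest sizes at which the
checked orderings are stable. Every stochastic test fixes its generator
seed; hypothesis suites run derandomized.

## Known limitations

- SNIRF support is a minimal profile: one data block, continuous-wave
  amplitude or processed HbO/HbR concentration; anything else is rejected
  with a clear message.
- The Beer–Lambert defaults (760/850 nm extinction values from standard
  compiled hemoglobin tables, DPF 6.0, separation 3 cm) are conventions,
  not measurements; converted concentrations are only as accurate as
  those constants. They are config-overridable.
- Single task type per session; multi-class paradigms and multi-regressor
  GLMs are out of scope.
- The t-value method's p-values treat the averaged-trial samples as
  independent; serial correlation left by filtering makes the nominal
  type-I rate approximate (the white-noise calibration test bounds it at
  the nominal level only for unfiltered noise).
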