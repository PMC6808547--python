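# Methods

This note documents the models, the synthetic stated world, the numerical
choices, and the limits of what the test suite establishes.

## 1. Acoustic parameterization

Each call is parameterized by 15 measures (phee, food) or 17 (trill):

| group | measures |
|---|---|
| F0 contour | start, end, mean, min, max (Hz); % duration at max F0; \|slope\| = \|F0_end − F0_start\| / duration (Hz/s); mean \|ΔF0\| per second |
| spectrum | energy quartiles Q25/Q50/Q75 (Hz) from the cumulative Welch power spectrum; peak frequency; % of frames whose own spectral peak lies within 1% of it |
| periodicity | local jitter = mean \|ΔT\| / mean T × 100 over consecutive frame periods |
| temporal | duration on a −25 dB frame-RMS envelope threshold (half-open frames) |
| trill FM | modulation rate (Hz) and peak-to-trough extent (Hz) of the F0 contour |

**Pitch tracking** is short-time autocorrelation: frames of 3/floor s at a
5 ms step are Hann-windowed; the FFT autocorrelation is normalized and the
integer-lag peak is picked on the *tapered* curve (the window taper
penalizes octave-down candidates), then refined on the taper-deconvolved
curve with an exact three-point cosine interpolation (parabolic fallback).
Defaults: floor 3 kHz, ceiling 14 kHz — the tonal range of marmoset calls —
voicing threshold 0.45, silence gate −40 dB below the loudest frame. Frames
failing either gate are unvoiced; calls with < 3 voiced frames are flagged
unmeasurable, as are silent calls. The exact settings of the original
Praat-based measurement chain are not public; these defaults are
documented choices, validated by synthesis→extraction round-trips (pure
tones recovered well within 1%, trill FM rate/extent within 5% at 20 dB
SNR).

**FM extent** is measured as twice the amplitude of a least-squares
sinusoid fitted at the detected FM rate. Raw sample-level peak-picking on
a 5 ms contour grid undersamples a 30 Hz modulation (~6.7 samples/cycle)
and biases the extent low by ~7%; the sine fit measures the excursion of
the underlying contour. Peak-picking remains available via
`fm_method="peaks"`.

**Inclusion rules.** Within a recording session the first 5 trills, 10
phees and 20 food calls are kept (flagged overlapping/noisy/unmeasurable
calls are excluded first; under-quota sessions keep everything). An animal
enters a week's data set only with ≥ 5 calls of that type in that week.

## 2. PCA with parallel-analysis retention

Parameters are z-scored (sample SD, ddof = 1) and decomposed by
correlation-matrix PCA (SVD of the z-scores; eigenvalues sum to the number
of parameters). Component k is retained when its eigenvalue exceeds the
95% quantile of the k-th eigenvalue over 10,000 standard-normal datasets of
the same shape (rank-wise Horn comparison; a single pooled-quantile
threshold is available via `mode="scalar"`). Retention stops at the first
failing rank, so the retained set is a leading run. If no component
passes, `NoComponentsRetainedError` is raised rather than silently keeping
one. Loadings are sign-fixed (largest-magnitude entry positive) for
reproducibility. For the social analysis the model is fit on the pooled
translocated + baseline calls of each call type and all calls are
projected; the fit set is configurable.

## 3. Crossed pDFA

The test factor is condition; the control factor is the individual; the
design must be crossed (every animal recorded in every condition). For
each of `n_selection_rounds` (default 100) balanced splits, `cell_quota`
calls per (animal × condition) cell (default min cell − 1, at least 2)
train a Fisher discriminant with pooled within-class covariance and equal
priors; the remaining calls are classified, and the statistic is the mean
held-out percent correct. The null distribution recomputes the *same*
selection-averaged statistic on `n_permutations` (default 1000) datasets
whose condition labels are permuted across whole blocks within each
animal. Using the same number of selection rounds on both sides keeps the
observed and permuted statistics exchangeable under the null; a
single-selection null would be conservative. The p-value uses the add-one
convention, the chance-expected percent correct is the mean of the null
draws, and p < 0.1 is flagged as a trend in reports. A singular pooled
covariance falls back to a ridge of 1e−8 × trace/p. Calibration: over 200
null worlds with strong caller effects the rejection rate at α = 0.05 sits
inside the exact binomial band and the p-values are uniform; power for a
1.5 within-animal-SD shift on 2 of 4 variables exceeds 0.8.

## 4. Vocal distance

The population centroid of a call type is computed per retained-PC axis as
the unweighted mean over baseline animals of each animal's 10% trimmed
mean (drop ⌊0.1 n⌋ from each tail), so every animal counts equally and
single outlier calls cannot move the centroid. It is computed once from
all baseline calls and frozen across weeks. A call's distance is

d = √( Σₖ [ pₖ (sₖ − cₖ) ]² ),

with pₖ the component's share of *total* variance (eigenvalue / number of
parameters). The alternative reading of variance weighting — pₖ as an
inner-product weight, d = √( Σₖ pₖ (sₖ−cₖ)² ) — is available via
`mode="sqrt"` for sensitivity analysis. Distances are ln-transformed for
modeling; an exact zero (probability zero in practice) is clamped at 1e−12
with a warning.

## 5. Accommodation models

Per call type, `ln d ~ sex + week + sex:week` with a random intercept per
animal, ML estimation (statsmodels MixedLM). Weeks use the study coding:
0 = natal colony, 0.5 = quarantine (new physical environment, no new vocal
input), 1–16 = weeks in acoustic contact with the target colony; the
pre-exposure rows anchor the baseline distance. Sex is coded with female
as reference. If the interaction's t-test (residual df = n_obs − k; no
Satterthwaite approximation is available in the backend) gives p ≥ 0.05
the model is refit without it. The reported `week_slope` is the
sex-averaged exposure-time slope: the week coefficient of the reduced
model, or week + interaction/2 (covariance-correct SE) when the
interaction is retained — in that case the week main effect alone is the
female-only slope and is not interpreted in isolation. Model comparison is
a likelihood-ratio test against the intercept + random-effects null (χ² =
2ΔLL, df = difference in fixed effects). Fit quality is summarized by
Nakagawa R²: R²m = var_f / (var_f + var_r + var_e) and R²c = (var_f +
var_r) / (same), with var_f the sample variance (ddof = 1) of the
fixed-effect predictor. If the random-intercept variance collapses to the
boundary and the Hessian is singular, the fit falls back to OLS (the exact
ML solution at the boundary) and is flagged. The pre/post contrast is an
OLS model `ln d ~ condition × sex` on the quarantine rows vs NewSoc weeks
≥ 5. Weekly summaries are per (animal, call type, week) means with
percentile-bootstrap 95% CIs (default 2000 resamples), restricted to cells
with ≥ 5 calls.

Random slopes per animal are available behind a flag but off by default:
four animals cannot support them.

## 6. The synthetic stated world

`default_scenario()` emulates the social design: colonies MA (translocated,
4 animals, 2F/2M) and ZH (baseline, 4 animals), three call types, weekly
sessions at weeks 0, 0.5, 1–16 yielding the selection quotas (5 trill / 10
phee / 20 food per animal). A call is

x = exp(c_i) · ( D·g(w) + P·[w = w_p] + Λf + ε ),

* **D** — dialect offset of the animal's colony: alternating ±3
  within-call SD per parameter (target colony at the origin). The
  magnitude is a free parameter chosen to give near-ceiling pDFA power and
  a retained-variance share (~65–80%) similar to real fits; alternation
  keeps the dialect direction clear of the factor loadings.
* **g(w)** — convergence: 1 for w < 1 (natal colony and quarantine carry
  the full natal dialect), exp(−r·w) afterwards. Defaults: trill r =
  0.0490 (calibrated so the induced expected ln-distance slope is exactly
  −0.050/week — the pre-exposure anchor weeks steepen the fitted line by
  ~2% relative to the raw decay rate), phee r = 0.021, food r = −0.009
  (divergence). Rates may differ by sex; defaults are sex-equal.
* **P** — transient perturbation applied only in the first week after an
  environment change (used by `perturbation_scenario()`, the environmental
  design: 8 animals, Before / After1 / After2, a 2-SD shift on 6 food-call
  parameters that is gone by After2).
* **Λf** — three latent factors with blockwise loadings (0.8) giving the
  correlated structure real acoustic parameters have; without it nothing
  would be retainable by parallel analysis.
* **exp(c_i)** — the per-animal effect, c_i ~ N(0, 0.3²), a *radial*
  scaling of the animal's deviation from the population centroid. This
  makes the individual effect an exact random intercept on ln vocal
  distance, which is the structure the mixed model assumes. Real animals
  also differ in *direction*; additive directional offsets act as random
  slopes on ln distance and make the random-intercept model's nominal CIs
  anticonservative, so directional variation is deliberately not part of
  the default world — a green slope-recovery test therefore certifies the
  pipeline under the model's own assumptions, not robustness to
  misspecified random effects.
* **ε** — iid Gaussian within-call noise, SD 1 (the unit of the offsets).

Determinism: identical (config, seed) reproduces the feature table
byte-for-byte; all stochastic operations take explicit seeds.

What the generator does **not** emulate: realistic spectro-temporal call
structure beyond tonal/FM synthesis (no harmonics, no compound calls such
as trillphees), session-level recording artifacts, unbalanced or missing
weeks, directional individual variation (above), or drift in the baseline
colony (its centroid is stationary by construction).

In the default social world the food type's persistent between-colony
separation inflates every parameter's variance enough that the factor
correlations fall below the parallel-analysis threshold: food calls then
retain only the dialect component. This is a property of the stated world,
not of the retention mechanism (which is validated on dedicated known-rank
data).

## 7. Known limitations

* The pitch tracker is validated on synthetic tonal/FM signals; real
  recordings with harmonics, reverberation or overlapping callers will
  need the voicing and band parameters tuned, and the defaults make no
  claim of matching the original Praat settings.
* Fixed-effect p-values use residual-df t statistics; with four animals
  these are anti-conservative relative to Satterthwaite/Kenward-Roger.
* The pre/post contrast treats calls as independent within windows (as an
  OLS model does); its p-values inherit that assumption.
* The end-to-end CI coverage of the convergence slope is honest only to
  the extent the random-intercept assumption holds (see §6); pipelines on
  real data share the same caveat, which is worth remembering when reading
  the original tables.
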