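# Methods

This note records the statistical model behind each metric, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions taken where more than one reasonable
implementation exists.

## Data model

One subject's record is a vector of `T` epoch-level acceleration
magnitudes in milli-g (1 g = 9.81 m/s², `milli-g` = g/1000), typically
1-minute ENMO averages over seven days (`T = 10 080`). Three derived
series feed the metrics:

- the acceleration series `x` itself (DFA input);
- the binary state series `y`, active iff `x_t > δ_y` with the strict
  inequality — an epoch exactly at the cut-point counts as rest. The
  default δ_y = 40 mg is the standard wrist cut-point separating
  inactivity from light-or-higher intensity; it is configurable;
- the hourly active-proportion series `z` of length `P = D·H`
  (default `H = 24`), requiring whole hours and whole days — partial hours
  or days are a hard error, as are missing or non-finite epochs. Non-wear
  handling is out of scope: the package expects complete records, and the
  error message names the offending epoch.

Internally all epoch indices are 0-based with half-open intervals;
1-based conventions in the formulas below are mapped at the boundary.

## IS and IV

IS and IV are implemented literally, with no finite-sample correction:

    IS(z) = D Σ_h (z̄_h − z̄)² / Σ_{d,h} (z_{d,h} − z̄)²
    IV(z) = P Σ_{p=2..P} (z_p − z_{p−1})² / ((P−1) Σ_p (z_p − z̄)²)

A constant `z` makes both undefined (zero variance); the package raises
`UndefinedMetricError` rather than emitting NaN silently, and the model
layer converts that into a per-metric status entry.

IS is a variance ratio and always lies in [0, 1]. IV's interpretable
range [0, 2] is asymptotic and model-based: if `z` is a stationary AR(1)
process `Z_p = μ + φ Z_{p−1} + ε_p` with `0 ≤ φ < 1`, then as `P → ∞`,
IV → 2(1 − φ). Finite records or negative `φ` (ultradian rhythms —
cycles shorter than a day) can push IV above 2; such values are returned
unchanged and flagged via `ultradian_flag` (`φ̂ < 0` or IV > 2). The
lag-1 coefficient `φ̂` is estimated by OLS of `z_p` on `z_{p−1}` with an
intercept, which coincides with conditional maximum likelihood for a
Gaussian AR(1); the estimator behind published `φ̂` panels is not uniquely
pinned down anywhere we know of, and OLS is the natural reading of the
model equation. IV is deliberately offered only on the hourly series `z`:
on 1-minute data the AR(1) rationale fails and the [0, 2] reading is
unsupported.

## Transition probabilities

With `n_r` rest bouts totalling `T_r` epochs (and symmetrically for
activity), the s = 1 estimators are

    ML:    (n_r − I(y_T = r)) / (T_r − I(y_T = r))
    Bayes: (n_r − I(y_T = r) + λ) / (T_r − I(y_T = r) + λ),  λ > 0
    RAD:    n_r / T_r

The indicator removes the final bout's unobserved closing transition from
both counts. For general memory length `s`, the ML numerator is
`Σ I(r_i ≥ s) − I(y_T = r)` and the denominator
`Σ (r_i − s + 1) I(r_i ≥ s) − I(y_T = r)`; the indicator is subtracted
unconditionally, exactly as the estimator is defined, even when the final
bout is shorter than `s`. `s` is accepted up to the longest bout length;
a denominator ≤ 0 after censoring (state absent, or a single fully
censored bout) raises the undefined-estimate error with a pointer to the
Bayesian estimator, which is defined for every λ > 0 and equals 1 when
the state is never observed (λ/λ — were the subject ever to enter that
state, an immediate return is the best available guess).

Default λ = 0.5 (horseshoe-type Beta prior); λ = 1 (uniform prior) and
λ = 1e-6 (numerically indistinguishable from ML) are the other presets
worth using. Values above 1 pull too far from the data.

### Wake/sleep windows

The four windowed TPs accumulate bout counts and time-in-state totals per
label over all of that label's intervals. A bout cut at a window boundary
is **censored at the cut**: it contributes to the bout count and to
time-in-state, but neither the cut itself counts as an observed
transition nor the cut epoch as a transition opportunity. Concretely,
with `k` censored bout ends in a label (boundary cuts plus the end of the
record),

    TP = (n − k + λ) / (T − k + λ).

For a single window covering the whole record `k = I(y_T = state)` and
the formula reduces exactly to the whole-series Bayesian estimator. This
is a design choice: the alternative — a single last-epoch indicator per
label with boundary-cut bouts counted as successes — systematically
inflates the numerator by roughly one per day. With 1-minute epochs and
daily windows the two differ by `≈ n_days / T_state`, negligible for
week-long records, but the censored form is the coherent ML reading and
is what the package computes.

## DFA and the ABI

The chain: integrate the mean-centred signal
(`c_t = Σ_{i≤t}(x_i − x̄)`, so `c_T = 0` up to rounding); for each box
size `n`, split `c` into `B = ⌊T/n⌋` non-overlapping boxes, fit an
order-`l` polynomial per box by least squares, and take the RMS residual
`F(n)`; regress `log F(n)` on `log n` by OLS over a grid of box sizes.
The slope is `α̂`, reported with the regression standard error.

Numerical decisions, made once:

- **Grid**: 40 log-spaced integers in `[4, ⌊T/4⌋]`, duplicates merged
  after rounding (configurable). The endpoints follow the standard
  recommendation; the count is a resolution/noise compromise — more
  points change `α̂` only marginally since the fit is a regression over a
  smooth curve.
- **Remainder epochs**: the trailing `T mod n` epochs are dropped and the
  RMS is taken over the `Bn` fitted epochs, i.e. `1/T` in the fluctuation
  formula becomes `1/(Bn)`; the textbook formula implicitly assumes
  `n | T`.
- **Within-box time covariate**: centred per box for conditioning. The
  fitted polynomial space is identical to one in the global epoch index,
  so residuals — and hence `F(n)` — are unchanged.
- **Logs**: natural; the slope is base-invariant.
- **Detrend order**: `l = 1` by default, `l = 2` available; on simulated
  ensembles the two exponents are highly correlated (|r| > 0.8, tested),
  and orders above 2 add nothing for these signals.
- **Zero fluctuations**: `F(n) = 0` (piecewise perfectly polynomial
  records) is excluded from the log–log fit with a warning; fewer than 3
  usable points is an error.

Benchmarks: `α ≈ 0.5` for iid noise, `≈ 1.0` for 1/f (pink) noise,
`≈ 1.5` for a random walk; `(0, 1)` stationary, `(1, 2)` non-stationary.
Estimates outside (0, 2) are returned with a warning and a validity flag.

The activity balance index is the exact transform
`ABI(α̂) = exp(−|α̂ − 1| / exp(−2))`: symmetric about the fractal point
α = 1, strictly decreasing in `|α̂ − 1|`, equal to 1 at α̂ = 1 and to
`exp(−e²) ≈ 0.0006` at the range extremes. It is defined for any finite
input; out-of-range α̂ is flagged upstream, not here.

DFA consumes the acceleration series directly (no thresholding); epoch
length matters — coarser epochs smooth the signal and push `α̂` and ABI
towards 1.

## Synthetic generators

All generators use numpy's PCG64 (`default_rng`) and are byte-reproducible
given a seed; the CLI records the algorithm, parameters and seed in a
metadata sidecar.

- `gen_ar1` — stationary Gaussian AR(1), initialised from the stationary
  law. Returns the raw draw plus a [0,1]-clipped copy; clipping perturbs
  the autocorrelation wherever the path leaves the unit interval, so
  recovery tests use the raw series.
- `gen_markov_states` — first-order two-state chain started from its
  stationary distribution; bout lengths are geometric, which is exactly
  the regime where the s = 1 ML estimator is the right tool.
- `gen_colored_noise` — spectral synthesis of `1/f^β` Gaussian noise with
  `β = 2α_target − 1`, shifted by its minimum and rescaled to a
  non-negative milli-g range (affine, so the exponent is untouched).
- `gen_random_walk` — cumulative sum of iid Gaussian steps, the α = 1.5
  benchmark, likewise shifted/rescaled.
- `gen_daily_profile` — a square-wave week: 16 h wake at 80 mg, 8 h sleep
  at 20 mg, iid Gaussian noise (SD 20 mg) clipped at zero, with matching
  alternating wake/sleep annotations. These levels keep day epochs mostly
  above and night epochs mostly below the 40 mg cut-point while producing
  occasional sedentary bouts by day and brief movements by night, so all
  four windowed TPs are informative.

What the generators do **not** emulate: non-wear and missing data, posture
and behaviour structure (commutes, naps, weekend effects), heteroscedastic
device noise, inter-subject variability in wake timing, and the serial
dependence of real within-state acceleration. Passing recovery tests
therefore demonstrates estimator correctness under each metric's stated
model, not robustness to real-world artefacts; the thresholding, windowing
and censoring logic is exercised end-to-end, but real cohort distributions
of the metrics are outside what synthetic data can certify.

## Problem sizes used in tests

Recovery tests use week-scale records (`T = 10 080` epochs) with 20 seeds
for DFA benchmarks and 100 seeds for Markov recovery, and long hourly
records (`P = 16 800`, 50 seeds per φ) for the asymptotic IV bound —
large enough that Monte-Carlo error is a small fraction of each
tolerance, small enough that the full suite runs in seconds. IS bounds
are checked over 1 000 random series of varied shape (uniform, binary,
noisy-sinusoid) and dimensions (`D ∈ [2,8)`, `H ∈ [2,25)`).

## Known limitations

- The package assumes complete records; it has no imputation or non-wear
  masking, and refuses partial hours/days for `z`-based metrics.
- Windowed TPs share one λ across labels; per-label priors are not
  exposed.
- The AR(1) `φ̂` is a diagnostic, not a full time-series fit: no seasonal
  terms, no standard errors beyond the OLS slope's.
- DFA box sizes are non-overlapping (no sliding windows) and multifractal
  extensions are out of scope.
- The s > 1 ML estimator applies the last-state censoring indicator
  unconditionally, as defined; when the final bout is shorter than `s`
  this arguably over-corrects by one count. The effect vanishes for long
  records and the s = 1 default is unaffected.
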