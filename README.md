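# fragmetrics

Rest–activity fragmentation metrics from epoch-level wrist accelerometry.

Circadian epidemiology increasingly summarises a week of free-living
accelerometer wear as a handful of per-subject rhythm-fragmentation
metrics. `fragmetrics` computes the full panel from three derived time
series — per-epoch acceleration magnitude `x` (milli-g), the thresholded
binary rest/active state sequence `y` (active iff `x > δ_y`, default
δ_y = 40 mg), and the per-hour active proportion `z` over `D` days of `H`
hours:

- **Inter-daily stability**
  `IS(z) = P Σ_h (z̄_h − z̄)² / (H Σ_p (z_p − z̄)²) ∈ [0, 1]` — how constant
  the 24-h profile is across days (1 = identical days).
- **Intradaily variability**
  `IV(z) = P Σ_{p≥2} (z_p − z_{p−1})² / ((P−1) Σ_p (z_p − z̄)²)` — hour-to-hour
  fragmentation; under a stationary AR(1) model with lag-1 autocorrelation
  `φ ≥ 0`, IV → 2(1 − φ), so values near 0 are smooth rhythms, near 2
  uncorrelated noise, and above 2 an ultradian pattern (flagged, never
  clipped). The fitted `φ̂` is reported as a diagnostic.
- **Transition probabilities** between rest and activity, from the bout
  (run-length) decomposition with a censoring correction for the
  unobserved end of the final bout: maximum-likelihood
  `π̂_ra(1) = (n_r − I(y_T=r)) / (T_r − I(y_T=r))`, the Beta-Binomial
  Bayesian estimator `(n_r − I(y_T=r) + λ) / (T_r − I(y_T=r) + λ)` (always
  defined for λ > 0), and the reciprocal-average-duration heuristic
  `RAD_r = n_r / T_r`. The Bayesian estimator is also computed separately
  over wake and sleep windows (`TP_{ra,w}`, `TP_{ra,s}`, `TP_{ar,w}`,
  `TP_{ar,s}`), with bouts cut at window boundaries treated as censored.
- **DFA self-similarity exponent** `α̂`: integrate the mean-centred
  acceleration, remove per-box polynomial trends over log-spaced box sizes
  `n ∈ [4, T/4]`, and regress `log F(n)` on `log n`. α = 0.5 is white
  noise, 1 pink/fractal noise, 1.5 a random walk.
- **Activity balance index** `ABI(α̂) = exp(−|α̂ − 1| / exp(−2)) ∈ (0, 1]` —
  distance of the motion signal from the fractal balance point on an
  interpretable scale (1 = perfectly balanced, ~0.0006 at α̂ = 0 or 2).

All estimators are validated against synthetic generators with known ground
truth (AR(1), two-state Markov chains, spectrally synthesised 1/f^β noise,
random walks, square-wave daily profiles), so no external dataset is
needed.

## Worked example

The 15-epoch state sequence `y = (a,a,a,r,r,a,r,a,a,a,r,r,a,r,r)`:

```python
from fragmetrics import StateSeries, extract_bouts, ml_tp, bayes_tp, rad

b = extract_bouts(StateSeries.from_symbols(list("aaarraraaarrarr")))
# rest bouts [2, 1, 2, 2], activity bouts [3, 1, 3, 1], ends in rest
print(rad(b, "ra").value)        # 4/7  = 0.57
print(ml_tp(b, "ra", 1).value)   # 3/6  = 0.50
print(bayes_tp(b, "ra", 0.5).value)  # 3.5/6.5 = 0.54
```

The record ends mid-rest-bout, so its final transition is unobserved: the
ML estimator counts 3 rest→active transitions in 6 opportunities (0.50),
while RAD inflates this to 4/7 ≈ 0.57 by implicitly counting the censored
bout end as a transition. The λ = 0.5 Bayesian estimate shrinks gently to
3.5/6.5 ≈ 0.54 and stays defined even when a state is never observed.

A full week-long panel on a synthetic subject:

```python
from fragmetrics import RestActivityModel
from fragmetrics.simulate import gen_daily_profile

x, windows = gen_daily_profile(7, seed=1, subject_id="demo")
results = RestActivityModel(x, windows=windows, subject_id="demo").fit()
print(results.summary())
```

```
Rest-activity fragmentation summary
====================================================
subject                       demo
epochs                        10080
ultradian flag                False
----------------------------------------------------
Inter-daily stability (IS)    0.9934
Intradaily variability (IV)   0.3780
AR(1) autocorrelation (phi)   0.8149 (se 0.0458)
TP rest->active, ML           0.1965
TP rest->active, Bayesian     0.1967
RAD rest                      0.1968
TP active->rest, ML           0.0837
TP active->rest, Bayesian     0.0838
RAD activity                  0.0837
TP rest->active, wake         0.9674
TP rest->active, sleep        0.1542
TP active->rest, wake         0.0226
TP active->rest, sleep        0.8689
DFA self-similarity (alpha)   1.1008 (se 0.0318)
Activity balance index (ABI)  0.4747
====================================================
```

The simulated subject repeats a near-identical square-wave day (IS ≈ 0.99,
IV ≈ 0.38, φ̂ ≈ 0.81), rarely stops moving during the day
(TP active→rest, wake ≈ 0.02) and rarely moves for long at night
(TP active→rest, sleep ≈ 0.87). Its motion signal is slightly smoother
than fractal (α̂ ≈ 1.10), giving ABI ≈ 0.47.

`results.to_frame()` returns the panel as a one-row DataFrame, and
`results.plot_fluctuation()` draws the DFA log–log diagnostic.

## Command line

```bash
fragmetrics simulate --kind daily-profile --n-days 7 --seed 1 --out-dir sim/
fragmetrics compute --epochs sim/epochs.csv --windows sim/windows.csv --out summary.csv
fragmetrics dfa-diag --epochs sim/epochs.csv --out fn_table.csv
```

`compute` writes one row per subject plus a JSON sidecar echoing the
configuration; per-subject failures are logged without aborting the batch.
CSV formats are documented in `fragmetrics.io`.

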