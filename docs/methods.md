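# Methods

## Scope and model

`berksim` studies the third component of exposure measurement error in
time-series air-pollution epidemiology: the difference between measured and
true *ambient* concentrations, arising from instrument imprecision and
spatial variability across a metropolitan monitoring network. Error is
treated as multiplicative — additive on the log scale — because daily
ambient concentrations are approximately lognormal; adding error on the log
scale keeps simulated series lognormal and strictly positive.

The analysis has four stages.

1. **Error budget (semivariance).** Between-monitor Pearson correlations R
   of log concentrations are converted to scaled semivariances
   γ′ = (1 − R)/(1 + R). An exponential semivariogram with sill fixed at 1,
   γ′(h) = nugget + (1 − nugget)(1 − e^(−3h/range)), is fit by least squares
   (range only; the nugget comes from collocated instruments). Evaluating it
   at tract-centroid distances and averaging with population weights gives
   γ̄′ and R̄ = (1 − γ̄′)/(1 + γ̄′).
2. **Error injection (Monte Carlo).** χ = s (χ* + ε)/√(1 + σ_err²) with
   ε = σ_err N, σ_err = √(1/R̄ − 1). The single formula interpolates the
   classical-like endpoint χ = χ* + ε (s = √(1+σ_err²)) and the Berkson-like
   endpoint χ = (χ* + ε)/(1+σ_err²) (s = 1/√(1+σ_err²)) while holding
   R(lnZ, lnZ*) = 1/√(1+σ_err²) = √R̄ fixed for every s. The literature
   defines the two endpoints only; this interpolation is the package's own
   construction of the intermediate types and is what the continuum sweep
   varies.
3. **Health model.** Quasi-Poisson GLM (log link, SEs scaled by
   √(Pearson χ²/df)) of daily counts on the lag-0 exposure plus optional
   confounder design. Sets of draws are aggregated by averaging β, SE, z and
   IQR; the scenario p-value is the two-sided normal tail of the mean z and
   intervals use the mean asymptotic SE.
4. **Attenuation.** Observed: 100 (RR* − RR)/(RR* − 1) per unit and per
   IQR, per draw against the error-free fit (and, as an alternative summary,
   from the draw-averaged RR — both are reported, since either convention is
   defensible for a scenario mean). Predicted: from the raw-scale slope
   m = Cov(Z − Z*, Z)/Var(Z) = 1 − Cov(Z*, Z)/Var(Z), as ≈100 m per unit and
   ≈100 [1 − (1 − m) IQR_Z/IQR_Z*] per IQR, a first-order result valid for
   RR near 1 and no confounding. m and the IQR ratio are computed per draw
   and averaged, so predicted and observed values share Monte Carlo draws.

## Key parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `gamma_bar` / `r_bar` | — | unitless | population-weighted error budget of a pollutant |
| `sigma_err` | derived | log-units | daily SD of injected log-scale error, √(1/R̄ − 1) |
| `s_ratio` | endpoint value | unitless | σ_lnZ/σ_lnZ*, indexes error type in [1/√(1+σ²), √(1+σ²)] |
| `n_sims` | 1000 | draws | Monte Carlo set size per scenario |
| `window` | 3 | days | running-average window of the noise (lag-k autocorrelation (w−k)/w) |
| `nugget` | 0.05 | unitless | h→0 share of scaled semivariance (instrument error) |
| `spatial_range_km` | 50 | km | distance at which γ′ reaches ~95% of the sill |
| `within_tract_distance` | 1.0 | km | distance used for same-tract resident pairs |
| `min_overlap` | 365 | days | minimum common days for a monitor-pair correlation |
| `alpha` | ln 76 | log-counts | baseline daily count (~76/day ≈ 166,950 visits / 2,192 days) |
| `beta_true` | ln 1.0139 | per unit | generating log risk ratio |

## The synthetic world

The generator emulates what the real study drew from monitoring networks,
the census and hospital records:

* **Monitor fields.** Log concentrations are Gaussian with configurable
  mean/SD (defaults 0.2/0.6, making a CO-like series with raw IQR ≈ 1 ppm),
  temporally smoothed by the same running-average device as the noise model,
  and cross-site correlated according to C(h) = (1 − γ′(h))/(1 + γ′(h)) for
  the generating semivariogram — so a collocated pair's sample scaled
  semivariance equals the nugget and the semivariance stage recovers the
  generating nugget and range (verified to within 20% at 10 sites × 2,192
  days). The correlation transform of a valid variogram need not be exactly
  positive semidefinite for every site layout; the matrix is projected to
  the nearest unit-diagonal PSD matrix (eigenvalue clipping) before the
  Cholesky draw.
* **Tracts.** Centroids uniform over the study extent (default 80 km,
  metropolitan scale); populations lognormal with median 4,000 and σ = 0.5,
  a plausible urban census-tract size distribution. The within-tract
  distance defaults to 1 km (typical tract diameter scale); no published
  value exists for this scalar, and γ̄′ is insensitive to it whenever
  between-tract pairs dominate the weight.
* **Confounders and counts.** Day-of-week and season indicators, sinusoidal
  temperature with AR(1) noise, dew point tracking temperature, and a day
  index; counts are Poisson from the log-linear model (optionally
  gamma-Poisson with target Pearson dispersion, to exercise the
  overdispersion scaling).

What it does **not** emulate: real monitor siting and network density,
pollutant-specific seasonality and cross-pollutant correlation, missing-data
patterns beyond simple random dropout, population clustering, or
harvesting/lag structure in the outcome. Passing tests therefore demonstrate
that the method behaves as the theory predicts under its own assumptions —
not that any particular real dataset satisfies those assumptions.

## Numerical choices

* Population (ddof = 0) SD throughout normalization, so the standardized
  series has mean 0 and SD 1 exactly and normalize/denormalize round-trips
  at machine precision.
* The noise stream is centred to zero sample mean before scaling, making the
  simulated log mean equal the base log mean exactly (not just in
  expectation); the running average is rescaled by √window so σ_err keeps
  its meaning as the marginal error SD.
* Per-draw RNGs are spawned from one scenario `SeedSequence`, so any single
  draw is reproducible without regenerating the set; pipeline stages derive
  their seeds the same way from one master seed. Scenario batteries reuse
  one scenario seed (common random numbers), so differences across error
  amounts reflect parameters rather than sampling noise.
* The semivariogram range is found by a 400-point log-grid scan over
  [10⁻³, 10⁵] km followed by bounded local refinement — the SSR surface is
  flat far from the data's distance scale and strands one-shot local
  optimisers. Fits are refused when no positive-distance pair exists or all
  pairs share a single distance (range unidentifiable).
* The scaled-semivariance/correlation conversion is validated against all
  twelve published (γ̄′, R̄) pairs to ±0.001 after rounding, the published
  rounding resolution. Note the defining normalization "semivariance of the
  difference over variance of the average" of two standardized series
  algebraically gives 2(1 − R)/(1 + R); the published table values follow
  (1 − R)/(1 + R), which is what the package implements — the factor-of-2
  discrepancy in the verbal definition is noted, not resolved.
* Pair weights in the population average are p_i + p_j over unordered pairs
  including i = j, normalized by their sum. The source description of the
  normalization is ambiguous; this choice makes γ̄′ a proper weighted mean,
  invariant to uniform population scaling and bounded by [nugget, 1].
* Degenerate inputs raise typed errors rather than returning NaN: constant
  series (normalization), R = −1 (conversion pole), constant exposure or
  collinear designs (rank check before IRLS), all-zero counts, empty
  aggregates, RR* = 1 (attenuation pole), zero-variance measurements
  (m-slope).
* Quasi-Poisson fits pass plain numpy design matrices to statsmodels GLM;
  indicator and spline bases drop one column each (and any zero-variance
  column from short calendars) to keep the design full rank alongside the
  intercept.

## Problem sizes in the shipped tests

The distributional checks of the simulation engine use the study-scale
1,000 draws on a 2,192-day series. The epidemiologic property checks use
100 draws per scenario across the twelve reference error amounts × two
types, a 9-step continuum sweep at 100 draws, and 100 seeded worlds for
coverage — sizes chosen to keep the full suite in the low minutes on a
single core while leaving Monte Carlo error well below the asserted margins
(the 1:1-concordance margin of 5 percentage points, for example, is several
times the standard error of a 100-draw scenario mean).

## Known limitations

* The analytic predictor is derived without confounders; with strong
  confounding the epidemiologic attenuation drifts from it (this drift is
  itself informative and is exercised in the tests), and predictions are
  reported but not asserted against confounded fits.
* Single pollutant, single city, lag 0: no distributed lags, case-crossover
  designs, multi-pollutant error correlation, or hierarchical pooling.
* No error *correction* (regression calibration, SIMEX) — the package
  quantifies and predicts bias, it does not undo it.
* Estimating the actual error type of a real network is out of scope; the
  continuum sweep brackets the possibilities between the B and C endpoints.
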