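# berksim

Measurement-error impact analysis for air-pollution time-series
epidemiology: quantify how much combined instrument-imprecision and
spatial-variability error an ambient pollutant carries, inject that error
into an exposure series as *multiplicative* (log-additive) noise anywhere on
the Berkson-to-classical continuum, and measure — and analytically predict —
the resulting bias in health risk ratios.

It is written for environmental epidemiologists and exposure scientists who
use a central-monitor or population-weighted average series in Poisson
time-series studies and want to know how error amount *and error type*
move their effect estimates.

## The model

**Error amount.** For monitors k, l a distance h apart, the Pearson
correlation R of their log-concentration series defines a *scaled
semivariance* γ′ = (1 − R)/(1 + R) — 0 for perfectly correlated monitors, 1
for uncorrelated ones, unitless across pollutants. An exponential
semivariogram (sill 1, nugget from collocated instruments) fit to the
pairwise values is evaluated at census-tract distances and averaged with
population weights p_ij = p_i + p_j over all unordered tract pairs
(within-tract pairs use an average between-residence distance), giving one
number γ̄′ per pollutant, equivalently R̄ = (1 − γ̄′)/(1 + γ̄′).

**Error injection.** With χ*_t the standardized log base-case series, a
simulated series is

    χ_t = s (χ*_t + ε_t) / √(1 + σ_err²),   ε_t = σ_err N_t,

denormalized through the base case's log moments. N_t is unit-variance
noise with 3-day running-average autocorrelation; σ_err = √(1/R̄ − 1) so
that R(lnZ, lnZ*) = √R̄ for every s. The log-SD ratio
s = σ_lnZ/σ_lnZ* indexes the error type: s = √(1 + σ_err²) is classical-like
(type C: error independent of the truth, variance inflated),
s = 1/√(1 + σ_err²) is Berkson-like (type B: error independent of the
measurement, variance deflated), and everything between is an intermediate
type.

**Health model and bias.** Counts follow a quasi-Poisson log-linear model
log E[Y_t] = α + β Z_t + γ′·confounders_t (SEs scaled by the Pearson
dispersion), reported as RR = exp(β) per unit and exp(β·IQR) per
interquartile range. Bias is summarized as percent attenuation
100 (RR* − RR)/(RR* − 1) toward the null (negative = away from the null),
and predicted analytically from the slope m of the raw-scale error (Z − Z*)
on Z: ≈ 100 m per unit and ≈ 100 [1 − (1 − m) IQR_Z/IQR_Z*] per IQR.

The monitor observations and hospital records of the motivating Atlanta
study are not public, so a first-class synthetic world (lognormal monitor
fields with distance-decaying correlation, census tracts, confounders,
Poisson counts with known risk ratio ≈ 1.014 per unit and ~76 counts/day
over 2,192 days) stands in for them; published summary values ship in
`berksim.reference` as worked-example inputs.

## Worked example

```python
import berksim as bk

# error budget for a CO-like pollutant from its population-weighted semivariance
budget = bk.ErrorBudget.from_gamma_bar(0.411)
sigma = bk.sigma_err_from_r(budget.r_bar)
print(f"R_bar = {budget.r_bar:.3f}  sigma_err = {sigma:.2f}  "
      f"s_B = {bk.sd_ratio(sigma, 'B'):.2f}  s_C = {bk.sd_ratio(sigma, 'C'):.2f}")

# synthetic base case and outcome counts
world = bk.WorldConfig(n_days=2192, n_sites=1, seed=11)
base = bk.generate_monitor_field(world).series["S00"]
counts = bk.generate_health_counts(base, None, bk.HealthConfig(seed=13))
fit0 = bk.fit_quasipoisson(counts, base)
print(f"base case: RR per unit = {fit0.rr_unit:.4f} "
      f"(95% CI {fit0.rr_unit_ci[0]:.4f}-{fit0.rr_unit_ci[1]:.4f}), p = {fit0.p:.2g}")

# classical-like error at the CO error amount, 200 Monte Carlo draws
spec = bk.ErrorSpec.from_gamma_bar(0.411, type_label="C", n_sims=200, seed=42)
res = bk.run_scenario(base, counts, spec, fit_true=fit0, gamma_bar=0.411)
print(f"type C:   RR per unit = {res.agg.rr_unit:.4f}, p = {res.agg.p_from_mean_z:.3g}")
print(f"observed attenuation  = {res.att_unit.mean():.0f}% per unit, "
      f"{res.att_iqr.mean():.0f}% per IQR")
print(f"predicted attenuation = {res.pred_unit.mean():.0f}% per unit, "
      f"{res.pred_iqr.mean():.0f}% per IQR")
```

prints

```
R_bar = 0.417  sigma_err = 1.18  s_B = 0.65  s_C = 1.55
base case: RR per unit = 1.0148 (95% CI 1.0099-1.0198), p = 3.6e-09
type C:   RR per unit = 1.0037, p = 0.000884
observed attenuation  = 75% per unit, 59% per IQR
predicted attenuation = 75% per unit, 59% per IQR
```

Reading it: a CO-like amount of spatial error (γ̄′ = 0.411) corresponds to a
daily log-scale error SD of 1.18; injected as classical-like error it wipes
out three quarters of the per-unit excess risk and costs several orders of
magnitude of significance, and the regression-slope predictor reproduces the
simulated attenuation almost exactly (the base-case series, simulated here,
yields RR* = 1.0148 against a generating RR of 1.0139).

## Command line

Each stage is also a CLI command over plain CSV/YAML files:

```sh
berksim synth    --n-days 2192 --n-sites 8 --out work/          # world
berksim semivar  --monitors work/monitors.csv --sites work/sites.csv \
                 --tracts work/tracts.csv --nugget 0.05 --out budget.csv
berksim simulate --base base.csv --gamma-bar 0.411 --error-type C --out sims/
berksim epifit   --counts work/counts.csv --exposure base.csv --out fit.csv
berksim attenuate --counts work/counts.csv --base base.csv \
                  --gamma-bar 0.411 --out attenuation.csv
berksim full     --config examples/config.yaml --out results/ --plots
```

`full` runs everything from one YAML config (see `examples/config.yaml`) and
writes the error-budget, scenario risk-ratio, attenuation, 1:1-concordance
and continuum-sweep tables plus a provenance manifest; outputs are
bit-for-bit reproducible under a fixed master seed.

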