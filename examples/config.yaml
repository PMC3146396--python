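# Full-pipeline scenario configuration for `berksim full --config ...`.
# Seeds for every stage are spawned deterministically from the master seed.

seed: 1           # master seed
n_sims: 1000      # Monte Carlo draws per scenario
n_tracts: 100     # synthetic census tracts for the population weighting
min_overlap: 365  # minimum common days for a monitor pair's correlation

world:
  n_days: 2192            # 1999-01-01 .. 2004-12-31
  n_sites: 8
  extent_km: 80.0
  log_mean: 0.2           # CO-like: raw-scale IQR ~ 1 ppm
  log_sd: 0.6
  spatial_range_km: 50.0  # semivariogram range of the generating field
  nugget: 0.05            # instrument-error share at h -> 0
  temporal_corr_days: 3

health:
  alpha: 4.3307           # ln(76): ~76 outcome counts/day
  beta_true: 0.013804     # ln(1.0139): generating RR per unit
  confounder_effects:
    temperature: 0.004
    dow_sun: -0.1

# Error scenarios: one entry per error amount, each run for the listed types.
# gamma_bar is the population-weighted scaled semivariance of the pollutant
# whose error amount the scenario emulates.
errors:
  - {label: 1-hr max CO, gamma_bar: 0.411, types: [B, C]}
  - {label: 8-hr max O3, gamma_bar: 0.051, types: [B, C]}
  - {label: 1-hr max NO2, gamma_bar: 0.516, types: [B, C]}

# Error-type continuum sweep at a fixed error amount (omit to skip).
sweep:
  gamma_bar: 0.411
  n_steps: 9
  n_sims: 1000
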