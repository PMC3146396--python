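"""Reference values from the metropolitan Atlanta analysis, 1999-2004.

These are the published summary numbers for the twelve daily pollutant
metrics monitored across the 20-county Atlanta area (AQS, SEARCH and ASACA
networks) and for cardiovascular emergency-department visits over the
2,192-day period 1999-01-01 .. 2004-12-31.  They serve as worked-example
inputs: the population-weighted scaled semivariances are the per-pollutant
error budgets the simulation scenarios target, and the risk-ratio summaries
let the attenuation arithmetic be exercised on real reported numbers.  The
underlying monitor observations and visit records are not public; the
synthetic world stands in for them.
"""

from __future__ import annotations

import pandas as pd

#: Population-weighted scaled semivariance (gamma_bar) per pollutant metric.
GAMMA_BAR: dict[str, float] = {
    "1-hr max NO2": 0.516,
    "1-hr max NOx": 0.384,
    "8-hr max O3": 0.051,
    "1-hr max SO2": 0.517,
    "1-hr max CO": 0.411,
    "24-hr PM10": 0.192,
    "24-hr PM2.5": 0.100,
    "24-hr PM2.5-SO4": 0.068,
    "24-hr PM2.5-NO3": 0.140,
    "24-hr PM2.5-NH4": 0.149,
    "24-hr PM2.5-EC": 0.337,
    "24-hr PM2.5-OC": 0.175,
}

#: Base case: 1-hr max CO vs cardiovascular ED visits, per-ppm scale.
BASE_CASE = {
    "rr_unit": 1.0139,
    "rr_unit_ci": (1.0078, 1.0201),
    "p": 0.000009,
    "iqr": 1.00,
    "n_visits": 166950,
    "n_days": 2192,
}

#: Reported scenario risk ratios: (type, pollutant) -> per-unit RR, IQR, per-IQR RR, p.
_RISK_RATIO_ROWS = [
    # type, pollutant, rr_unit, iqr, rr_iqr, p
    ("C", "1-hr max NO2", 1.0011, 1.84, 1.0020, 0.0957),
    ("C", "1-hr max NOx", 1.0024, 1.51, 1.0037, 0.0251),
    ("C", "8-hr max O3", 1.0114, 1.05, 1.0120, 0.00004),
    ("C", "1-hr max SO2", 1.0011, 1.84, 1.0019, 0.0966),
    ("C", "1-hr max CO", 1.0021, 1.57, 1.0033, 0.0342),
    ("C", "24-hr PM10", 1.0063, 1.20, 1.0076, 0.0013),
    ("C", "24-hr PM2.5", 1.0094, 1.10, 1.0103, 0.000157),
    ("C", "24-hr PM2.5-SO4", 1.0107, 1.07, 1.0114, 0.000066),
    ("C", "24-hr PM2.5-NO3", 1.0079, 1.14, 1.0090, 0.00040),
    ("C", "24-hr PM2.5-NH4", 1.0076, 1.15, 1.0088, 0.00050),
    ("C", "24-hr PM2.5-EC", 1.0032, 1.42, 1.0045, 0.0140),
    ("C", "24-hr PM2.5-OC", 1.0068, 1.18, 1.0080, 0.00090),
    ("B", "1-hr max NO2", 1.0182, 0.51, 1.0092, 0.0112),
    ("B", "1-hr max NOx", 1.0169, 0.61, 1.0103, 0.0034),
    ("B", "8-hr max O3", 1.0142, 0.94, 1.0133, 0.000027),
    ("B", "1-hr max SO2", 1.0182, 0.51, 1.0092, 0.0114),
    ("B", "1-hr max CO", 1.0172, 0.59, 1.0101, 0.0044),
    ("B", "24-hr PM10", 1.0152, 0.78, 1.0117, 0.00030),
    ("B", "24-hr PM2.5", 1.0144, 0.88, 1.0127, 0.000074),
    ("B", "24-hr PM2.5-SO4", 1.0143, 0.92, 1.0130, 0.000039),
    ("B", "24-hr PM2.5-NO3", 1.0147, 0.83, 1.0122, 0.000152),
    ("B", "24-hr PM2.5-NH4", 1.0148, 0.82, 1.0121, 0.000175),
    ("B", "24-hr PM2.5-EC", 1.0165, 0.65, 1.0106, 0.0021),
    ("B", "24-hr PM2.5-OC", 1.0150, 0.79, 1.0119, 0.00030),
]

RISK_RATIOS = pd.DataFrame(
    _RISK_RATIO_ROWS, columns=["type", "pollutant", "rr_unit", "iqr", "rr_iqr", "p"]
)


def reference_error_budget_table() -> pd.DataFrame:
    """Recompute the full error-budget table from the reported gamma_bar values.

    Columns: gamma_bar, R_bar, sigma_err, and the type B / type C log-SD
    ratios, all derived through the semivariance-correlation relation and the
    error-amount calibration with unrounded intermediates.
    """
    from .semivariance import ErrorBudget, error_budget_table

    budgets = {name: ErrorBudget.from_gamma_bar(g) for name, g in GAMMA_BAR.items()}
    return error_budget_table(budgets).drop(columns=["nugget", "range_km"])
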