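"""Quasi-Poisson health model and risk-ratio reporting.

Fits log E[Y_t] = alpha + beta Z_t + gamma' confounders_t by Poisson GLM with
standard errors scaled by the Pearson dispersion (quasi-Poisson), and reports
risk ratios per unit of measurement, RR = exp(beta), and per interquartile
range, RR_IQR = exp(beta * IQR), with normal-asymptotic 95% intervals.
Simulation sets are aggregated by averaging over draws, with the p-value
taken from the average z statistic and intervals from the average asymptotic
standard error.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.stats import norm

from .exceptions import (
    AlignmentError,
    DomainError,
    FitError,
    IdentifiabilityError,
)
from .series import PollutantSeries

__all__ = [
    "EpiFit",
    "AggregatedEpi",
    "build_confounder_design",
    "fit_quasipoisson",
    "risk_ratios",
    "aggregate_fits",
]

Z95 = 1.96  # normal quantile for 95% intervals, matching asymptotic-SE convention


@dataclasses.dataclass(frozen=True)
class EpiFit:
    """Summary of one fitted health model."""

    beta: float
    se_beta: float
    dispersion: float
    z: float
    p: float
    rr_unit: float
    rr_unit_ci: tuple[float, float]
    rr_iqr: float
    rr_iqr_ci: tuple[float, float]
    iqr_used: float


@dataclasses.dataclass(frozen=True)
class AggregatedEpi:
    """Draw-averaged results for one Monte Carlo scenario.

    The p-value is the two-sided normal tail of the mean z statistic, and the
    confidence intervals use the mean asymptotic standard error.
    """

    n: int
    mean_beta: float
    sd_beta: float
    mean_se: float
    mean_z: float
    sd_z: float
    p_from_mean_z: float
    mean_iqr: float
    rr_unit: float
    rr_unit_ci: tuple[float, float]
    rr_iqr: float
    rr_iqr_ci: tuple[float, float]


def _spline_basis(x: np.ndarray, knot_spacing: float) -> np.ndarray:
    """Cubic B-spline basis with knots every ``knot_spacing`` along x."""
    lo, hi = float(x.min()), float(x.max())
    n_interior = max(int(np.floor((hi - lo) / knot_spacing)) - 1, 0)
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    basis = BSpline.design_matrix(x, t, k=3).toarray()
    return basis[:, 1:]  # drop one column: the basis sums to 1 (intercept)


def build_confounder_design(
    confounders: pd.DataFrame | None,
    knot_spacing_days: float = 30.44,
) -> pd.DataFrame | None:
    """Regression design from a confounder table.

    Mirrors the usual time-series confounder control: day-of-week and season
    indicators (one reference level dropped each), cubic polynomials in
    centred temperature and dew point, and a cubic spline with ~monthly knots
    in the day index for the long-term trend.  Columns absent from the table
    are simply skipped, so reduced tables work too.
    """
    if confounders is None:
        return None
    cols: dict[str, np.ndarray] = {}
    dow = [c for c in confounders.columns if c.startswith("dow_")]
    for c in dow[1:]:
        cols[c] = confounders[c].to_numpy(dtype=float)
    seasons = [c for c in confounders.columns if c.startswith("season_")]
    for c in seasons[1:]:
        cols[c] = confounders[c].to_numpy(dtype=float)
    for met in ("temperature", "dew_point"):
        if met in confounders.columns:
            x = confounders[met].to_numpy(dtype=float)
            xc = (x - x.mean()) / max(x.std(), 1e-12)
            for power in (1, 2, 3):
                cols[f"{met}_p{power}"] = xc**power
    if "day_index" in confounders.columns:
        basis = _spline_basis(
            confounders["day_index"].to_numpy(dtype=float), knot_spacing_days
        )
        for j in range(basis.shape[1]):
            cols[f"trend_s{j:02d}"] = basis[:, j]
    design = pd.DataFrame(cols, index=confounders.index)
    # levels absent from short study windows yield zero-variance columns
    return design.loc[:, design.std() > 0]


def risk_ratios(
    beta: float, se: float, iqr: float
) -> tuple[float, tuple[float, float], float, tuple[float, float]]:
    """RR per unit and per IQR with 95% intervals.

    RR = exp(beta), CI = exp(beta +/- 1.96 se); RR_IQR = exp(beta * IQR),
    CI = exp((beta +/- 1.96 se) * IQR).
    """
    if iqr <= 0:
        raise DomainError("IQR must be positive")
    if se < 0:
        raise DomainError("standard error must be nonnegative")
    lo, hi = beta - Z95 * se, beta + Z95 * se
    return (
        float(np.exp(beta)),
        (float(np.exp(lo)), float(np.exp(hi))),
        float(np.exp(beta * iqr)),
        (float(np.exp(lo * iqr)), float(np.exp(hi * iqr))),
    )


def fit_quasipoisson(
    counts: pd.Series,
    exposure: PollutantSeries | pd.Series,
    confounders: pd.DataFrame | None = None,
    design: pd.DataFrame | None = None,
) -> EpiFit:
    """Fit the lag-0 health model and summarise it as an :class:`EpiFit`.

    ``design`` may carry a prebuilt confounder design (reused across draws
    for speed); otherwise it is built from ``confounders``.  Standard errors
    are scaled by sqrt(Pearson chi^2 / df).
    """
    if isinstance(exposure, PollutantSeries):
        exp_values = exposure.values
        iqr = exposure.iqr
    else:
        exp_values = exposure.astype(float)
        q75, q25 = np.nanpercentile(exp_values.to_numpy(), [75, 25])
        iqr = float(q75 - q25)
    if not counts.index.equals(exp_values.index):
        raise AlignmentError("counts and exposure must share the same date index")
    y = counts.to_numpy()
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise DomainError("counts must be nonnegative integers")
    if y.sum() == 0:
        raise FitError("all counts are zero; the model is degenerate")
    if exp_values.isna().any():
        raise DomainError("exposure series has missing days")

    if design is None:
        design = build_confounder_design(confounders)
    n = len(y)
    if design is not None:
        if not design.index.equals(counts.index):
            raise AlignmentError("confounder design must share the counts' date index")
        X = np.column_stack(
            [np.ones(n), exp_values.to_numpy(dtype=float), design.to_numpy(dtype=float)]
        )
    else:
        X = np.column_stack([np.ones(n), exp_values.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise IdentifiabilityError(
            "design matrix is rank deficient (constant exposure or collinear confounders)"
        )
    try:
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit(scale="X2")
    except Exception as exc:  # statsmodels raises various convergence errors
        raise FitError(f"quasi-Poisson fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError("quasi-Poisson fit produced non-finite coefficients")
    beta = float(res.params[1])
    se = float(res.bse[1])
    dispersion = float(res.scale)
    z = beta / se if se > 0 else np.inf
    p = float(max(2.0 * norm.sf(abs(z)), np.nextafter(0, 1)))
    rr_unit, rr_unit_ci, rr_iqr, rr_iqr_ci = risk_ratios(beta, se, iqr)
    return EpiFit(
        beta=beta,
        se_beta=se,
        dispersion=dispersion,
        z=float(z),
        p=p,
        rr_unit=rr_unit,
        rr_unit_ci=rr_unit_ci,
        rr_iqr=rr_iqr,
        rr_iqr_ci=rr_iqr_ci,
        iqr_used=float(iqr),
    )


def aggregate_fits(fits: list[EpiFit]) -> AggregatedEpi:
    """Average a set of per-draw fits into one scenario summary."""
    if not fits:
        raise DomainError("cannot aggregate an empty list of fits")
    betas = np.array([f.beta for f in fits])
    ses = np.array([f.se_beta for f in fits])
    zs = np.array([f.z for f in fits])
    iqrs = np.array([f.iqr_used for f in fits])
    mean_beta = float(betas.mean())
    mean_se = float(ses.mean())
    mean_z = float(zs.mean())
    mean_iqr = float(iqrs.mean())
    p = float(max(2.0 * norm.sf(abs(mean_z)), np.nextafter(0, 1)))
    rr_unit, rr_unit_ci, rr_iqr, rr_iqr_ci = risk_ratios(mean_beta, mean_se, mean_iqr)
    many = len(fits) > 1
    return AggregatedEpi(
        n=len(fits),
        mean_beta=mean_beta,
        sd_beta=float(betas.std(ddof=1)) if many else 0.0,
        mean_se=mean_se,
        mean_z=mean_z,
        sd_z=float(zs.std(ddof=1)) if many else 0.0,
        p_from_mean_z=p,
        mean_iqr=mean_iqr,
        rr_unit=rr_unit,
        rr_unit_ci=rr_unit_ci,
        rr_iqr=rr_iqr,
        rr_iqr_ci=rr_iqr_ci,
    )
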