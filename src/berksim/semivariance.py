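"""Population-weighted scaled semivariance: the per-pollutant error budget.

The amount of combined instrument-imprecision and spatial-variability error
in an ambient pollutant is summarised by a *scaled semivariance* gamma'
computed from between-monitor correlations of log concentrations,

    gamma'(R) = (1 - R) / (1 + R),

which is 0 for perfectly correlated monitors and 1 for uncorrelated ones and
is unitless, so it can be compared across pollutants.  A semivariogram model
(sill fixed at 1, nugget supplied from collocated-instrument analysis,
exponential distance decay) is fit to the pairwise values by least squares,
evaluated at the distances between census-tract centroids, and averaged with
population weights to give a single number gamma_bar per pollutant.  The
equivalent population-weighted correlation is the exact inverse

    R_bar = (1 - gamma_bar) / (1 + gamma_bar).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform

from .exceptions import AnalysisError, DomainError, FitError, IllPosedFitError
from .series import MonitorField

logger = logging.getLogger(__name__)

__all__ = [
    "PairCorrelation",
    "SemivariogramFit",
    "ErrorBudget",
    "scaled_semivariance_from_r",
    "correlation_from_semivariance",
    "pairwise_log_correlations",
    "fit_semivariogram",
    "population_weighted_semivariance",
]


def scaled_semivariance_from_r(r):
    """Scaled semivariance gamma' = (1 - R)/(1 + R) of a monitor-pair correlation.

    Accepts a scalar or array with entries in (-1, 1]; R = -1 is a pole and
    raises :class:`DomainError`.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= -1.0) or np.any(arr > 1.0):
        raise DomainError("correlation must lie in (-1, 1]")
    out = (1.0 - arr) / (1.0 + arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def correlation_from_semivariance(gamma):
    """Population-weighted correlation R_bar = (1 - gamma')/(1 + gamma').

    Exact inverse of :func:`scaled_semivariance_from_r`.  A population-
    weighted average lies in [0, 1] (R_bar in [0, 1]); individual pair values
    above 1 (anticorrelated monitors) are accepted and map to negative R.
    """
    arr = np.asarray(gamma, dtype=float)
    if np.any(arr < 0.0):
        raise DomainError("scaled semivariance must be nonnegative")
    out = (1.0 - arr) / (1.0 + arr)
    return float(out) if np.isscalar(gamma) or arr.ndim == 0 else out


@dataclasses.dataclass(frozen=True)
class PairCorrelation:
    """Correlation between one unordered pair of monitors."""

    site_a: str
    site_b: str
    distance_km: float
    r: float
    n_overlap: int


@dataclasses.dataclass(frozen=True)
class SemivariogramFit:
    """Exponential scaled-semivariogram model with sill fixed at 1.

    gamma'(h) = nugget + (1 - nugget) * (1 - exp(-3 h / range_km)),
    so gamma' reaches ~95% of the sill at h = range_km.  The nugget is the
    site-level (h -> 0) share of the scaled semivariance attributable to
    instrument imprecision; it comes from collocated-instrument analysis (or
    from generator truth in synthetic studies), not from this fit.
    """

    nugget: float
    range_km: float
    sill: float = 1.0
    form: str = "exponential"

    def __post_init__(self) -> None:
        if not 0.0 <= self.nugget <= self.sill:
            raise DomainError("nugget must lie in [0, sill]")
        if self.range_km <= 0:
            raise DomainError("range must be positive")
        if self.sill != 1.0:
            raise DomainError("the scaled semivariogram uses a sill of exactly 1")

    def gamma(self, h):
        """Model scaled semivariance at distance(s) h (km)."""
        h = np.asarray(h, dtype=float)
        out = self.nugget + (self.sill - self.nugget) * (1.0 - np.exp(-3.0 * h / self.range_km))
        return float(out) if out.ndim == 0 else out

    __call__ = gamma


@dataclasses.dataclass(frozen=True)
class ErrorBudget:
    """The error budget of one pollutant: gamma_bar and its correlation form."""

    gamma_bar: float
    r_bar: float
    nugget: float | None = None
    range_km: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_bar <= 1.0:
            raise DomainError("gamma_bar must lie in [0, 1]")
        expected = correlation_from_semivariance(self.gamma_bar)
        if abs(self.r_bar - expected) > 1e-9:
            raise DomainError("r_bar is not consistent with gamma_bar")

    @classmethod
    def from_gamma_bar(cls, gamma_bar: float, **kw) -> "ErrorBudget":
        return cls(gamma_bar=float(gamma_bar),
                   r_bar=correlation_from_semivariance(gamma_bar), **kw)

    @classmethod
    def from_r_bar(cls, r_bar: float, **kw) -> "ErrorBudget":
        return cls(gamma_bar=scaled_semivariance_from_r(r_bar), r_bar=float(r_bar), **kw)


def pairwise_log_correlations(
    field: MonitorField, min_overlap: int = 365
) -> list[PairCorrelation]:
    """Pearson correlations of normalized log series for all monitor pairs.

    Pairs with fewer than ``min_overlap`` common non-missing days are dropped
    with a warning; if every pair is dropped an :class:`AnalysisError` is
    raised.  Correlations are computed on the log scale (normalization does
    not change a Pearson correlation, so log values are used directly);
    distances are Euclidean in km from the site coordinates.
    """
    if field.n_sites < 2:
        raise AnalysisError("need at least two sites for pairwise correlations")
    out: list[PairCorrelation] = []
    logs = {sid: np.log(s.values.to_numpy()) for sid, s in field}
    for a, b in itertools.combinations(field.site_ids, 2):
        la, lb = logs[a], logs[b]
        mask = np.isfinite(la) & np.isfinite(lb)
        n = int(mask.sum())
        if n < min_overlap:
            logger.warning(
                "dropping pair (%s, %s): %d overlapping days < %d", a, b, n, min_overlap
            )
            continue
        xa, xb = la[mask], lb[mask]
        if xa.std() == 0 or xb.std() == 0:
            logger.warning("dropping pair (%s, %s): a series is constant", a, b)
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        out.append(PairCorrelation(a, b, field.distance(a, b), r, n))
    if not out:
        raise AnalysisError("all monitor pairs were dropped (insufficient overlap)")
    return out


def fit_semivariogram(
    pairs: list[PairCorrelation], nugget: float
) -> SemivariogramFit:
    """Least-squares fit of the exponential scaled semivariogram range.

    The sill is fixed at 1 and the nugget is supplied externally; only the
    range is estimated, by minimising the sum of squared residuals between
    the model and the pairwise scaled semivariances gamma'(R).
    """
    if not pairs:
        raise FitError("no pairs to fit")
    h = np.array([p.distance_km for p in pairs], dtype=float)
    g = scaled_semivariance_from_r(np.array([p.r for p in pairs], dtype=float))
    if not np.any(h > 0):
        raise FitError("no positive-distance pairs; range is not estimable")
    if np.unique(np.round(h, 9)).size < 2:
        raise IllPosedFitError(
            "all pairs lie at a single distance; the range is unidentifiable"
        )

    def ssr(log_range: float) -> float:
        model = nugget + (1.0 - nugget) * (1.0 - np.exp(-3.0 * h / np.exp(log_range)))
        return float(np.sum((model - g) ** 2))

    # the SSR surface is flat far from the data's distance scale, which can
    # strand a local optimiser: scan a log grid first, then refine locally
    grid = np.linspace(np.log(1e-3), np.log(1e5), 400)
    values = np.array([ssr(x) for x in grid])
    i = int(values.argmin())
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(ssr, bounds=(lo, hi), method="bounded")
    if not res.success:
        raise FitError(f"semivariogram range optimisation failed: {res.message}")
    return SemivariogramFit(nugget=float(nugget), range_km=float(np.exp(res.x)))


def population_weighted_semivariance(fit, tracts) -> ErrorBudget:
    """Average the semivariogram over all tract pairs with population weights.

    gamma_bar = sum_{i<=j} p_ij * gamma'(h_ij) / sum_{i<=j} p_ij with
    p_ij = p_i + p_j over all unordered tract pairs including i = j, where
    h_ij is the distance between tract centroids and h_ii is the average
    within-tract distance between residences.  ``fit`` is any object with a
    vectorised ``gamma(h)`` method (normally a :class:`SemivariogramFit`).
    """
    table = tracts.table
    if table.empty:
        raise AnalysisError("tract table is empty")
    pop = table["population"].to_numpy(dtype=float)
    if pop.sum() <= 0:
        raise AnalysisError("total tract population must be positive")
    xy = table[["x_km", "y_km"]].to_numpy(dtype=float)
    n = len(table)
    if n == 1:
        d = np.array([[tracts.within_tract_distance]])
    else:
        d = squareform(pdist(xy))
        np.fill_diagonal(d, tracts.within_tract_distance)
    iu = np.triu_indices(n)
    w = (pop[:, None] + pop[None, :])[iu]
    g = np.asarray(fit.gamma(d[iu]), dtype=float)
    gamma_bar = float(np.sum(w * g) / np.sum(w))
    gamma_bar = min(max(gamma_bar, 0.0), 1.0)
    nug = getattr(fit, "nugget", None)
    rng = getattr(fit, "range_km", None)
    return ErrorBudget.from_gamma_bar(gamma_bar, nugget=nug, range_km=rng)


def error_budget_table(budgets: dict[str, ErrorBudget]) -> pd.DataFrame:
    """Tabulate budgets (one row per pollutant) in the standard report shape."""
    from .error_model import sd_ratio, sigma_err_from_r

    rows = []
    for name, b in budgets.items():
        sigma = sigma_err_from_r(b.r_bar)
        rows.append(
            {
                "pollutant": name,
                "gamma_bar": b.gamma_bar,
                "r_bar": b.r_bar,
                "sigma_err": sigma,
                "sd_ratio_type_B": sd_ratio(sigma, "B"),
                "sd_ratio_type_C": sd_ratio(sigma, "C"),
                "nugget": b.nugget,
                "range_km": b.range_km,
            }
        )
    return pd.DataFrame(rows)
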