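"""Synthetic study world: monitor network, census tracts, confounders, counts.

Emulates the inputs a real time-series study obtains from ambient monitoring
networks, the census, and hospital records, with the statistical structure
the downstream analysis assumes:

* daily pollutant concentrations lognormal, with short-term temporal
  autocorrelation and between-monitor correlation decaying with distance;
* tract centroids with populations for the population weighting;
* daily outcome counts drawn from a known log-linear risk model, so the
  generating risk ratio is available as ground truth.

The spatial structure is parameterised directly by the exponential scaled
semivariogram gamma'(h) = nugget + (1-nugget)(1 - exp(-3h/range)); the
cross-site correlation of log concentrations is its correlation transform
C(h) = (1 - gamma'(h))/(1 + gamma'(h)), so the semivariance stage applied to
a generated field recovers the generating nugget and range.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, AnalysisError, ConfigurationError
from .semivariance import SemivariogramFit
from .series import MonitorField, PollutantSeries

__all__ = [
    "WorldConfig",
    "TractTable",
    "HealthConfig",
    "study_dates",
    "generate_monitor_field",
    "generate_tracts",
    "generate_confounders",
    "generate_health_counts",
]

#: First day of the emulated study period.
DEFAULT_START = "1999-01-01"
#: Days in the six-year study period 1999-01-01 .. 2004-12-31.
DEFAULT_N_DAYS = 2192


def study_dates(n_days: int = DEFAULT_N_DAYS, start: str = DEFAULT_START) -> pd.DatetimeIndex:
    """Daily date index of the study period."""
    return pd.date_range(start, periods=n_days, freq="D")


@dataclasses.dataclass(frozen=True)
class WorldConfig:
    """Generator settings for the synthetic monitor field.

    ``log_mean``/``log_sd`` are the mean and SD of the log concentrations
    (the defaults give a CO-like series whose raw-scale IQR is ~1 ppm);
    ``spatial_range_km`` and ``nugget`` parameterise the scaled semivariogram
    of the generating field; ``temporal_corr_days`` is the running-average
    window producing day-to-day autocorrelation.
    """

    n_days: int = DEFAULT_N_DAYS
    n_sites: int = 8
    site_coords: Sequence[tuple[float, float]] | None = None
    extent_km: float = 80.0
    log_mean: float = 0.2
    log_sd: float = 0.6
    spatial_range_km: float = 50.0
    nugget: float = 0.05
    temporal_corr_days: int = 3
    missing_frac: float = 0.0
    pollutant: str = "1-hr max CO"
    start: str = DEFAULT_START
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 30:
            raise ConfigurationError("n_days must be at least 30")
        if self.log_sd <= 0:
            raise ConfigurationError("log_sd must be positive")
        if not 0.0 <= self.nugget < 1.0:
            raise ConfigurationError("nugget must lie in [0, 1)")
        if self.temporal_corr_days < 1:
            raise ConfigurationError("temporal_corr_days must be at least 1")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ConfigurationError("missing_frac must lie in [0, 1)")
        if self.site_coords is not None:
            arr = np.asarray(self.site_coords, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or not np.isfinite(arr).all():
                raise ConfigurationError("site_coords must be finite 2-D points (km)")
            if len(arr) != self.n_sites:
                object.__setattr__(self, "n_sites", len(arr))
        if self.n_sites < 1:
            raise ConfigurationError("need at least one site")


def _site_correlation(config: WorldConfig, coords: np.ndarray) -> np.ndarray:
    """Cross-site correlation of log series implied by the semivariogram."""
    from scipy.spatial.distance import pdist, squareform

    n = len(coords)
    if n == 1:
        return np.ones((1, 1))
    fit = SemivariogramFit(nugget=config.nugget, range_km=config.spatial_range_km)
    d = squareform(pdist(coords))
    gamma = fit.gamma(d)
    corr = (1.0 - gamma) / (1.0 + gamma)
    np.fill_diagonal(corr, 1.0)
    # project to the nearest PSD matrix with unit diagonal (the correlation
    # transform of a valid variogram need not be exactly PSD for every layout)
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        corr = (v * w) @ v.T
        scale = np.sqrt(np.diag(corr))
        corr = corr / np.outer(scale, scale)
    return corr


def generate_monitor_field(config: WorldConfig) -> MonitorField:
    """Draw a lognormal monitor field with the configured spatio-temporal structure.

    Each site's log series is marginally N(log_mean, log_sd^2) with lag-1
    autocorrelation (w-1)/w from the running-average window w; cross-site
    correlation follows the generating semivariogram.
    """
    rng = np.random.default_rng(config.seed)
    if config.site_coords is not None:
        coords = np.asarray(config.site_coords, dtype=float)
    else:
        coords = rng.uniform(0.0, config.extent_km, size=(config.n_sites, 2))
    corr = _site_correlation(config, coords)
    chol = np.linalg.cholesky(corr)
    w = config.temporal_corr_days
    raw = rng.standard_normal((config.n_days + w - 1, len(coords)))
    correlated = raw @ chol.T
    kernel = np.full(w, 1.0 / w)
    smoothed = np.apply_along_axis(
        lambda col: np.convolve(col, kernel, mode="valid"), 0, correlated
    ) * np.sqrt(w)
    logs = config.log_mean + config.log_sd * smoothed
    dates = study_dates(config.n_days, config.start)
    series: dict[str, PollutantSeries] = {}
    for j in range(len(coords)):
        vals = np.exp(logs[:, j])
        if config.missing_frac > 0:
            drop = rng.random(config.n_days) < config.missing_frac
            vals = np.where(drop, np.nan, vals)
        series[f"S{j:02d}"] = PollutantSeries(
            pd.Series(vals, index=dates), config.pollutant
        )
    coord_df = pd.DataFrame(
        coords, columns=["x_km", "y_km"], index=[f"S{j:02d}" for j in range(len(coords))]
    )
    return MonitorField(series=series, coords=coord_df)


@dataclasses.dataclass(frozen=True)
class TractTable:
    """Census tracts: centroid coordinates (km) and populations.

    ``within_tract_distance`` is the single scalar distance (km) used for
    same-tract resident pairs in the population weighting.
    """

    table: pd.DataFrame
    within_tract_distance: float = 1.0

    def __post_init__(self) -> None:
        req = {"tract_id", "x_km", "y_km", "population"}
        if not req.issubset(self.table.columns):
            raise ConfigurationError(f"tract table must carry columns {sorted(req)}")
        if self.within_tract_distance < 0:
            raise ConfigurationError("within_tract_distance must be nonnegative")
        if not np.isfinite(self.table[["x_km", "y_km"]].to_numpy()).all():
            raise ConfigurationError("tract centroids must be finite")
        pop = self.table["population"]
        if (pop < 0).any():
            raise ConfigurationError("populations must be nonnegative")
        if pop.sum() <= 0:
            raise AnalysisError("total tract population must be positive")

    @property
    def total_population(self) -> int:
        return int(self.table["population"].sum())

    def __len__(self) -> int:
        return len(self.table)


def generate_tracts(
    n_tracts: int,
    extent_km: float = 80.0,
    population_law: Mapping | None = None,
    seed: int = 0,
    within_tract_distance: float = 1.0,
) -> TractTable:
    """Scatter tract centroids uniformly and draw populations.

    ``population_law`` is a mapping with a ``kind`` key: ``constant``
    (``value``), ``uniform`` (``low``, ``high``), or the default
    ``lognormal`` (``median`` 4000 people, ``sigma`` 0.5) — a plausible size
    distribution for urban census tracts.
    """
    if n_tracts < 1:
        raise ConfigurationError("n_tracts must be at least 1")
    law = dict(population_law or {"kind": "lognormal", "median": 4000, "sigma": 0.5})
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, extent_km, size=(n_tracts, 2))
    kind = law.get("kind", "lognormal")
    if kind == "constant":
        pop = np.full(n_tracts, int(law["value"]))
    elif kind == "uniform":
        pop = rng.integers(int(law["low"]), int(law["high"]) + 1, size=n_tracts)
    elif kind == "lognormal":
        pop = np.round(
            float(law.get("median", 4000))
            * np.exp(rng.normal(0.0, float(law.get("sigma", 0.5)), size=n_tracts))
        ).astype(int)
    else:
        raise ConfigurationError(f"unknown population law: {kind!r}")
    table = pd.DataFrame(
        {
            "tract_id": [f"T{i:04d}" for i in range(n_tracts)],
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "population": pop,
        }
    )
    return TractTable(table=table, within_tract_distance=within_tract_distance)


_DOW = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")
_SEASONS = ("winter", "spring", "summer", "fall")
_MONTH_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


def generate_confounders(
    n_days: int, seed: int = 0, start: str = DEFAULT_START
) -> pd.DataFrame:
    """Daily confounder table: day-of-week and season indicators, weather, time.

    Temperature (deg C) is a smooth seasonal sinusoid plus AR(1) noise; dew
    point tracks temperature with an offset and its own noise; ``day_index``
    counts days from the study start for long-term-trend smoothing.
    """
    rng = np.random.default_rng(seed)
    dates = study_dates(n_days, start)
    out = pd.DataFrame(index=dates)
    dow = dates.dayofweek
    for i, name in enumerate(_DOW):
        out[f"dow_{name}"] = (dow == i).astype(int)
    season = np.array([_MONTH_SEASON[m] for m in dates.month])
    for name in _SEASONS:
        out[f"season_{name}"] = (season == name).astype(int)
    doy = dates.dayofyear.to_numpy()
    seasonal = 16.5 + 10.5 * np.sin(2 * np.pi * (doy - 105) / 365.25)
    ar = np.empty(n_days)
    eps = rng.normal(0.0, 2.5, size=n_days)
    prev = 0.0
    for t in range(n_days):
        prev = 0.7 * prev + eps[t]
        ar[t] = prev
    out["temperature"] = seasonal + ar
    out["dew_point"] = out["temperature"] - 6.0 + rng.normal(0.0, 2.0, size=n_days)
    out["day_index"] = np.arange(n_days)
    return out


@dataclasses.dataclass(frozen=True)
class HealthConfig:
    """Generating log-linear risk model for daily outcome counts.

    ``alpha`` is the log baseline count, ``beta_true`` the log risk ratio per
    exposure unit, ``confounder_effects`` maps confounder-table column names
    to log-scale coefficients.  ``dispersion`` > 1 switches from pure Poisson
    to a gamma-Poisson (negative binomial) mixture with that approximate
    Pearson dispersion.
    """

    alpha: float = float(np.log(76.0))
    beta_true: float = float(np.log(1.0139))
    confounder_effects: Mapping[str, float] = dataclasses.field(default_factory=dict)
    dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta_true):
            raise ConfigurationError("beta_true must be finite")
        base = np.exp(self.alpha)
        if not 0.0 < base < 1e6:
            raise ConfigurationError("exp(alpha) must lie in (0, 1e6)")
        if self.dispersion < 1.0:
            raise ConfigurationError("dispersion must be >= 1")


def generate_health_counts(
    truth: PollutantSeries,
    confounders: pd.DataFrame | None,
    hc: HealthConfig,
) -> pd.Series:
    """Draw daily counts from log E[Y_t] = alpha + beta Z*_t + gamma' confounders_t."""
    if not truth.is_complete:
        raise AlignmentError("truth series must be complete to generate counts")
    log_mu = hc.alpha + hc.beta_true * truth.values.to_numpy()
    if hc.confounder_effects:
        if confounders is None:
            raise ConfigurationError("confounder effects given but no confounder table")
        truth.align_with(confounders)
        for name, coef in hc.confounder_effects.items():
            if name not in confounders.columns:
                raise ConfigurationError(f"unknown confounder column: {name!r}")
            log_mu = log_mu + coef * confounders[name].to_numpy(dtype=float)
    elif confounders is not None:
        truth.align_with(confounders)
    mu = np.exp(log_mu)
    rng = np.random.default_rng(hc.seed)
    if hc.dispersion > 1.0:
        # gamma-Poisson mixture with Pearson dispersion ~ hc.dispersion
        k = float(mu.mean()) / (hc.dispersion - 1.0)
        mu = mu * rng.gamma(shape=k, scale=1.0 / k, size=len(mu))
    counts = rng.poisson(mu)
    return pd.Series(counts, index=truth.dates, name="count")
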