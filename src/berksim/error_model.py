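"""Monte Carlo injection of multiplicative measurement error into a series.

Error is additive on the log scale (hence multiplicative on concentrations).
Writing chi* for the standardized log base-case series, a simulated series
with error amount sigma_err and type indexed by the log-SD ratio
s = sigma_lnZ / sigma_lnZ* is

    chi = s * (chi* + eps) / sqrt(1 + sigma_err^2),      eps = sigma_err * N,

denormalized back through the base case's log mean and SD.  N is a
unit-variance noise stream with short-term temporal autocorrelation (a
rescaled 3-day running average of iid standard normals by default).  The two
named endpoints are

* type C (classical-like): s = sqrt(1 + sigma_err^2), i.e. chi = chi* + eps;
  the error is independent of the *true* series and the simulated log SD
  exceeds the true one;
* type B (Berkson-like): s = 1/sqrt(1 + sigma_err^2), i.e.
  chi = (chi* + eps)/(1 + sigma_err^2); the error is independent of the
  *simulated* series and the simulated log SD is below the true one.

Every s in between is an intermediate error type; for all of them the
population correlation R(lnZ, lnZ*) equals 1/sqrt(1 + sigma_err^2), which is
how sigma_err is calibrated from a population-weighted correlation R_bar:
R(lnZ, lnZ*) = sqrt(R_bar), hence sigma_err = sqrt(1/R_bar - 1).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateSeriesError,
    DomainError,
    SpecificationError,
)
from .series import PollutantSeries

__all__ = [
    "ErrorSpec",
    "SimulatedSeries",
    "SimulationSet",
    "normalize",
    "denormalize",
    "autocorrelated_noise",
    "sigma_err_from_r",
    "sd_ratio",
    "simulate_once",
    "simulate_set",
]


def sigma_err_from_r(r_bar: float) -> float:
    """Error amount sigma_err = sqrt(1/R_bar - 1) from a population-weighted correlation.

    Calibrated so the simulated-vs-true log correlation is sqrt(R_bar): the
    correlation between any two series carrying the same amount of
    independent error is R_bar, so each shares sqrt(R_bar) with the truth.
    """
    if not 0.0 < r_bar <= 1.0:
        raise DomainError("R_bar must lie in (0, 1]")
    return float(np.sqrt(1.0 / r_bar - 1.0))


def sd_ratio(sigma_err: float, type_label: str) -> float:
    """Log-SD ratio sigma_lnZ/sigma_lnZ* at a named error-type endpoint."""
    if sigma_err < 0:
        raise DomainError("sigma_err must be nonnegative")
    if type_label == "C":
        return float(np.sqrt(1.0 + sigma_err**2))
    if type_label == "B":
        return float(1.0 / np.sqrt(1.0 + sigma_err**2))
    raise SpecificationError(f"unknown error type label: {type_label!r}")


@dataclasses.dataclass(frozen=True)
class ErrorSpec:
    """Error budget for one simulation scenario.

    ``s_ratio`` may be omitted for the named endpoints ("C", "B"), in which
    case it is derived from ``sigma_err``; an "intermediate" spec must state
    it explicitly.  The admissible interval is
    [(1+sigma_err^2)^(-1/2), (1+sigma_err^2)^(1/2)], with type B at the lower
    and type C at the upper end.
    """

    sigma_err: float
    type_label: str = "C"
    s_ratio: float | None = None
    n_sims: int = 1000
    window: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_err < 0:
            raise SpecificationError("sigma_err must be nonnegative")
        if self.n_sims < 1:
            raise SpecificationError("n_sims must be at least 1")
        if self.window < 1:
            raise SpecificationError("window must be at least 1")
        if self.s_ratio is None:
            if self.type_label not in ("C", "B"):
                raise SpecificationError(
                    "intermediate error types require an explicit s_ratio"
                )
            object.__setattr__(self, "s_ratio", sd_ratio(self.sigma_err, self.type_label))
        lo, hi = self.s_bounds
        tol = 1e-9 * max(1.0, hi)
        if not (lo - tol <= self.s_ratio <= hi + tol):
            raise SpecificationError(
                f"s_ratio {self.s_ratio:.4f} outside admissible [{lo:.4f}, {hi:.4f}]"
            )
        if self.type_label == "C" and abs(self.s_ratio - hi) > 1e-9:
            raise SpecificationError("type C requires s_ratio at the upper bound")
        if self.type_label == "B" and abs(self.s_ratio - lo) > 1e-9:
            raise SpecificationError("type B requires s_ratio at the lower bound")

    @property
    def s_bounds(self) -> tuple[float, float]:
        hi = float(np.sqrt(1.0 + self.sigma_err**2))
        return 1.0 / hi, hi

    @classmethod
    def from_gamma_bar(cls, gamma_bar: float, **kw) -> "ErrorSpec":
        """Build a spec from a population-weighted scaled semivariance."""
        from .semivariance import correlation_from_semivariance

        return cls(sigma_err=sigma_err_from_r(correlation_from_semivariance(gamma_bar)), **kw)

    @classmethod
    def from_r_bar(cls, r_bar: float, **kw) -> "ErrorSpec":
        return cls(sigma_err=sigma_err_from_r(r_bar), **kw)


def normalize(series: PollutantSeries) -> np.ndarray:
    """Standardized log series chi* = (ln Z* - mu_lnZ*) / sigma_lnZ*.

    Uses population (ddof=0) moments, so the output has mean 0 and SD 1
    exactly.  The series must be complete and non-degenerate.
    """
    if not series.is_complete:
        raise DomainError("cannot normalize a series with missing days")
    logs = series.log_values
    sd = logs.std()
    if sd == 0:
        raise DegenerateSeriesError("series is constant; log SD is zero")
    return (logs - logs.mean()) / sd


def denormalize(
    chi: np.ndarray,
    log_mean: float,
    log_sd: float,
    dates: pd.DatetimeIndex,
    pollutant: str = "pollutant",
) -> PollutantSeries:
    """Invert :func:`normalize`: Z = exp(mu + sigma * chi) on the given dates."""
    values = np.exp(log_mean + log_sd * np.asarray(chi, dtype=float))
    return PollutantSeries(pd.Series(values, index=dates), pollutant)


def autocorrelated_noise(
    n_days: int, window: int = 3, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Unit-variance noise with short-term temporal autocorrelation.

    A ``window``-day running mean of iid standard normals, rescaled by
    sqrt(window) so the marginal variance is 1; the lag-k autocorrelation is
    (window - k)/window for k < window and 0 beyond.
    """
    if window < 1:
        raise ConfigurationError("window must be at least 1")
    if window > n_days:
        raise ConfigurationError("window cannot exceed the series length")
    rng = np.random.default_rng(rng)
    raw = rng.standard_normal(n_days + window - 1)
    kernel = np.full(window, 1.0 / window)
    return np.convolve(raw, kernel, mode="valid") * np.sqrt(window)


@dataclasses.dataclass(frozen=True)
class SimulatedSeries:
    """One Monte Carlo draw of a series with error added, plus achieved stats."""

    series: PollutantSeries
    r_log: float       # achieved correlation of lnZ with lnZ*
    sd_ratio: float    # achieved sigma_lnZ / sigma_lnZ*
    iqr: float
    draw: int = 0


def simulate_once(
    base: PollutantSeries,
    spec: ErrorSpec,
    rng: np.random.Generator | int | None = None,
    draw: int = 0,
) -> SimulatedSeries:
    """Generate one simulated series with the spec's error amount and type.

    The noise stream is centred to zero sample mean before scaling, so the
    simulated log mean equals the base log mean exactly; the log SD scales by
    s_ratio up to Monte Carlo fluctuation in the realized noise.
    """
    chi_star = normalize(base)
    n = autocorrelated_noise(len(chi_star), spec.window, rng)
    n = n - n.mean()  # exact log-mean preservation
    eps = spec.sigma_err * n
    chi = spec.s_ratio * (chi_star + eps) / np.sqrt(1.0 + spec.sigma_err**2)
    sim = denormalize(chi, base.log_mean, base.log_sd, base.dates, base.pollutant)
    if spec.sigma_err == 0:
        r = 1.0
    else:
        r = float(np.corrcoef(chi, chi_star)[0, 1])
    return SimulatedSeries(
        series=sim,
        r_log=r,
        sd_ratio=float(chi.std()),  # chi* has SD exactly 1
        iqr=sim.iqr,
        draw=draw,
    )


@dataclasses.dataclass(frozen=True)
class SimulationSet:
    """A full Monte Carlo set for one scenario, with summary statistics."""

    spec: ErrorSpec
    draws: tuple[SimulatedSeries, ...]

    @property
    def r_log(self) -> np.ndarray:
        return np.array([d.r_log for d in self.draws])

    @property
    def sd_ratios(self) -> np.ndarray:
        return np.array([d.sd_ratio for d in self.draws])

    @property
    def iqrs(self) -> np.ndarray:
        return np.array([d.iqr for d in self.draws])

    def summary(self) -> dict[str, float]:
        return {
            "n_sims": len(self.draws),
            "mean_r_log": float(self.r_log.mean()),
            "sd_r_log": float(self.r_log.std(ddof=1)) if len(self.draws) > 1 else 0.0,
            "mean_sd_ratio": float(self.sd_ratios.mean()),
            "sd_sd_ratio": float(self.sd_ratios.std(ddof=1)) if len(self.draws) > 1 else 0.0,
            "mean_iqr": float(self.iqrs.mean()),
            "sd_iqr": float(self.iqrs.std(ddof=1)) if len(self.draws) > 1 else 0.0,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": [d.draw for d in self.draws],
                "r_log": self.r_log,
                "sd_ratio": self.sd_ratios,
                "iqr": self.iqrs,
            }
        )


def simulate_set(base: PollutantSeries, spec: ErrorSpec) -> SimulationSet:
    """Run ``spec.n_sims`` draws with per-draw RNGs spawned from ``spec.seed``.

    Spawning from a single :class:`numpy.random.SeedSequence` makes every
    draw independently reproducible and the whole set deterministic.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_sims)
    draws = tuple(
        simulate_once(base, spec, np.random.default_rng(child), draw=i)
        for i, child in enumerate(children)
    )
    return SimulationSet(spec=spec, draws=draws)
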