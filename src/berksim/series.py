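"""Containers for dated pollutant concentration series and monitor networks.

A :class:`PollutantSeries` holds one strictly positive daily concentration
series (lognormal in a typical ambient-monitoring application) together with
the log-scale moments and interquartile range that the error model and the
health model consume.  A :class:`MonitorField` is a set of such series, one
per monitoring site, on a shared date index with site coordinates in km.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError, DomainError


@dataclasses.dataclass(frozen=True)
class PollutantSeries:
    """A dated, strictly positive daily exposure series.

    Parameters
    ----------
    values
        Daily metric values indexed by a :class:`pandas.DatetimeIndex`.
        NaN marks a missing day; every observed value must be > 0.
    pollutant
        Label used in tabular outputs (e.g. ``"1-hr max CO"``).
    """

    values: pd.Series
    pollutant: str = "pollutant"

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.Series):
            raise ConfigurationError("values must be a pandas Series")
        if not isinstance(v.index, pd.DatetimeIndex):
            raise ConfigurationError("values must be indexed by a DatetimeIndex")
        v = v.astype(float)
        if not v.index.is_monotonic_increasing:
            v = v.sort_index()
        object.__setattr__(self, "values", v)
        observed = v.dropna()
        if observed.empty:
            raise DomainError(f"{self.pollutant}: series has no observations")
        if (observed <= 0).any() or np.isinf(observed).any():
            raise DomainError(
                f"{self.pollutant}: concentrations must be strictly positive and finite"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.values.index

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any()

    @property
    def log_values(self) -> np.ndarray:
        return np.log(self.values.to_numpy())

    @property
    def log_mean(self) -> float:
        """Mean of the log concentrations over observed days."""
        return float(np.nanmean(self.log_values))

    @property
    def log_sd(self) -> float:
        """Population (ddof=0) standard deviation of the log concentrations."""
        return float(np.nanstd(self.log_values))

    @property
    def iqr(self) -> float:
        """Interquartile range on the raw concentration scale."""
        q75, q25 = np.nanpercentile(self.values.to_numpy(), [75, 25])
        return float(q75 - q25)

    def dropna(self) -> "PollutantSeries":
        return PollutantSeries(self.values.dropna(), self.pollutant)

    def align_with(self, other: pd.Series | pd.DataFrame) -> None:
        """Raise :class:`AlignmentError` unless ``other`` shares this date index."""
        if not self.dates.equals(other.index):
            raise AlignmentError(
                f"{self.pollutant}: date index does not match companion data"
            )


@dataclasses.dataclass(frozen=True)
class MonitorField:
    """Pollutant series at several monitoring sites sharing a date index.

    ``coords`` is indexed by site id with columns ``x_km`` and ``y_km``.
    """

    series: Mapping[str, PollutantSeries]
    coords: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.series:
            raise ConfigurationError("monitor field has no sites")
        missing = set(self.series) - set(self.coords.index)
        if missing:
            raise ConfigurationError(f"sites without coordinates: {sorted(missing)}")
        for col in ("x_km", "y_km"):
            if col not in self.coords.columns:
                raise ConfigurationError(f"coords must carry a {col!r} column")
        if not np.isfinite(self.coords[["x_km", "y_km"]].to_numpy()).all():
            raise ConfigurationError("site coordinates must be finite")
        dates = None
        for sid, s in self.series.items():
            if dates is None:
                dates = s.dates
            elif not s.dates.equals(dates):
                raise AlignmentError(f"site {sid}: date index differs from the field's")

    @property
    def site_ids(self) -> list[str]:
        return list(self.series)

    @property
    def n_sites(self) -> int:
        return len(self.series)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return next(iter(self.series.values())).dates

    def __iter__(self) -> Iterator[tuple[str, PollutantSeries]]:
        return iter(self.series.items())

    def distance(self, a: str, b: str) -> float:
        """Euclidean distance in km between two sites."""
        pa = self.coords.loc[a, ["x_km", "y_km"]].to_numpy(float)
        pb = self.coords.loc[b, ["x_km", "y_km"]].to_numpy(float)
        return float(np.hypot(*(pa - pb)))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: date, site_id, pollutant, value."""
        rows = []
        for sid, s in self:
            df = pd.DataFrame(
                {
                    "date": s.dates,
                    "site_id": sid,
                    "pollutant": s.pollutant,
                    "value": s.values.to_numpy(),
                }
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, obs: pd.DataFrame, coords: pd.DataFrame) -> "MonitorField":
        """Build a field from a long-format observation table.

        ``obs`` columns: date, site_id, pollutant, value.  ``coords`` columns:
        site_id, x_km, y_km (site_id may be a column or the index).
        """
        obs = obs.copy()
        obs["date"] = pd.to_datetime(obs["date"])
        if "site_id" in coords.columns:
            coords = coords.set_index("site_id")
        dates = pd.DatetimeIndex(sorted(obs["date"].unique()))
        series = {}
        for sid, grp in obs.groupby("site_id", sort=True):
            s = grp.set_index("date")["value"].reindex(dates)
            pollutant = str(grp["pollutant"].iloc[0])
            series[str(sid)] = PollutantSeries(s, pollutant)
        coords.index = coords.index.astype(str)
        return cls(series=series, coords=coords)
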