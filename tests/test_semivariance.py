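"""Scaled semivariance, semivariogram fitting, and population weighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import berksim as bk
from berksim.exceptions import AnalysisError, DomainError, FitError, IllPosedFitError

# Reported (gamma_bar, R_bar) pairs for the twelve Atlanta pollutant metrics;
# the printed columns agree with the conversion formula to within rounding.
PRINTED_R_BAR = {
    "1-hr max NO2": 0.320,
    "1-hr max NOx": 0.445,
    "8-hr max O3": 0.903,
    "1-hr max SO2": 0.319,
    "1-hr max CO": 0.418,
    "24-hr PM10": 0.678,
    "24-hr PM2.5": 0.819,
    "24-hr PM2.5-SO4": 0.873,
    "24-hr PM2.5-NO3": 0.754,
    "24-hr PM2.5-NH4": 0.741,
    "24-hr PM2.5-EC": 0.495,
    "24-hr PM2.5-OC": 0.702,
}


@pytest.mark.parametrize(
    "r, expected",
    [(1.0, 0.0), (0.903, 0.051), (0.320, 0.516), (0.0, 1.0)],
)
def test_scaled_semivariance_reference_values(r, expected):
    assert bk.scaled_semivariance_from_r(r) == pytest.approx(expected, abs=1e-3)


@pytest.mark.parametrize(
    "gamma, expected",
    [(0.411, 0.418), (0.0, 1.0), (0.337, 0.495), (1.0, 0.0)],
)
def test_correlation_from_semivariance_reference_values(gamma, expected):
    assert bk.correlation_from_semivariance(gamma) == pytest.approx(expected, abs=1e-3)


def test_all_reference_rows_satisfy_the_conversion():
    from berksim.reference import GAMMA_BAR

    for name, gamma in GAMMA_BAR.items():
        computed = bk.correlation_from_semivariance(gamma)
        assert computed == pytest.approx(PRINTED_R_BAR[name], abs=1e-3), name


@settings(derandomize=True, max_examples=200)
@given(st.floats(min_value=-0.99, max_value=1.0))
def test_round_trip_to_machine_precision(r):
    g = bk.scaled_semivariance_from_r(r)
    assert bk.correlation_from_semivariance(g) == pytest.approx(r, abs=1e-12)


def test_domain_errors():
    with pytest.raises(DomainError):
        bk.scaled_semivariance_from_r(-1.0)
    with pytest.raises(DomainError):
        bk.scaled_semivariance_from_r(1.5)
    with pytest.raises(DomainError):
        bk.correlation_from_semivariance(-0.1)


def _field_from_logs(logs: dict[str, np.ndarray], coords: dict[str, tuple]) -> bk.MonitorField:
    dates = bk.study_dates(len(next(iter(logs.values()))))
    series = {
        sid: bk.PollutantSeries(pd.Series(np.exp(x), index=dates)) for sid, x in logs.items()
    }
    cdf = pd.DataFrame(
        [(sid, x, y) for sid, (x, y) in coords.items()],
        columns=["site_id", "x_km", "y_km"],
    ).set_index("site_id")
    return bk.MonitorField(series=series, coords=cdf)


def test_pairwise_correlations_copy_and_noise(rng):
    n = 2192
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)  # independent unit-variance log-scale noise
    field = _field_from_logs(
        {"A": x, "B": x.copy(), "C": x + e},
        {"A": (0, 0), "B": (0, 0), "C": (10, 0)},
    )
    pairs = {(p.site_a, p.site_b): p for p in bk.pairwise_log_correlations(field)}
    assert pairs[("A", "B")].r == pytest.approx(1.0, abs=1e-12)
    assert pairs[("A", "B")].distance_km == 0.0
    assert pairs[("A", "C")].r == pytest.approx(1 / np.sqrt(2), abs=0.03)


def test_pairwise_overlap_rule(rng):
    n = 800
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    xa, ya = x.copy(), y.copy()
    xa[n // 2:] = np.nan  # disjoint coverage
    ya[: n // 2] = np.nan
    field = _field_from_logs({"A": xa, "B": ya}, {"A": (0, 0), "B": (5, 0)})
    with pytest.raises(AnalysisError):
        bk.pairwise_log_correlations(field, min_overlap=100)


def test_fit_semivariogram_closed_form_range():
    nugget = 0.2
    r0 = bk.correlation_from_semivariance(nugget)
    # the far pair sits at 95% of the sill rise, i.e. exactly at the range
    g_far = nugget + (1 - nugget) * (1 - np.exp(-3.0))
    r_far = bk.correlation_from_semivariance(g_far)
    pairs = [
        bk.PairCorrelation("a", "b", 0.0, r0, 2000),
        bk.PairCorrelation("a", "c", 0.0, r0, 2000),
        bk.PairCorrelation("b", "d", 40.0, r_far, 2000),
    ]
    fit = bk.fit_semivariogram(pairs, nugget=nugget)
    assert fit.range_km == pytest.approx(40.0, rel=0.02)
    assert fit.sill == 1.0


def test_fit_semivariogram_degenerate_designs():
    same = [bk.PairCorrelation("a", "b", 10.0, 0.5, 500)] * 3
    with pytest.raises(IllPosedFitError):
        bk.fit_semivariogram(same, nugget=0.1)
    zero = [bk.PairCorrelation("a", "b", 0.0, 0.9, 500)]
    with pytest.raises(FitError):
        bk.fit_semivariogram(zero, nugget=0.1)


class _StubGamma:
    """Maps exact distances to semivariance values, vectorised."""

    def __init__(self, mapping):
        self.mapping = mapping

    def gamma(self, h):
        h = np.atleast_1d(np.asarray(h, float))
        out = np.empty_like(h)
        for i, hi in enumerate(h):
            out[i] = self.mapping[round(float(hi), 6)]
        return out


def _tracts(populations, coords, wtd=1.0):
    table = pd.DataFrame(
        {
            "tract_id": [f"T{i}" for i in range(len(populations))],
            "x_km": [c[0] for c in coords],
            "y_km": [c[1] for c in coords],
            "population": populations,
        }
    )
    return bk.TractTable(table=table, within_tract_distance=wtd)


def test_population_weighted_three_tract_toy():
    # populations 1,2,3 at a 3-4-5 triangle; within-tract gamma'=0.05 and
    # pairwise 0.1/0.2/0.3: brute-force weighted mean over all 6 unordered
    # pairs (incl. i=j, weights p_i+p_j) is 3.2/24.
    tr = _tracts([1, 2, 3], [(0, 0), (3, 0), (0, 4)], wtd=1.0)
    stub = _StubGamma({1.0: 0.05, 3.0: 0.1, 4.0: 0.2, 5.0: 0.3})
    budget = bk.population_weighted_semivariance(stub, tr)
    assert budget.gamma_bar == pytest.approx(3.2 / 24, abs=1e-12)
    assert budget.r_bar == pytest.approx(bk.correlation_from_semivariance(3.2 / 24))


def test_population_weighting_scale_invariance_and_constant():
    coords = [(0, 0), (3, 0), (0, 4)]
    stub = _StubGamma({1.0: 0.05, 3.0: 0.1, 4.0: 0.2, 5.0: 0.3})
    b1 = bk.population_weighted_semivariance(stub, _tracts([1, 2, 3], coords))
    b7 = bk.population_weighted_semivariance(stub, _tracts([7, 14, 21], coords))
    assert b1.gamma_bar == pytest.approx(b7.gamma_bar, abs=1e-12)
    const = _StubGamma({1.0: 0.42, 3.0: 0.42, 4.0: 0.42, 5.0: 0.42})
    assert bk.population_weighted_semivariance(const, _tracts([1, 2, 3], coords)).gamma_bar == pytest.approx(0.42)


def test_single_tract_uses_within_tract_distance():
    fit = bk.SemivariogramFit(nugget=0.1, range_km=30.0)
    tr = _tracts([100], [(5, 5)], wtd=2.0)
    budget = bk.population_weighted_semivariance(fit, tr)
    assert budget.gamma_bar == pytest.approx(float(fit.gamma(2.0)))


def test_gamma_bar_monotone_in_pointwise_semivariance():
    tr = _tracts([5, 1, 9], [(0, 0), (20, 0), (0, 35)])
    lo = bk.SemivariogramFit(nugget=0.1, range_km=50.0)
    hi = bk.SemivariogramFit(nugget=0.3, range_km=50.0)  # gamma'(h) larger everywhere
    assert (
        bk.population_weighted_semivariance(hi, tr).gamma_bar
        > bk.population_weighted_semivariance(lo, tr).gamma_bar
    )
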