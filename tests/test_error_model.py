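"""Error injection: normalization, noise, calibration, and simulation sets."""

import numpy as np
import pandas as pd
import pytest

import berksim as bk
from berksim.exceptions import (
    ConfigurationError,
    DegenerateSeriesError,
    DomainError,
    SpecificationError,
)


def _series(values) -> bk.PollutantSeries:
    dates = bk.study_dates(len(values))
    return bk.PollutantSeries(pd.Series(values, index=dates))


class TestNormalize:
    def test_hand_computed_standardization(self):
        s = _series(np.exp([-1.0, 0.0, 1.0]))
        chi = bk.normalize(s)
        root = np.sqrt(3.0 / 2.0)  # population SD of [-1,0,1] is sqrt(2/3)
        assert chi == pytest.approx([-root, 0.0, root])

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            bk.normalize(_series([2.0] * 40))

    def test_round_trip(self, base_series):
        chi = bk.normalize(base_series)
        back = bk.denormalize(
            chi, base_series.log_mean, base_series.log_sd, base_series.dates
        )
        np.testing.assert_allclose(
            back.values.to_numpy(), base_series.values.to_numpy(), rtol=1e-12
        )


class TestAutocorrelatedNoise:
    def test_window_one_is_iid_standard_normal(self, rng):
        n = bk.autocorrelated_noise(100_000, window=1, rng=rng)
        assert n.mean() == pytest.approx(0.0, abs=0.02)
        assert n.var() == pytest.approx(1.0, abs=0.02)
        assert np.corrcoef(n[:-1], n[1:])[0, 1] == pytest.approx(0.0, abs=0.02)

    def test_running_average_autocorrelation_theory(self, rng):
        n = bk.autocorrelated_noise(100_000, window=3, rng=rng)
        assert n.var() == pytest.approx(1.0, abs=0.02)
        lag = lambda k: np.corrcoef(n[:-k], n[k:])[0, 1]
        assert lag(1) == pytest.approx(2.0 / 3.0, abs=0.02)
        assert lag(2) == pytest.approx(1.0 / 3.0, abs=0.02)
        assert lag(3) == pytest.approx(0.0, abs=0.02)

    def test_window_longer_than_series(self):
        with pytest.raises(ConfigurationError):
            bk.autocorrelated_noise(5, window=10, rng=0)


@pytest.mark.parametrize(
    "r_bar, expected",
    [(0.418, 1.18), (1.0, 0.0), (0.819, 0.47), (0.320, 1.46)],
)
def test_sigma_err_calibration(r_bar, expected):
    assert round(bk.sigma_err_from_r(r_bar), 2) == expected


def test_sigma_err_domain():
    with pytest.raises(DomainError):
        bk.sigma_err_from_r(0.0)
    with pytest.raises(DomainError):
        bk.sigma_err_from_r(-0.2)


@pytest.mark.parametrize(
    "sigma, label, expected",
    [
        (1.46, "C", 1.77),
        (1.46, "B", 0.57),
        (0.33, "B", 0.95),
        (0.0, "C", 1.0),
        (0.0, "B", 1.0),
    ],
)
def test_sd_ratio_endpoints(sigma, label, expected):
    assert round(bk.sd_ratio(sigma, label), 2) == expected


def test_sd_ratio_unknown_label():
    with pytest.raises(SpecificationError):
        bk.sd_ratio(1.0, "classical")


class TestErrorSpec:
    def test_named_endpoints_fill_s_ratio(self):
        spec = bk.ErrorSpec(sigma_err=1.18, type_label="C")
        assert spec.s_ratio == pytest.approx(np.sqrt(1 + 1.18**2))
        spec = bk.ErrorSpec(sigma_err=1.18, type_label="B")
        assert spec.s_ratio == pytest.approx(1 / np.sqrt(1 + 1.18**2))

    def test_out_of_bounds_s_ratio_rejected(self):
        with pytest.raises(SpecificationError):
            bk.ErrorSpec(sigma_err=0.5, type_label="intermediate", s_ratio=2.0)

    def test_intermediate_requires_explicit_s_ratio(self):
        with pytest.raises(SpecificationError):
            bk.ErrorSpec(sigma_err=0.5, type_label="intermediate")

    def test_mislabeled_endpoint_rejected(self):
        with pytest.raises(SpecificationError):
            bk.ErrorSpec(sigma_err=0.5, type_label="C", s_ratio=1.0)


class TestSimulateOnce:
    def test_zero_error_is_identity(self, base_series):
        spec = bk.ErrorSpec(sigma_err=0.0, type_label="C", n_sims=1, seed=1)
        sim = bk.simulate_once(base_series, spec, rng=np.random.default_rng(0))
        np.testing.assert_allclose(
            sim.series.values.to_numpy(), base_series.values.to_numpy(), rtol=1e-12
        )
        assert sim.r_log == 1.0

    def test_log_mean_preserved_exactly(self, base_series):
        spec = bk.ErrorSpec(sigma_err=1.18, type_label="B", seed=3)
        sim = bk.simulate_once(base_series, spec, rng=np.random.default_rng(5))
        assert sim.series.log_mean == pytest.approx(base_series.log_mean, abs=1e-10)

    def test_type_c_matches_direct_formula(self, base_series):
        # at the type C endpoint the pipeline reduces to chi = chi* + eps
        sigma = 0.9
        spec = bk.ErrorSpec(sigma_err=sigma, type_label="C", seed=3)
        sim = bk.simulate_once(base_series, spec, rng=np.random.default_rng(42))
        chi_star = bk.normalize(base_series)
        noise = bk.autocorrelated_noise(len(chi_star), 3, np.random.default_rng(42))
        noise = noise - noise.mean()
        expected = np.exp(
            base_series.log_mean + base_series.log_sd * (chi_star + sigma * noise)
        )
        np.testing.assert_allclose(sim.series.values.to_numpy(), expected, rtol=1e-10)


class TestSimulateSet:
    def test_deterministic_under_fixed_seed(self, base_series):
        spec = bk.ErrorSpec.from_gamma_bar(0.411, type_label="C", n_sims=5, seed=99)
        a = bk.simulate_set(base_series, spec)
        b = bk.simulate_set(base_series, spec)
        np.testing.assert_array_equal(a.r_log, b.r_log)
        np.testing.assert_allclose(
            a.draws[3].series.values.to_numpy(), b.draws[3].series.values.to_numpy()
        )

    def test_achieved_correlation_matches_calibration(self, base_series):
        spec = bk.ErrorSpec.from_gamma_bar(0.411, type_label="C", n_sims=200, seed=7)
        sims = bk.simulate_set(base_series, spec)
        summary = sims.summary()
        target = np.sqrt(bk.correlation_from_semivariance(0.411))
        se = summary["sd_r_log"] / np.sqrt(summary["n_sims"])
        assert abs(summary["mean_r_log"] - target) < 3 * se

    def test_iqr_and_sd_orderings_by_type(self, base_series):
        kw = dict(n_sims=50, seed=21)
        c = bk.simulate_set(base_series, bk.ErrorSpec(sigma_err=1.18, type_label="C", **kw))
        b = bk.simulate_set(base_series, bk.ErrorSpec(sigma_err=1.18, type_label="B", **kw))
        assert c.summary()["mean_iqr"] > base_series.iqr > b.summary()["mean_iqr"]
        assert c.summary()["mean_sd_ratio"] > 1.0 > b.summary()["mean_sd_ratio"]

    def test_error_independence_structure_by_type(self, base_series):
        # type C error is independent of the true series; type B error is
        # independent of the simulated series (log scale)
        ln_star = np.log(base_series.values.to_numpy())
        for label, against in (("C", "true"), ("B", "sim")):
            spec = bk.ErrorSpec(sigma_err=1.18, type_label=label, n_sims=200, seed=31)
            sims = bk.simulate_set(base_series, spec)
            corrs = []
            for d in sims.draws:
                ln_sim = np.log(d.series.values.to_numpy())
                err = ln_sim - ln_star
                ref = ln_star if against == "true" else ln_sim
                corrs.append(np.corrcoef(err, ref)[0, 1])
            corrs = np.array(corrs)
            se = corrs.std(ddof=1) / np.sqrt(len(corrs))
            assert abs(corrs.mean()) < max(3 * se, 0.01), label

    def test_wider_correlation_spread_for_larger_error(self, base_series):
        kw = dict(type_label="C", n_sims=100, seed=41)
        small = bk.simulate_set(base_series, bk.ErrorSpec(sigma_err=0.33, **kw))
        large = bk.simulate_set(base_series, bk.ErrorSpec(sigma_err=1.46, **kw))
        assert large.summary()["sd_r_log"] > small.summary()["sd_r_log"]


def test_window_one_matches_bivariate_normal_construction(base_series):
    """With iid noise the (lnZ*, lnZ) pairs follow the analytic joint moments."""
    sigma, s = 1.18, np.sqrt(1 + 1.18**2)
    spec = bk.ErrorSpec(sigma_err=sigma, type_label="C", n_sims=50, window=1, seed=77)
    sims = bk.simulate_set(base_series, spec)
    chi_star = bk.normalize(base_series)
    pooled_chi = np.concatenate(
        [
            (np.log(d.series.values.to_numpy()) - base_series.log_mean) / base_series.log_sd
            for d in sims.draws
        ]
    )  # ~1.1e5 points
    pooled_star = np.tile(chi_star, len(sims.draws))
    # analytic joint: Var(chi) = s^2, Corr(chi, chi*) = 1/sqrt(1+sigma^2)
    assert pooled_chi.mean() == pytest.approx(0.0, abs=0.02)
    assert pooled_chi.std() == pytest.approx(s, rel=0.02)
    rho = np.corrcoef(pooled_chi, pooled_star)[0, 1]
    assert rho == pytest.approx(1 / np.sqrt(1 + sigma**2), abs=0.02)
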