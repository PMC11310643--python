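"""Monte Carlo engine: moment matching, supports, determinism, intervals."""

import numpy as np
import pytest
import scipy.stats

from econeval import (
    InfeasibleMomentsError,
    OutcomeSpec,
    PSAConfig,
    beta_from_moments,
    predicted_interval,
    sample_draws,
    uniform_from_moments,
)

N_LARGE = 100_000


def _spec(mean_c, sd_c, mean_i, sd_i, dw_mean, dw_sd, name="x"):
    return OutcomeSpec(
        name=name,
        risk_control={"mean": mean_c, "sd": sd_c},
        risk_intervention={"mean": mean_i, "sd": sd_i},
        dw={"mean": dw_mean, "sd": dw_sd},
    )


class TestBetaFromMoments:
    def test_uniform_is_beta_one_one(self):
        alpha, beta = beta_from_moments(0.5, np.sqrt(1.0 / 12.0))
        assert alpha == pytest.approx(1.0)
        assert beta == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "mean, sd, expected",
        [
            (0.211, 0.109, (2.7455, 10.2665)),  # GBV weight
            (0.147, 0.085, (2.4042, 13.9501)),  # HIV weight
        ],
    )
    def test_fixture_weights(self, mean, sd, expected):
        alpha, beta = beta_from_moments(mean, sd)
        assert alpha == pytest.approx(expected[0], rel=1e-3)
        assert beta == pytest.approx(expected[1], rel=1e-3)

    @pytest.mark.parametrize("mean, sd", [(0.211, 0.109), (0.006, 0.002), (0.9, 0.05)])
    def test_moments_recovered_exactly(self, mean, sd):
        alpha, beta = beta_from_moments(mean, sd)
        m = alpha / (alpha + beta)
        v = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1.0))
        assert m == pytest.approx(mean, abs=1e-12)
        assert np.sqrt(v) == pytest.approx(sd, abs=1e-12)

    def test_infeasible_moments_raise_named_error(self):
        with pytest.raises(InfeasibleMomentsError):
            beta_from_moments(0.01, 0.5)
        with pytest.raises(InfeasibleMomentsError):
            beta_from_moments(1.5, 0.1)


class TestUniformFromMoments:
    def test_point_mass(self):
        assert uniform_from_moments(50.0, 0.0) == (50.0, 50.0)

    def test_unit_width(self):
        low, high = uniform_from_moments(0.0, 1.0 / np.sqrt(12.0))
        assert low == pytest.approx(-0.5)
        assert high == pytest.approx(0.5)

    def test_fixture_risk_bounds(self):
        low, high = uniform_from_moments(70.25, 5.93)
        assert low == pytest.approx(59.98, abs=0.01)
        assert high == pytest.approx(80.52, abs=0.01)


@pytest.mark.parametrize("family", ["normal", "beta", "uniform"])
def test_moment_recovery_within_four_mc_ses(family):
    """Sample mean and SD of each risk/weight column match the spec moments."""
    spec = _spec(40.09, 3.39, 48.23, 4.07, 0.211, 0.109, name="gbv")
    draws = sample_draws([spec], PSAConfig(n_sims=N_LARGE, seed=7,
                                           risk_family=family))
    checks = [
        (draws.risk_control["gbv"], 40.09, 3.39),
        (draws.risk_intervention["gbv"], 48.23, 4.07),
        (draws.dw["gbv"], 0.211, 0.109),
    ]
    for column, mean, sd in checks:
        se_mean = sd / np.sqrt(N_LARGE)
        se_sd = sd / np.sqrt(2.0 * N_LARGE)
        assert abs(column.mean() - mean) < 4.0 * se_mean
        assert abs(column.std(ddof=1) - sd) < 4.0 * se_sd


def test_beta_and_uniform_draws_respect_supports():
    spec = _spec(29.17, 2.46, 39.1, 3.3, 0.006, 0.002, name="sti")
    beta_draws = sample_draws([spec], PSAConfig(n_sims=20_000, seed=3,
                                                risk_family="beta"))
    for column in (beta_draws.risk_control["sti"], beta_draws.risk_intervention["sti"]):
        assert column.min() > 0.0 and column.max() < 100.0
    assert beta_draws.dw["sti"].min() > 0.0 and beta_draws.dw["sti"].max() < 1.0

    uni = sample_draws([spec], PSAConfig(n_sims=20_000, seed=3,
                                         risk_family="uniform"))
    low, high = uniform_from_moments(29.17, 2.46)
    assert uni.risk_control["sti"].min() >= low
    assert uni.risk_control["sti"].max() <= high


def test_explicit_uniform_bounds_mode():
    spec = OutcomeSpec(
        name="x",
        risk_control={"mean": 50.0, "sd": 5.0},
        risk_intervention={"mean": 55.0, "sd": 5.0},
        dw={"mean": 0.1, "sd": 0.01},
        risk_control_bounds=(45.0, 55.0),
        risk_intervention_bounds=(50.0, 60.0),
    )
    draws = sample_draws([spec], PSAConfig(n_sims=5_000, seed=11,
                                           risk_family="uniform"))
    assert draws.risk_control["x"].min() >= 45.0
    assert draws.risk_control["x"].max() <= 55.0
    assert draws.risk_intervention["x"].min() >= 50.0


def test_gbv_daly_mean_matches_analytic_product(normal_draws):
    """E[(ARD/100)*DW] = E[ARD]/100 * E[DW] under independence."""
    column = normal_draws.dalys["low_or_no_gbv"]
    analytic = (48.23 - 40.09) / 100.0 * 0.211  # 0.0171754
    mc_se = column.std(ddof=1) / np.sqrt(column.size)
    assert abs(column.mean() - analytic) < 3.0 * mc_se


def test_total_column_is_rowwise_sum(normal_draws):
    stacked = np.column_stack([normal_draws.dalys[n] for n in normal_draws.outcomes])
    np.testing.assert_allclose(stacked.sum(axis=1), normal_draws.total, rtol=0,
                               atol=1e-12)


def test_total_mean_converges_to_analytic_sum(normal_draws):
    analytic = 0.0174647
    mc_se = normal_draws.total.std(ddof=1) / np.sqrt(normal_draws.n_sims)
    assert abs(normal_draws.total.mean() - analytic) < 4.0 * mc_se


def test_zero_sd_inputs_collapse_to_point_estimates():
    spec = _spec(40.0, 0.0, 48.0, 0.0, 0.2, 0.0)
    for family in ("normal", "beta", "uniform"):
        draws = sample_draws([spec], PSAConfig(n_sims=50, seed=1,
                                               risk_family=family))
        assert np.all(draws.ard["x"] == 8.0)
        assert np.all(draws.dalys["x"] == pytest.approx(0.016))


def test_same_seed_reproduces_draw_matrix(fixture_specs):
    cfg = PSAConfig(n_sims=2_000, seed=42)
    a = sample_draws(fixture_specs, cfg)
    b = sample_draws(fixture_specs, cfg)
    np.testing.assert_array_equal(a.total, b.total)
    for name in a.outcomes:
        np.testing.assert_array_equal(a.dw[name], b.dw[name])


def test_infeasible_beta_risk_moments_raise():
    # control risk 1% with SD 15 pp: on the proportion scale sd^2 = 0.0225
    # exceeds mean*(1-mean) = 0.0099, so no beta has these moments
    spec = _spec(1.0, 15.0, 50.0, 3.0, 0.1, 0.01)
    with pytest.raises(InfeasibleMomentsError):
        sample_draws([spec], PSAConfig(n_sims=10, seed=0, risk_family="beta"))


class TestPredictedInterval:
    def test_order_statistic_bounds_on_1_to_100(self):
        low, high = predicted_interval(np.arange(1.0, 101.0))
        assert low <= 6.0
        assert high >= 95.0

    def test_constant_column_degenerates(self):
        low, high = predicted_interval(np.full(100, 3.25))
        assert low == high == 3.25

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(5)
        low, high = predicted_interval(rng.standard_normal(N_LARGE))
        z = scipy.stats.norm.ppf(0.95)
        assert low == pytest.approx(-z, abs=0.02)
        assert high == pytest.approx(z, abs=0.02)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            predicted_interval(np.arange(10.0))
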