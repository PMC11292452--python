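import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import policyfx as px
from policyfx.model_core import (
    DEFAULT_CONFOUNDERS,
    DEFAULT_OTHERS,
    ModelConfig,
    ModelDataError,
    ModelParams,
    build_model_inputs,
    cumulative_policy_effect,
    deterministic_recursion,
    lag_log_rate,
    linear_predictor,
    nb_log_density,
)
from policyfx.policy_coding import LawRecord, POLICY_IDS, build_policy_panel


def make_params(n_years, **kw):
    defaults = dict(
        gamma=np.zeros(n_years),
        beta_conf=np.zeros(5),
        beta_other=np.zeros(23),
        rho1=0.0,
        rho2=0.0,
        beta_inst=np.zeros(10),
        beta_slope=np.zeros(10),
        phi=10.0,
    )
    defaults.update(kw)
    return ModelParams(**defaults)


class TestLagLogRate:
    def test_zero_count_continuity(self):
        assert lag_log_rate(0, 1e6) == pytest.approx(np.log(0.5e-6))

    def test_direct_evaluation(self):
        # independent arithmetic: ln(100.5) - ln(1e6)
        assert lag_log_rate(100, 1e6) == pytest.approx(
            np.log(100.5) - np.log(1e6)
        )
        assert lag_log_rate(100, 1e6) == pytest.approx(-9.2054, abs=1e-4)

    def test_monotone_in_y(self):
        ys = np.arange(0, 50)
        vals = lag_log_rate(ys, 1e6)
        assert np.all(np.diff(vals) > 0)

    def test_bad_population_rejected(self):
        with pytest.raises(ModelDataError, match="population"):
            lag_log_rate(3, 0.0)


class TestCumulativePolicyEffect:
    def test_all_zero(self):
        assert cumulative_policy_effect(
            np.ones(10), np.ones(10), np.zeros(10), np.zeros(10)
        ) == pytest.approx(0.0)

    def test_full_phase_equals_total(self):
        bi, bs = np.zeros(10), np.zeros(10)
        bi[3], bs[3] = -0.04, -0.06
        e = np.zeros(10)
        f = np.zeros(10)
        e[3] = f[3] = 1.0
        assert cumulative_policy_effect(bi, bs, e, f) == pytest.approx(-0.1)

    def test_log_additivity(self):
        theta = np.log(0.9)
        bi = np.zeros(10)
        bi[0] = bi[1] = theta
        e = np.zeros(10)
        e[0] = e[1] = 1.0
        delta = cumulative_policy_effect(bi, np.zeros(10), e, np.zeros(10))
        assert np.exp(delta) == pytest.approx(0.81)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ModelDataError, match="mismatch"):
            cumulative_policy_effect(np.ones(9), np.ones(10), np.ones(10), np.ones(10))


class TestNbLogDensity:
    def test_zero_closed_form(self):
        mu, phi = 3.7, 2.2
        assert nb_log_density(0, mu, phi) == pytest.approx(
            phi * np.log(phi / (phi + mu))
        )

    def test_matches_gammaln_oracle(self):
        # independent oracle via scipy's pmf in (n, p) parameterization
        y, mu, phi = 3, 2.0, 5.0
        oracle = stats.nbinom.logpmf(y, phi, phi / (phi + mu))
        assert abs(nb_log_density(y, mu, phi) - oracle) < 1e-10

    def test_poisson_limit(self):
        mu, phi = 2.0, 1e6
        for y in range(11):
            assert nb_log_density(y, mu, phi) == pytest.approx(
                stats.poisson.logpmf(y, mu), abs=1e-4
            )

    @pytest.mark.parametrize("mu,phi", [(0.5, 0.3), (2.0, 5.0), (40.0, 12.0)])
    def test_normalization(self, mu, phi):
        ys = np.arange(0, 4000)
        total = np.exp(nb_log_density(ys, mu, phi)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_domain_violations_rejected(self):
        with pytest.raises(ModelDataError):
            nb_log_density(-1, 2.0, 5.0)
        with pytest.raises(ModelDataError):
            nb_log_density(2, -1.0, 5.0)
        with pytest.raises(ModelDataError):
            nb_log_density(2, 1.0, 0.0)
        with pytest.raises(ModelDataError):
            nb_log_density(2.5, 1.0, 1.0)


def single_row_inputs(a1=0.0, a2=0.0, e0=None, f0=None, e1=None, f1=None, e2=None, f2=None):
    z = np.zeros((1, 10))

    def m(x):
        return z.copy() if x is None else np.asarray(x, float).reshape(1, 10)

    return px.ModelInputs(
        states=["AA"],
        years=np.array([1990]),
        row_state=np.array([0]),
        row_year=np.array([0]),
        y=np.array([5]),
        log_pop=np.array([np.log(1e6)]),
        x_conf=np.full((1, 5), 0.3),
        x_other=np.full((1, 23), -0.2),
        a1=np.array([a1]),
        a2=np.array([a2]),
        E0=m(e0), F0=m(f0), E1=m(e1), F1=m(f1), E2=m(e2), F2=m(f2),
    )


class TestLinearPredictor:
    def test_no_ar_no_policy(self):
        inputs = single_row_inputs(a1=-9.0, a2=-9.0)
        params = make_params(
            1, gamma=np.array([-0.3]), beta_conf=np.full(5, 0.1),
            beta_other=np.full(23, 0.02),
        )
        eta = linear_predictor(inputs, params)
        expected = (
            np.log(1e6) - 0.3 + 5 * 0.3 * 0.1 + 23 * (-0.2) * 0.02
        )
        assert eta[0] == pytest.approx(expected)

    def test_debias_cancellation(self):
        # fully phased-in policy with lag rates at their policy equilibrium
        # (counterfactual + theta): the predictor shifts by exactly theta,
        # independent of rho1, rho2
        theta = -0.1
        on = np.zeros(10)
        on[0] = 1.0
        base = single_row_inputs(a1=-9.0, a2=-9.0)
        treated = single_row_inputs(
            a1=-9.0 + theta, a2=-9.0 + theta,
            e0=on, f0=on, e1=on, f1=on, e2=on, f2=on,
        )
        bi, bs = np.zeros(10), np.zeros(10)
        bi[0], bs[0] = theta / 2, theta / 2
        params = make_params(1, rho1=0.6, rho2=0.2, beta_inst=bi, beta_slope=bs)
        eta_treated = linear_predictor(treated, params)
        eta_base = linear_predictor(base, params)
        assert eta_treated[0] - eta_base[0] == pytest.approx(theta, abs=1e-12)

    def test_debias_term_cancels_lag(self):
        # with D1 = a1 and rho2 = 0, D0 = 0: eta is independent of a1
        on = np.zeros(10)
        on[0] = 1.0
        bi = np.zeros(10)
        etas = []
        for a1 in (-9.0, -5.0):
            bi_local = bi.copy()
            bi_local[0] = a1  # sets D1 = a1 via e1 = on
            inputs = single_row_inputs(a1=a1, e1=on)
            params = make_params(1, rho1=0.7, rho2=0.0, beta_inst=bi_local)
            # remove the D0 contribution (e0 = 0) so only the lag adjustment acts
            etas.append(linear_predictor(inputs, params)[0])
        assert etas[0] == pytest.approx(etas[1])

    def test_naive_mode_drops_adjustment(self):
        on = np.zeros(10)
        on[0] = 1.0
        bi = np.zeros(10)
        bi[0] = -0.1
        inputs = single_row_inputs(a1=-9.0, e1=on)
        params = make_params(1, rho1=0.5, beta_inst=bi)
        eta_debias = linear_predictor(inputs, params, debias=True)
        eta_naive = linear_predictor(inputs, params, debias=False)
        assert eta_debias[0] - eta_naive[0] == pytest.approx(0.5 * 0.1)


class TestDeterministicRecursion:
    @pytest.mark.parametrize("rho1,rho2", [(0.0, 0.0), (0.6, 0.2), (0.9, -0.1)])
    def test_equilibrium_shift_is_theta(self, rho1, rho2):
        theta = -0.1
        base = deterministic_recursion(-2.0, rho1, rho2, 0.0, 400, a_init=-9.0)
        shifted = deterministic_recursion(-2.0, rho1, rho2, theta, 400, a_init=-9.0)
        assert shifted[-1] - base[-1] == pytest.approx(theta, abs=1e-10)


@pytest.fixture(scope="module")
def full_panel():
    cfg = px.SimConfig(n_states=50, start_year=1979, end_year=2019, burn_in=4)
    panel, laws, truth = px.simulate_dataset(cfg, seed=21)
    pol = build_policy_panel(
        laws, sorted(panel["state"].unique()), sorted(panel["year"].unique())
    )
    return panel, pol


class TestBuildModelInputs:
    def test_analysis_row_count(self, full_panel):
        panel, pol = full_panel
        inputs = build_model_inputs(panel, pol)
        assert inputs.n_rows == 50 * 39
        assert inputs.years[0] == 1981 and inputs.years[-1] == 2019

    def test_standardization(self, full_panel):
        panel, pol = full_panel
        inputs = build_model_inputs(panel, pol)
        np.testing.assert_allclose(inputs.x_conf.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(inputs.x_conf.std(axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(inputs.x_other.std(axis=0), 1.0, atol=1e-10)

    def test_idempotence(self, full_panel):
        panel, pol = full_panel
        a = build_model_inputs(panel, pol)
        b = build_model_inputs(panel, pol)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.x_conf, b.x_conf)
        np.testing.assert_array_equal(a.a1, b.a1)
        np.testing.assert_array_equal(a.E0, b.E0)
        np.testing.assert_array_equal(a.F2, b.F2)

    def test_lag_alignment(self, full_panel):
        panel, pol = full_panel
        inputs = build_model_inputs(panel, pol)
        sub = panel.set_index(["state", "year"]).sort_index()
        state = inputs.states[3]
        i = np.flatnonzero(
            (inputs.row_state == 3) & (inputs.years[inputs.row_year] == 1990)
        )[0]
        y89 = sub.loc[(state, 1989), "deaths_total"]
        n89 = sub.loc[(state, 1989), "population"]
        assert inputs.a1[i] == pytest.approx(np.log((y89 + 0.5) / n89))
        y88 = sub.loc[(state, 1988), "deaths_total"]
        assert inputs.a2[i] == pytest.approx(np.log((y88 + 0.5) / n89))

    def test_offset_doubling_population(self, full_panel):
        # fix the lag-centering constant so only the offset varies
        panel, pol = full_panel
        cfg = ModelConfig(lag_center=-9.2)
        inputs = build_model_inputs(panel, pol, cfg)
        doubled = panel.copy()
        doubled["population"] = doubled["population"] * 2
        inputs2 = build_model_inputs(doubled, pol, cfg)
        params = make_params(
            inputs.n_years, gamma=np.full(inputs.n_years, -1.8), rho1=0.3
        )
        # lag log rates change too; hold them fixed to isolate the offset
        inputs2.a1, inputs2.a2 = inputs.a1, inputs.a2
        mu1 = np.exp(linear_predictor(inputs, params))
        mu2 = np.exp(linear_predictor(inputs2, params))
        np.testing.assert_allclose(mu2, 2.0 * mu1, rtol=1e-12)

    def test_missing_lag_years_rejected(self, full_panel):
        panel, pol = full_panel
        trimmed = panel[panel["year"] >= 1981]
        with pytest.raises(ModelDataError, match="lag years"):
            build_model_inputs(trimmed, pol, ModelConfig(analysis_years=(1981, 2019)))

    def test_missing_state_year_rejected(self, full_panel):
        panel, pol = full_panel
        broken = panel.drop(panel[(panel.state == panel.state.iloc[0]) & (panel.year == 1990)].index)
        with pytest.raises(ModelDataError, match="missing state-year"):
            build_model_inputs(broken, pol)

    def test_missing_covariate_cell_named(self, full_panel):
        panel, pol = full_panel
        broken = panel.copy()
        state = sorted(panel["state"].unique())[2]
        idx = broken[(broken.state == state) & (broken.year == 1995)].index[0]
        broken.loc[idx, "cov_07"] = np.nan
        with pytest.raises(ModelDataError) as err:
            build_model_inputs(broken, pol)
        assert state in str(err.value)
        assert "1995" in str(err.value)
        assert "cov_07" in str(err.value)

    def test_non_integer_counts_rejected(self, full_panel):
        panel, pol = full_panel
        broken = panel.copy()
        broken["deaths_total"] = broken["deaths_total"].astype(float)
        broken.loc[broken.index[0], "deaths_total"] = 1.5
        with pytest.raises(ModelDataError, match="integer"):
            build_model_inputs(broken, pol)


class TestModelParams:
    def test_theta_is_derived(self):
        p = make_params(3, beta_inst=np.full(10, -0.02), beta_slope=np.full(10, -0.03))
        np.testing.assert_allclose(p.theta, -0.05)

    def test_positive_phi_enforced(self):
        with pytest.raises(ModelDataError, match="phi"):
            make_params(3, phi=-1.0)
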