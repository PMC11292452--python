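import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

import policyfx as px
from policyfx.model_core import ModelConfig, build_model_inputs
from policyfx.policy_coding import POLICY_IDS, build_policy_panel
from policyfx.synthetic_data import (
    AdoptionConfig,
    SimConfig,
    SimulationError,
    TrueParams,
    generate_adoptions,
    generate_covariates,
    generate_panel,
    simulate_dataset,
    true_model_params,
)


class TestGenerateCovariates:
    def test_shape_and_columns(self):
        df = generate_covariates(5, range(1990, 2000), seed=0)
        assert len(df) == 5 * 10
        assert df.filter(regex="^(gun|political|violent|incarceration|income)").shape[1] == 5
        assert df.filter(regex="^cov_").shape[1] == 23

    def test_same_seed_identical(self):
        a = generate_covariates(4, range(1990, 1998), seed=42)
        b = generate_covariates(4, range(1990, 1998), seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_lag1_autocorrelation_near_target(self):
        df = generate_covariates(50, range(1979, 2020), seed=1, ar=0.9)
        vals = df.sort_values(["state", "year"])["gun_ownership"].to_numpy().reshape(50, 41)
        x0, x1 = vals[:, :-1].ravel(), vals[:, 1:].ravel()
        r = np.corrcoef(x0, x1)[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)

    def test_unit_marginal_variance(self):
        # strong autocorrelation inflates per-column sampling noise; average
        # the marginal SD over the 28 independent covariate processes
        df = generate_covariates(50, range(1979, 2020), seed=2)
        sds = df.drop(columns=["state", "year"]).std()
        assert sds.mean() == pytest.approx(1.0, abs=0.1)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(SimulationError):
            generate_covariates(1, range(1990, 2000), seed=0)
        with pytest.raises(SimulationError):
            generate_covariates(5, range(1990, 1993), seed=0)


class TestGenerateAdoptions:
    def test_impossible_hazard_no_adoptions(self):
        cov = generate_covariates(5, range(1990, 2000), seed=0)
        recs = generate_adoptions(
            cov, [AdoptionConfig("bc_dealer", intercept=-np.inf)], seed=1
        )
        assert recs == []

    def test_certain_hazard_all_adopt_first_year(self):
        cov = generate_covariates(5, range(1990, 2000), seed=0)
        recs = generate_adoptions(
            cov, [AdoptionConfig("bc_dealer", intercept=50.0)], seed=1
        )
        assert len(recs) == 5
        assert all(r.effective_date == dt.date(1990, 7, 1) for r in recs)

    def test_mid_year_effective_dates(self):
        cov = generate_covariates(8, range(1990, 2005), seed=3)
        recs = generate_adoptions(
            cov, [AdoptionConfig("wait_7day", intercept=-1.0)], seed=4
        )
        assert recs
        assert all((r.effective_date.month, r.effective_date.day) == (7, 1) for r in recs)

    def test_confounded_adoption_positive_association(self):
        # states with a higher mean confounder adopt more often
        hits = 0
        n_reps = 40
        for rep in range(n_reps):
            cov = generate_covariates(20, range(1990, 2006), seed=100 + rep)
            recs = generate_adoptions(
                cov,
                [AdoptionConfig("bc_dealer", intercept=-2.5, conf_coef=1.5)],
                seed=200 + rep,
            )
            adopted = {r.state for r in recs}
            means = cov.groupby("state")["gun_ownership"].mean()
            flag = means.index.isin(adopted).astype(float)
            if flag.std() == 0:
                continue
            if np.corrcoef(means.to_numpy(), flag)[0, 1] > 0:
                hits += 1
        assert hits >= int(0.95 * n_reps) - 2


class TestGeneratePanel:
    def test_counts_valid_and_complete(self, small_sim):
        cfg, panel, laws, truth = small_sim
        counts = panel["deaths_total"]
        assert (counts >= 0).all()
        assert counts.dtype == np.int64
        assert not panel.isna().any().any()
        assert len(panel) == cfg.n_states * len(list(cfg.years))

    def test_passes_model_input_validation(self, small_sim):
        cfg, panel, laws, truth = small_sim
        pol = build_policy_panel(
            laws, sorted(panel["state"].unique()), sorted(panel["year"].unique())
        )
        inputs = build_model_inputs(panel, pol)
        assert inputs.n_rows == cfg.n_states * (cfg.end_year - cfg.start_year - 1)

    def test_same_seed_identical(self):
        cfg = SimConfig(n_states=4, start_year=1990, end_year=1999, burn_in=3)
        p1, l1, t1 = simulate_dataset(cfg, seed=5)
        p2, l2, t2 = simulate_dataset(cfg, seed=5)
        pd.testing.assert_frame_equal(p1, p2)
        assert l1 == l2
        assert t1.to_json() == t2.to_json()

    def test_law_after_panel_end_rejected(self):
        cfg = SimConfig(n_states=4, start_year=1990, end_year=1999, burn_in=3)
        cov = generate_covariates(4, cfg.extended_years, seed=0)
        truth = TrueParams(true_model_params(cfg, 1), cfg, 1)
        bad = [px.LawRecord("AK", "bc_dealer", dt.date(2050, 1, 1))]
        with pytest.raises(SimulationError, match="after panel end"):
            generate_panel(truth, cov, bad, cfg.population, seed=2)

    def test_deterministic_mode_reaches_steady_state(self):
        # noise off, constant covariates: the realized log rate settles at the
        # no-policy equilibrium and shifts by exactly theta after phase-in
        theta = np.log(0.9)
        cfg = SimConfig(
            n_states=2,
            start_year=1990,
            end_year=2019,
            burn_in=40,
            year_shock_sd=0.0,
            cov_ar=0.0,
            beta_conf=(0.0,) * 5,
            theta=theta,
            adoption=(),
            rho1=0.5,
            rho2=0.2,
        )
        cov = generate_covariates(2, cfg.extended_years, seed=0)
        for c in cov.columns[2:]:
            cov[c] = 0.0
        params = true_model_params(cfg, seed=1)
        truth = TrueParams(params, cfg, 1)
        laws = [px.LawRecord("AK", cfg.effect_policy, dt.date(1991, 1, 1))]
        panel = generate_panel(truth, cov, laws, cfg.population, seed=2, deterministic=True)
        rates = panel.assign(rate=np.log(panel.deaths_total / panel.population))
        ak = rates[rates.state == "AK"].set_index("year")["rate"]
        al = rates[rates.state == "AL"].set_index("year")["rate"]
        # untreated state sits at the equilibrium implied by alpha
        assert al.loc[2019] == pytest.approx(cfg.alpha, abs=1e-6)
        # treated state settles theta lower (geometric decay of transients)
        assert ak.loc[2019] - al.loc[2019] == pytest.approx(theta, abs=1e-3)

    def test_effect_lowers_post_adoption_counts(self):
        # Monte Carlo contrast: same seeds, theta = ln(0.8) vs theta = 0
        diffs = []
        for rep in range(30):
            base = SimConfig(
                n_states=6,
                start_year=1990,
                end_year=2005,
                burn_in=4,
                adoption=(AdoptionConfig("child_access_storage", intercept=0.0),),
            )
            with_effect = dataclasses.replace(base, theta=np.log(0.8))
            without = dataclasses.replace(base, theta=0.0)
            p1, l1, _ = simulate_dataset(with_effect, seed=1000 + rep)
            p0, l0, _ = simulate_dataset(without, seed=1000 + rep)
            assert l1 == l0  # same adoption histories
            late1 = p1[p1.year >= 2000]["deaths_total"].mean()
            late0 = p0[p0.year >= 2000]["deaths_total"].mean()
            diffs.append(late1 - late0)
        assert np.mean(diffs) < 0
        assert np.mean(np.array(diffs) < 0) > 0.8

    def test_log_density_higher_at_truth_than_perturbed(self, small_sim, small_inputs):
        from policyfx.evaluation import calibration_priors
        from policyfx.inference import Posterior

        cfg, panel, laws, truth = small_sim
        post = Posterior(small_inputs, calibration_priors())
        # truth gamma spans output years; the model's spans analysis years
        params = dataclasses.replace(truth.params, gamma=truth.params.gamma[2:])
        vec = post.layout.pack(params)
        lp_truth = post.log_density(vec)
        assert np.isfinite(lp_truth)
        priors = calibration_priors()
        rng = np.random.default_rng(0)
        worse = 0
        for _ in range(10):
            pert = vec.copy()
            j = rng.integers(post.layout.dim)
            scale = {"rho1": priors.sd_rho1, "rho2": priors.sd_rho2}.get(
                post.layout.param_names(small_inputs)[j], 0.1
            )
            pert[j] += 3 * scale * rng.choice([-1, 1])
            if post.log_density(pert) < lp_truth:
                worse += 1
        assert worse >= 8


class TestConfoundingIsReal:
    def test_omitting_adoption_confounder_shifts_estimate(self):
        """Breaking the adoption-driving confounder biases the null policy's
        estimate toward harm (adopters have elevated mortality)."""
        from policyfx.evaluation import calibration_priors
        from policyfx.inference import McmcConfig

        shifts = []
        for rep in range(3):
            cfg = SimConfig(
                n_states=10, start_year=1979, end_year=1994, burn_in=6,
                rho1=0.35, rho2=0.1, phi=33.0, theta=0.0,
                beta_conf=(0.25, 0.02, 0.03, 0.01, 0.02),
                adoption=(
                    AdoptionConfig(
                        "child_access_storage", intercept=-2.0, conf_coef=2.0
                    ),
                ),
            )
            panel, laws, _ = simulate_dataset(cfg, seed=300 + rep)
            pol = build_policy_panel(
                laws, sorted(panel.state.unique()), sorted(panel.year.unique())
            )
            mc = ModelConfig(standardize=False, lag_center=cfg.lag_center)
            inputs_full = build_model_inputs(panel, pol, mc)
            broken = panel.copy()
            broken["gun_ownership"] = np.random.default_rng(rep).normal(size=len(panel))
            inputs_broken = build_model_inputs(broken, pol, mc)
            mcmc = McmcConfig(chains=2, warmup=250, draws=200)
            j = POLICY_IDS.index("child_access_storage")
            full = px.fit(inputs_full, calibration_priors(), mcmc, seed=10 + rep)
            omit = px.fit(inputs_broken, calibration_priors(), mcmc, seed=10 + rep)
            shifts.append(
                np.median(omit.theta_draws()[:, j]) - np.median(full.theta_draws()[:, j])
            )
        assert np.mean(shifts) > 0.01
        assert sum(s > 0 for s in shifts) >= 2


class TestTrueParams:
    def test_json_round_trip(self, small_sim):
        cfg, panel, laws, truth = small_sim
        back = TrueParams.from_json(truth.to_json())
        np.testing.assert_allclose(back.params.gamma, truth.params.gamma)
        np.testing.assert_allclose(back.params.theta, truth.params.theta)
        assert back.config == cfg
        assert back.seed == truth.seed

    def test_default_effect_split(self):
        cfg = SimConfig()
        params = true_model_params(cfg, seed=0)
        j = POLICY_IDS.index(cfg.effect_policy)
        assert params.beta_inst[j] == pytest.approx(np.log(0.9) / 2)
        assert params.beta_slope[j] == pytest.approx(np.log(0.9) / 2)
        assert np.all(np.delete(params.theta, j) == 0)


def test_sim_config_validation():
    with pytest.raises(SimulationError):
        SimConfig(n_states=1)
    with pytest.raises(SimulationError):
        SimConfig(start_year=2000, end_year=2002)
    with pytest.raises(SimulationError):
        SimConfig(population=-1)
    with pytest.raises(SimulationError):
        AdoptionConfig("nope")
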