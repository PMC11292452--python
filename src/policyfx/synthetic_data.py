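"""Synthetic state-year panels with known ground truth.

Generates covariates (stationary AR(1) within state), policy adoption driven
by a logistic hazard on a designated confounder (so adoption is confounded by
construction), and overdispersed death counts forward-simulated from exactly
the model family the fitter assumes — autoregressive negative binomial with
counterfactually adjusted lags.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model_core import (
    DEFAULT_CONFOUNDERS,
    DEFAULT_OTHERS,
    ModelParams,
    N_OTHER,
    N_POLICIES,
)
from .policy_coding import (
    LawRecord,
    POLICY_IDS,
    build_policy_panel,
    synthetic_state_codes,
)


class SimulationError(ValueError):
    """Raised on invalid simulation configuration."""


@dataclass(frozen=True)
class AdoptionConfig:
    """Logistic adoption hazard for one policy.

    P(adopt in year t | not yet adopted) = expit(intercept + coef * confounder).
    Effective dates fall on July 1 of the adoption year.
    """

    policy_id: str
    intercept: float = -2.0
    conf_coef: float = 0.8
    confounder: str = DEFAULT_CONFOUNDERS[0]

    def __post_init__(self) -> None:
        if self.policy_id not in POLICY_IDS:
            raise SimulationError(f"unknown policy {self.policy_id!r}")


@dataclass(frozen=True)
class SimConfig:
    """Scenario settings for a synthetic dataset."""

    n_states: int = 50
    start_year: int = 1979
    end_year: int = 2019
    burn_in: int = 10
    population: float = 5e6
    cov_ar: float = 0.9
    #: baseline year effect; with lag_center == alpha the no-policy
    #: equilibrium log rate equals alpha for any stable (rho1, rho2)
    alpha: float = -9.2
    lag_center: float = -9.2
    year_shock_sd: float = 0.05
    rho1: float = 0.6
    rho2: float = 0.2
    phi: float = 50.0
    beta_conf: tuple[float, ...] = (0.05, 0.02, 0.03, 0.01, 0.02)
    beta_other_scale: float = 0.0        # if > 0, Laplace draws for the 23 others
    effect_policy: str = "child_access_storage"
    theta: float = float(np.log(0.9))    # split evenly across instant and slope
    adoption: tuple[AdoptionConfig, ...] = (
        AdoptionConfig(policy_id="child_access_storage"),
    )

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise SimulationError("need at least 2 states")
        if self.end_year - self.start_year + 1 < 5:
            raise SimulationError("need at least 5 panel years")
        if self.burn_in < 2:
            raise SimulationError("need at least 2 burn-in years")
        if self.population <= 0:
            raise SimulationError("population must be positive")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    @property
    def extended_years(self) -> range:
        return range(self.start_year - self.burn_in, self.end_year + 1)


@dataclass
class TrueParams:
    """Ground truth for a simulated dataset, serializable next to the panel."""

    params: ModelParams
    config: SimConfig
    seed: int
    analysis_years: tuple[int, int] = (0, 0)

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "analysis_years": list(self.analysis_years),
            "config": _config_to_dict(self.config),
            "params": {
                "gamma": self.params.gamma.tolist(),
                "beta_conf": self.params.beta_conf.tolist(),
                "beta_other": self.params.beta_other.tolist(),
                "rho1": self.params.rho1,
                "rho2": self.params.rho2,
                "beta_inst": self.params.beta_inst.tolist(),
                "beta_slope": self.params.beta_slope.tolist(),
                "phi": self.params.phi,
            },
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrueParams":
        d = json.loads(text)
        cfg = d["config"]
        adoption = tuple(AdoptionConfig(**a) for a in cfg.pop("adoption"))
        cfg["beta_conf"] = tuple(cfg["beta_conf"])
        config = SimConfig(adoption=adoption, **cfg)
        p = d["params"]
        params = ModelParams(
            gamma=np.array(p["gamma"]),
            beta_conf=np.array(p["beta_conf"]),
            beta_other=np.array(p["beta_other"]),
            rho1=p["rho1"],
            rho2=p["rho2"],
            beta_inst=np.array(p["beta_inst"]),
            beta_slope=np.array(p["beta_slope"]),
            phi=p["phi"],
        )
        return cls(
            params=params,
            config=config,
            seed=d["seed"],
            analysis_years=tuple(d["analysis_years"]),
        )


def _config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["adoption"] = [dataclasses.asdict(a) for a in config.adoption]
    d["beta_conf"] = list(config.beta_conf)
    return d


# ---------------------------------------------------------------------------

def generate_covariates(
    n_states: int,
    years,
    seed,
    ar: float = 0.9,
    conf_names: tuple[str, ...] = DEFAULT_CONFOUNDERS,
    other_names: tuple[str, ...] = DEFAULT_OTHERS,
) -> pd.DataFrame:
    """Stationary AR(1) covariates per state, unit marginal variance.

    Returns a (state, year) DataFrame with the 5 confounder and 23 other
    covariate columns.  Identical output for identical seeds.
    """
    years = list(years)
    if n_states < 2:
        raise SimulationError("need at least 2 states")
    if len(years) < 5:
        raise SimulationError("need at least 5 years of covariates")
    if not (0 <= ar < 1):
        raise SimulationError("AR coefficient must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed)) if isinstance(seed, int) else np.random.default_rng(seed)
    n_cov = len(conf_names) + len(other_names)
    n_years = len(years)
    innov_sd = np.sqrt(1.0 - ar**2)
    x = np.empty((n_states, n_years, n_cov))
    x[:, 0, :] = rng.standard_normal((n_states, n_cov))
    for t in range(1, n_years):
        x[:, t, :] = ar * x[:, t - 1, :] + innov_sd * rng.standard_normal((n_states, n_cov))
    states = synthetic_state_codes(n_states)
    df = pd.DataFrame(
        {
            "state": np.repeat(states, n_years),
            "year": np.tile(years, n_states),
        }
    )
    for j, name in enumerate([*conf_names, *other_names]):
        df[name] = x[:, :, j].reshape(-1)
    return df


def generate_adoptions(
    covariates: pd.DataFrame,
    adoption_configs,
    seed,
    first_year: int | None = None,
) -> list[LawRecord]:
    """First-passage policy adoption via a logistic hazard on a confounder.

    Each state-policy adopts at most once; effective date is July 1 of the
    adoption year.  Years before ``first_year`` (default: first covariate
    year) are not at risk.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed)) if isinstance(seed, int) else np.random.default_rng(seed)
    states = sorted(covariates["state"].unique())
    years = np.sort(covariates["year"].unique())
    if first_year is not None:
        years = years[years >= first_year]
    cov_idx = covariates.set_index(["state", "year"])
    records: list[LawRecord] = []
    for cfg in adoption_configs:
        if cfg.confounder not in covariates.columns:
            raise SimulationError(f"confounder column {cfg.confounder!r} not in covariates")
        for state in states:
            for year in years:
                z = cov_idx.loc[(state, int(year)), cfg.confounder]
                p = expit(cfg.intercept + cfg.conf_coef * float(z))
                if rng.uniform() < p:
                    records.append(
                        LawRecord(
                            state=state,
                            policy_id=cfg.policy_id,
                            effective_date=dt.date(int(year), 7, 1),
                        )
                    )
                    break
    return records


def true_model_params(config: SimConfig, seed) -> ModelParams:
    """Ground-truth parameters implied by a SimConfig.

    Year effects are the baseline plus independent shocks for the output
    years; policy effects put ``theta`` (split evenly across instant and
    slope) on the designated policy.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed)) if isinstance(seed, int) else np.random.default_rng(seed)
    n_out = len(list(config.years))
    gamma = config.alpha + np.concatenate(
        [[0.0], rng.normal(0.0, config.year_shock_sd, n_out - 1)]
    )
    beta_other = (
        rng.laplace(0.0, config.beta_other_scale, N_OTHER)
        if config.beta_other_scale > 0
        else np.zeros(N_OTHER)
    )
    beta_inst = np.zeros(N_POLICIES)
    beta_slope = np.zeros(N_POLICIES)
    j = POLICY_IDS.index(config.effect_policy)
    beta_inst[j] = config.theta / 2.0
    beta_slope[j] = config.theta / 2.0
    return ModelParams(
        gamma=gamma,
        beta_conf=np.asarray(config.beta_conf, dtype=float),
        beta_other=beta_other,
        rho1=config.rho1,
        rho2=config.rho2,
        beta_inst=beta_inst,
        beta_slope=beta_slope,
        phi=config.phi,
    )


def generate_panel(
    true_params: TrueParams,
    covariates: pd.DataFrame,
    law_records: list[LawRecord],
    populations: pd.DataFrame | float,
    seed,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Forward-simulate the state-year panel over the covariate years.

    Counts are drawn sequentially: y ~ NB(mu, phi) with log mu given by the
    fitted model's linear predictor applied to *realized* lagged log rates.
    Year effects apply over output years; burn-in years use the baseline.
    With ``deterministic=True`` counts equal their means (no sampling, no
    continuity correction in lags), exposing the noise-free recursion.
    """
    config = true_params.config
    params = true_params.params
    rng = np.random.default_rng(np.random.SeedSequence(seed)) if isinstance(seed, int) else np.random.default_rng(seed)

    states = sorted(covariates["state"].unique())
    years = np.sort(covariates["year"].unique()).tolist()
    if years != list(config.extended_years):
        raise SimulationError(
            "covariate years must equal the config's extended years "
            f"(got {years[0]}..{years[-1]}, expected "
            f"{config.extended_years.start}..{config.extended_years.stop - 1})"
        )
    last_year = years[-1]
    for r in law_records:
        if r.state not in states:
            raise SimulationError(f"law record state {r.state!r} not in panel")
        if r.effective_date.year > last_year:
            raise SimulationError(
                f"law effective {r.effective_date} after panel end {last_year}"
            )

    pol = build_policy_panel(law_records, states, years)
    e_grid = (
        pol.pivot_table(index=["state", "year"], columns="policy_id", values="exposure")
        .reindex(columns=list(POLICY_IDS))
        .to_numpy()
        .reshape(len(states), len(years), N_POLICIES)
    )
    f_grid = (
        pol.pivot_table(index=["state", "year"], columns="policy_id", values="phase")
        .reindex(columns=list(POLICY_IDS))
        .to_numpy()
        .reshape(len(states), len(years), N_POLICIES)
    )

    cov_names = [*DEFAULT_CONFOUNDERS, *DEFAULT_OTHERS]
    cov = (
        covariates.sort_values(["state", "year"])[cov_names]
        .to_numpy()
        .reshape(len(states), len(years), len(cov_names))
    )
    beta_all = np.concatenate([params.beta_conf, params.beta_other])

    if isinstance(populations, (int, float)):
        pop = np.full((len(states), len(years)), float(populations))
    else:
        pop = (
            populations.sort_values(["state", "year"])["population"]
            .to_numpy()
            .reshape(len(states), len(years))
        )
    if np.any(pop <= 0):
        raise SimulationError("populations must be positive")

    out_years = list(config.years)
    gamma_by_year = {y: params.gamma[i] for i, y in enumerate(out_years)}
    gamma_ref = params.gamma[0]

    rho_sum = params.rho1 + params.rho2
    if abs(1.0 - rho_sum) < 0.05:
        raise SimulationError(
            f"rho1 + rho2 = {rho_sum:.3f} too close to 1; no stable equilibrium"
        )

    # initialize lags at the no-policy equilibrium for year-0 covariates
    c = config.lag_center
    xb0 = cov[:, 0, :] @ beta_all
    a_eq = (gamma_ref + xb0 - rho_sum * c) / (1.0 - rho_sum)
    a_prev1 = a_eq.copy()
    a_prev2 = a_eq.copy()

    counts = np.empty((len(states), len(years)))
    for t, year in enumerate(years):
        gamma_t = gamma_by_year.get(year, gamma_ref)
        d0 = e_grid[:, t, :] @ params.beta_inst + f_grid[:, t, :] @ params.beta_slope
        d1 = (
            e_grid[:, t - 1, :] @ params.beta_inst + f_grid[:, t - 1, :] @ params.beta_slope
            if t >= 1
            else np.zeros(len(states))
        )
        d2 = (
            e_grid[:, t - 2, :] @ params.beta_inst + f_grid[:, t - 2, :] @ params.beta_slope
            if t >= 2
            else np.zeros(len(states))
        )
        xb = cov[:, t, :] @ beta_all
        log_rate = (
            gamma_t
            + xb
            + params.rho1 * (a_prev1 - c - d1)
            + params.rho2 * (a_prev2 - c - d2)
            + d0
        )
        mu = pop[:, t] * np.exp(log_rate)
        if np.any(mu > 1e9):
            raise SimulationError(
                f"simulated mean count exceeds 1e9 in year {year}; "
                "parameters imply an unstable trajectory"
            )
        if deterministic:
            y = mu
            a_new = np.log(y / pop[:, t])
        else:
            y = rng.negative_binomial(params.phi, params.phi / (params.phi + mu)).astype(float)
            a_new = np.log((y + 0.5) / pop[:, t])
        counts[:, t] = y
        a_prev2 = a_prev1
        a_prev1 = a_new

    df = pd.DataFrame(
        {
            "state": np.repeat(states, len(years)),
            "year": np.tile(years, len(states)),
            "population": pop.reshape(-1),
            "deaths_total": counts.reshape(-1) if deterministic else counts.reshape(-1).astype(np.int64),
        }
    )
    cov_sorted = covariates.sort_values(["state", "year"]).reset_index(drop=True)
    for name in cov_names:
        df[name] = cov_sorted[name].to_numpy()
    # keep only output years (burn-in consumed)
    df = df[df["year"] >= config.start_year].reset_index(drop=True)
    return df


def simulate_dataset(
    config: SimConfig,
    seed: int,
    params: ModelParams | None = None,
    deterministic: bool = False,
):
    """Generate (panel, law_records, TrueParams) for a scenario.

    Splits the seed into independent streams for covariates, adoptions, true
    parameters, and counts, so the pieces are individually reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_cov, s_adopt, s_params, s_counts = ss.spawn(4)
    covariates = generate_covariates(
        config.n_states, config.extended_years, s_cov, ar=config.cov_ar
    )
    law_records = generate_adoptions(
        covariates, config.adoption, s_adopt, first_year=config.start_year
    )
    if params is None:
        params = true_model_params(config, s_params)
    truth = TrueParams(
        params=params,
        config=config,
        seed=seed,
        analysis_years=(config.start_year + 2, config.end_year),
    )
    panel = generate_panel(
        truth, covariates, law_records, config.population, s_counts,
        deterministic=deterministic,
    )
    return panel, law_records, truth
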