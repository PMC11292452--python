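"""Priors and MCMC fitting for the panel model.

The policy prior is constructed so that the *total* effect of each policy
(instant + fully phased-in slope) has a zero-mean normal prior on the log-IRR
scale whose central 95% interval matches a stated IRR band (default
[0.82, 1.22]).  The total-effect SD is split equally (in variance) between the
instant and slope coefficients.  The 23 non-confounder covariates get a
double-exponential (bayesian lasso) prior; everything else is weakly
informative.

Sampling is by the package's own NUTS implementation with analytic gradients;
results are byte-reproducible for a fixed (inputs, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, gammaln

from . import _hmc
from .diagnostics import ess_mean, split_rhat
from .model_core import (
    N_CONFOUNDERS,
    N_OTHER,
    N_POLICIES,
    ModelInputs,
    ModelParams,
    cumulative_policy_effect,
    nb_log_density,
)
from .policy_coding import POLICY_IDS

UNINFORMATIVE_INFLATION = 20.0


class PriorError(ValueError):
    """Raised on invalid prior configuration."""


def prior_sd_total(lower: float = 0.82, upper: float = 1.22, mass: float = 0.95) -> float:
    """SD of the zero-mean normal prior on a policy's total log-IRR effect.

    Chosen so the central ``mass`` interval of the implied IRR distribution
    spans [lower, upper]:  sigma = (ln upper - ln lower) / (2 z), with z the
    standard-normal quantile at (1 + mass) / 2.
    """
    if not (0 < lower < upper):
        raise PriorError(f"require 0 < lower < upper, got ({lower}, {upper})")
    if not (0 < mass < 1):
        raise PriorError(f"mass must be in (0, 1), got {mass}")
    z = stats.norm.ppf((1 + mass) / 2)
    return (np.log(upper) - np.log(lower)) / (2 * z)


@dataclass(frozen=True)
class PriorSpec:
    """All prior scales for the model, on the sampling scale.

    ``sigma_total`` is the SD of the induced prior on each policy's total
    effect theta_p; the equal-variance allocation gives each of beta_inst and
    beta_slope SD ``sigma_total / sqrt(2)``.
    """

    sigma_total: float
    lasso_scale: float = 0.05
    sd_conf: float = 0.1
    mu_alpha: float = 0.0
    sd_alpha: float = 10.0
    sd_year: float = 1.0
    mu_rho1: float = 0.5
    sd_rho1: float = 0.5
    mu_rho2: float = 0.0
    sd_rho2: float = 0.5
    mu_logphi: float = 3.0
    sd_logphi: float = 2.0
    mode: str = "informative"

    def __post_init__(self) -> None:
        if self.sigma_total <= 0:
            raise PriorError("sigma_total must be positive")
        if self.lasso_scale <= 0 or self.sd_conf <= 0:
            raise PriorError("prior scales must be positive")
        if self.mode not in ("informative", "uninformative"):
            raise PriorError(f"unknown prior mode {self.mode!r}")

    @property
    def sd_policy(self) -> float:
        """Per-coefficient SD for beta_inst and beta_slope."""
        return self.sigma_total / np.sqrt(2.0)


def make_priors(config: dict) -> PriorSpec:
    """Build a :class:`PriorSpec` from a configuration mapping.

    The policy-prior scale must be given either directly (``sigma_total``) or
    as an IRR band (``irr_lower``, ``irr_upper``, ``mass``); ``mode`` must be
    ``informative`` or ``uninformative``.  In uninformative mode the policy
    scale is inflated by ``UNINFORMATIVE_INFLATION``.
    """
    config = dict(config)
    mode = config.pop("mode", None)
    if mode is None:
        raise PriorError("prior config must name a mode (informative|uninformative)")
    if "sigma_total" in config:
        sigma = float(config.pop("sigma_total"))
        config.pop("irr_lower", None)
        config.pop("irr_upper", None)
        config.pop("mass", None)
    elif "irr_lower" in config and "irr_upper" in config:
        sigma = prior_sd_total(
            float(config.pop("irr_lower")),
            float(config.pop("irr_upper")),
            float(config.pop("mass", 0.95)),
        )
    else:
        raise PriorError(
            "prior config must give sigma_total or (irr_lower, irr_upper[, mass])"
        )
    if mode == "uninformative":
        sigma *= UNINFORMATIVE_INFLATION
    allowed = {f.name for f in PriorSpec.__dataclass_fields__.values()} - {
        "sigma_total",
        "mode",
    }
    unknown = set(config) - allowed
    if unknown:
        raise PriorError(f"unknown prior config keys: {sorted(unknown)}")
    return PriorSpec(sigma_total=sigma, mode=mode, **{k: float(v) for k, v in config.items()})


def default_priors() -> PriorSpec:
    return make_priors({"mode": "informative", "irr_lower": 0.82, "irr_upper": 1.22})


def sample_prior_theta(priors: PriorSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Monte Carlo draws of one policy's total effect theta from the prior."""
    sd = priors.sd_policy
    return rng.normal(0.0, sd, size) + rng.normal(0.0, sd, size)


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    max_treedepth: int = 10
    target_accept: float = 0.8
    dense_mass: bool = True

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.draws < 1:
            raise PriorError("invalid MCMC configuration")


# ---------------------------------------------------------------------------
# Parameter vector layout

@dataclass(frozen=True)
class ParamLayout:
    """Mapping between the unconstrained sampling vector and ModelParams.

    Vector order: alpha (reference-year effect), year deviations for the
    remaining analysis years, beta_conf, beta_other, rho1, rho2, beta_inst,
    beta_slope, log phi.
    """

    n_years: int

    @property
    def dim(self) -> int:
        return self.n_years + N_CONFOUNDERS + N_OTHER + 2 + 2 * N_POLICIES + 1

    def slices(self) -> dict[str, slice]:
        i = 0
        out = {}
        for name, width in (
            ("alpha", 1),
            ("year_dev", self.n_years - 1),
            ("beta_conf", N_CONFOUNDERS),
            ("beta_other", N_OTHER),
            ("rho1", 1),
            ("rho2", 1),
            ("beta_inst", N_POLICIES),
            ("beta_slope", N_POLICIES),
            ("log_phi", 1),
        ):
            out[name] = slice(i, i + width)
            i += width
        return out

    def unpack(self, vec: np.ndarray) -> ModelParams:
        s = self.slices()
        alpha = vec[s["alpha"]][0]
        gamma = np.concatenate([[alpha], alpha + vec[s["year_dev"]]])
        return ModelParams(
            gamma=gamma,
            beta_conf=vec[s["beta_conf"]].copy(),
            beta_other=vec[s["beta_other"]].copy(),
            rho1=float(vec[s["rho1"]][0]),
            rho2=float(vec[s["rho2"]][0]),
            beta_inst=vec[s["beta_inst"]].copy(),
            beta_slope=vec[s["beta_slope"]].copy(),
            phi=float(np.exp(vec[s["log_phi"]][0])),
        )

    def pack(self, params: ModelParams) -> np.ndarray:
        s = self.slices()
        vec = np.empty(self.dim)
        vec[s["alpha"]] = params.gamma[0]
        vec[s["year_dev"]] = params.gamma[1:] - params.gamma[0]
        vec[s["beta_conf"]] = params.beta_conf
        vec[s["beta_other"]] = params.beta_other
        vec[s["rho1"]] = params.rho1
        vec[s["rho2"]] = params.rho2
        vec[s["beta_inst"]] = params.beta_inst
        vec[s["beta_slope"]] = params.beta_slope
        vec[s["log_phi"]] = np.log(params.phi)
        return vec

    def param_names(self, inputs: ModelInputs) -> list[str]:
        names = ["alpha"]
        names += [f"year_dev_{y}" for y in inputs.years[1:]]
        names += [f"beta_conf_{c}" for c in inputs.conf_names]
        names += [f"beta_other_{c}" for c in inputs.other_names]
        names += ["rho1", "rho2"]
        names += [f"beta_inst_{p}" for p in POLICY_IDS]
        names += [f"beta_slope_{p}" for p in POLICY_IDS]
        names += ["log_phi"]
        return names


def sample_params_from_prior(
    priors: PriorSpec, layout: ParamLayout, rng: np.random.Generator
) -> ModelParams:
    """Draw a full parameter set from the prior (used for SBC harnesses)."""
    s = layout.slices()
    vec = np.empty(layout.dim)
    vec[s["alpha"]] = rng.normal(priors.mu_alpha, priors.sd_alpha)
    vec[s["year_dev"]] = rng.normal(0.0, priors.sd_year, layout.n_years - 1)
    vec[s["beta_conf"]] = rng.normal(0.0, priors.sd_conf, N_CONFOUNDERS)
    vec[s["beta_other"]] = rng.laplace(0.0, priors.lasso_scale, N_OTHER)
    vec[s["rho1"]] = rng.normal(priors.mu_rho1, priors.sd_rho1)
    vec[s["rho2"]] = rng.normal(priors.mu_rho2, priors.sd_rho2)
    vec[s["beta_inst"]] = rng.normal(0.0, priors.sd_policy, N_POLICIES)
    vec[s["beta_slope"]] = rng.normal(0.0, priors.sd_policy, N_POLICIES)
    vec[s["log_phi"]] = rng.normal(priors.mu_logphi, priors.sd_logphi)
    return layout.unpack(vec)


# ---------------------------------------------------------------------------
# Posterior density

class Posterior:
    """Log posterior density and gradient on the unconstrained vector.

    The density is the sum of NB log-likelihood terms over analysis rows plus
    log priors (including the log-phi change-of-variables Jacobian, absorbed
    into the normal prior on log phi).
    """

    def __init__(self, inputs: ModelInputs, priors: PriorSpec, debias: bool = True):
        self.inputs = inputs
        self.priors = priors
        self.debias = debias
        self.layout = ParamLayout(inputs.n_years)
        self._s = self.layout.slices()
        self._n_years = inputs.n_years

        # Fused design for the purely linear blocks (alpha, year deviations,
        # covariates), which occupy the leading positions of the vector.
        n = inputs.n_rows
        year_dummies = np.zeros((n, inputs.n_years - 1))
        nonref = inputs.row_year >= 1
        year_dummies[np.flatnonzero(nonref), inputs.row_year[nonref] - 1] = 1.0
        self._Dfix = np.ascontiguousarray(
            np.column_stack([np.ones(n), year_dummies, inputs.x_conf, inputs.x_other])
        )
        self._k_fix = self._Dfix.shape[1]

        # Vectorized prior arrays: normal everywhere except the lasso block.
        p, s, dim = priors, self._s, self.layout.dim
        self._pmu = np.zeros(dim)
        psd = np.empty(dim)
        self._pmu[s["alpha"]], psd[s["alpha"]] = p.mu_alpha, p.sd_alpha
        psd[s["year_dev"]] = p.sd_year
        psd[s["beta_conf"]] = p.sd_conf
        psd[s["beta_other"]] = 1.0  # placeholder; laplace handled separately
        self._pmu[s["rho1"]], psd[s["rho1"]] = p.mu_rho1, p.sd_rho1
        self._pmu[s["rho2"]], psd[s["rho2"]] = p.mu_rho2, p.sd_rho2
        psd[s["beta_inst"]] = p.sd_policy
        psd[s["beta_slope"]] = p.sd_policy
        self._pmu[s["log_phi"]], psd[s["log_phi"]] = p.mu_logphi, p.sd_logphi
        self._normal_mask = np.ones(dim, dtype=bool)
        self._normal_mask[s["beta_other"]] = False
        self._pisd2 = 1.0 / psd**2
        self._pisd2_masked = np.where(self._normal_mask, self._pisd2, 0.0)
        self._prior_const = float(
            np.sum(-np.log(psd[self._normal_mask]) - 0.5 * np.log(2 * np.pi))
        ) + N_OTHER * float(-np.log(2 * p.lasso_scale))

        # hot-path precomputations: stacked policy designs and count constants
        self._EF0 = np.ascontiguousarray(np.hstack([inputs.E0, inputs.F0]))
        self._EF1 = np.ascontiguousarray(np.hstack([inputs.E1, inputs.F1]))
        self._EF2 = np.ascontiguousarray(np.hstack([inputs.E2, inputs.F2]))
        self._yf = inputs.y.astype(float)
        self._sum_gammaln_y1 = float(np.sum(gammaln(self._yf + 1.0)))
        self._n = n
        self._a1c = inputs.a1 - inputs.lag_center
        self._a2c = inputs.a2 - inputs.lag_center

    def _eta_and_designs(self, vec: np.ndarray):
        x = self.inputs
        s = self._s
        alpha = vec[s["alpha"]][0]
        year_dev = vec[s["year_dev"]]
        beta_conf = vec[s["beta_conf"]]
        beta_other = vec[s["beta_other"]]
        rho1 = vec[s["rho1"]][0]
        rho2 = vec[s["rho2"]][0]
        beta_inst = vec[s["beta_inst"]]
        beta_slope = vec[s["beta_slope"]]

        gamma = np.concatenate([[alpha], alpha + year_dev])
        if self.debias:
            d1 = cumulative_policy_effect(beta_inst, beta_slope, x.E1, x.F1)
            d2 = cumulative_policy_effect(beta_inst, beta_slope, x.E2, x.F2)
            U_inst = x.E0 - rho1 * x.E1 - rho2 * x.E2
            U_slope = x.F0 - rho1 * x.F1 - rho2 * x.F2
        else:
            d1 = d2 = np.zeros(x.n_rows)
            U_inst, U_slope = x.E0, x.F0
        d0 = cumulative_policy_effect(beta_inst, beta_slope, x.E0, x.F0)
        c = x.lag_center
        eta = (
            x.log_pop
            + gamma[x.row_year]
            + x.x_conf @ beta_conf
            + x.x_other @ beta_other
            + rho1 * (x.a1 - c - d1)
            + rho2 * (x.a2 - c - d2)
            + d0
        )
        return eta, d1, d2, U_inst, U_slope

    @staticmethod
    def _safe_mu_phi(eta: np.ndarray, log_phi: float):
        """Clip to keep exp() finite; distant tails stay astronomically
        improbable while gradients continue to point back inward."""
        return np.exp(np.clip(eta, -500.0, 500.0)), float(np.exp(np.clip(log_phi, -30.0, 30.0)))

    def log_likelihood(self, vec: np.ndarray) -> float:
        eta, *_ = self._eta_and_designs(vec)
        mu, phi = self._safe_mu_phi(eta, vec[self._s["log_phi"]][0])
        return float(np.sum(nb_log_density(self.inputs.y, mu, phi)))

    def log_prior_terms(self, vec: np.ndarray) -> dict[str, float]:
        p, s = self.priors, self._s

        def normal_lp(x, mu, sd):
            return float(np.sum(-0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)))

        def laplace_lp(x, b):
            return float(np.sum(-np.abs(x) / b - np.log(2 * b)))

        return {
            "alpha": normal_lp(vec[s["alpha"]], p.mu_alpha, p.sd_alpha),
            "year_dev": normal_lp(vec[s["year_dev"]], 0.0, p.sd_year),
            "beta_conf": normal_lp(vec[s["beta_conf"]], 0.0, p.sd_conf),
            "beta_other": laplace_lp(vec[s["beta_other"]], p.lasso_scale),
            "rho1": normal_lp(vec[s["rho1"]], p.mu_rho1, p.sd_rho1),
            "rho2": normal_lp(vec[s["rho2"]], p.mu_rho2, p.sd_rho2),
            "beta_inst": normal_lp(vec[s["beta_inst"]], 0.0, p.sd_policy),
            "beta_slope": normal_lp(vec[s["beta_slope"]], 0.0, p.sd_policy),
            "log_phi": normal_lp(vec[s["log_phi"]], p.mu_logphi, p.sd_logphi),
        }

    def log_density(self, vec: np.ndarray) -> float:
        return self.log_likelihood(vec) + float(sum(self.log_prior_terms(vec).values()))

    def logp_and_grad(self, vec: np.ndarray):
        x, p = self.inputs, self.priors
        k = self._k_fix
        rho1, rho2 = vec[k], vec[k + 1]
        b = vec[k + 2 : k + 2 + 2 * N_POLICIES]  # (beta_inst, beta_slope) stacked
        log_phi = vec[k + 2 + 2 * N_POLICIES]

        if self.debias:
            d1 = self._EF1 @ b
            d2 = self._EF2 @ b
            U = self._EF0 - rho1 * self._EF1 - rho2 * self._EF2
        else:
            d1 = d2 = 0.0
            U = self._EF0
        eta = (
            x.log_pop
            + self._Dfix @ vec[:k]
            + rho1 * self._a1c
            + rho2 * self._a2c
            + U @ b
        )

        # inlined NB log-density and derivatives (mean-dispersion form)
        eta_c = np.minimum(np.maximum(eta, -500.0), 500.0)
        phi = float(np.exp(min(max(log_phi, -30.0), 30.0)))
        mu = np.exp(eta_c)
        y = self._yf
        yphi = y + phi
        t = mu + phi
        log_t = np.log(t)
        log_phi_s = np.log(phi)
        ll = (
            gammaln(yphi).sum()
            - self._n * float(gammaln(phi))
            - self._sum_gammaln_y1
            + self._n * phi * log_phi_s
            - phi * log_t.sum()
            + y @ eta_c
            - y @ log_t
        )
        g_eta = y - yphi * (mu / t)
        g_phi = (
            digamma(yphi).sum()
            - self._n * float(digamma(phi))
            + self._n * (log_phi_s + 1.0)
            - log_t.sum()
            - (yphi / t).sum()
        )

        grad = np.empty(self.layout.dim)
        grad[:k] = g_eta @ self._Dfix
        grad[k] = g_eta @ (self._a1c - d1)
        grad[k + 1] = g_eta @ (self._a2c - d2)
        grad[k + 2 : k + 2 + 2 * N_POLICIES] = g_eta @ U
        grad[-1] = g_phi * phi

        # priors: normal blocks fused, lasso block separate
        dv = vec - self._pmu
        lp = ll + self._prior_const - 0.5 * (dv @ (self._pisd2_masked * dv))
        other = vec[self._s["beta_other"]]
        lp -= np.abs(other).sum() / p.lasso_scale
        pgrad = -self._pisd2_masked * dv
        pgrad[self._s["beta_other"]] = -np.sign(other) / p.lasso_scale
        grad += pgrad
        return float(lp), grad

    def initial_vector(self) -> np.ndarray:
        """Data-informed starting point: baseline at the mean observed log rate."""
        x = self.inputs
        vec = np.zeros(self.layout.dim)
        s = self._s
        mean_lograte = float(
            np.mean(np.log((x.y + x.config.continuity) / np.exp(x.log_pop)))
        )
        vec[s["alpha"]] = mean_lograte
        vec[s["log_phi"]] = self.priors.mu_logphi
        return vec


# ---------------------------------------------------------------------------
# Fit results

RHAT_WARN_THRESHOLD = 1.05


@dataclass
class PosteriorDraws:
    """Pooled post-warmup draws with per-parameter diagnostics."""

    raw: np.ndarray               # (chains, draws, dim)
    layout: ParamLayout
    param_names: list[str]
    diagnostics: pd.DataFrame     # parameter, rhat, ess
    metadata: dict

    @property
    def n_draws(self) -> int:
        return self.raw.shape[0] * self.raw.shape[1]

    def pooled(self) -> np.ndarray:
        return self.raw.reshape(-1, self.raw.shape[-1])

    def get(self, name: str) -> np.ndarray:
        idx = self.param_names.index(name)
        return self.pooled()[:, idx]

    def _block(self, block: str) -> np.ndarray:
        return self.pooled()[:, self.layout.slices()[block]]

    @property
    def beta_inst(self) -> np.ndarray:
        return self._block("beta_inst")

    @property
    def beta_slope(self) -> np.ndarray:
        return self._block("beta_slope")

    @property
    def policy_ids(self) -> tuple[str, ...]:
        return POLICY_IDS

    def theta_draws(self) -> np.ndarray:
        """(S, 10) draws of the total per-policy effects."""
        return self.beta_inst + self.beta_slope

    def params_at(self, i: int) -> ModelParams:
        return self.layout.unpack(self.pooled()[i])

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(self.diagnostics["rhat"].to_numpy()))

    @property
    def convergence_warning(self) -> bool:
        return bool(self.max_rhat > RHAT_WARN_THRESHOLD)

    def to_tidy(self) -> pd.DataFrame:
        """Long format: draw, chain, parameter, value."""
        chains, n, dim = self.raw.shape
        recs = {
            "draw": np.tile(np.repeat(np.arange(n), dim), chains),
            "chain": np.repeat(np.arange(chains), n * dim),
            "parameter": np.tile(self.param_names, chains * n),
            "value": self.raw.reshape(-1),
        }
        return pd.DataFrame(recs)

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, years: list[int] | None = None) -> "PosteriorDraws":
        """Rebuild from the tidy CSV format (diagnostics are recomputed)."""
        names = list(dict.fromkeys(df["parameter"]))
        chains = int(df["chain"].max()) + 1
        n = int(df["draw"].max()) + 1
        dim = len(names)
        values = df["value"].to_numpy()
        # relies on the writing order: chain-major, then draw, then parameter
        raw = values.reshape(chains, n, dim)
        n_years = sum(1 for p in names if p.startswith("year_dev_")) + 1
        layout = ParamLayout(n_years)
        diag = pd.DataFrame(
            [
                {
                    "parameter": names[j],
                    "rhat": split_rhat(raw[:, :, j]),
                    "ess": ess_mean(raw[:, :, j]),
                }
                for j in range(dim)
            ]
        )
        return cls(raw=raw, layout=layout, param_names=names, diagnostics=diag, metadata={})


def fit(
    model_inputs: ModelInputs,
    priors: PriorSpec,
    mcmc_config: McmcConfig,
    seed: int,
    debias: bool = True,
) -> PosteriorDraws:
    """Sample the posterior by NUTS.

    Deterministic for fixed (inputs, priors, config, seed).  Raises if the
    posterior density is non-finite at the initial point, naming the term.
    """
    post = Posterior(model_inputs, priors, debias=debias)
    init = post.initial_vector()

    ll = post.log_likelihood(init)
    if not np.isfinite(ll):
        raise ValueError("non-finite log likelihood at the initial point")
    for term, val in post.log_prior_terms(init).items():
        if not np.isfinite(val):
            raise ValueError(f"non-finite log prior at initialization: {term}")

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(mcmc_config.chains)
    all_draws = []
    divergences = 0
    step_sizes = []
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        q0 = init + rng.uniform(-0.02, 0.02, init.shape)
        draws, cstats = _hmc.sample_chain(
            post.logp_and_grad,
            q0,
            mcmc_config.warmup,
            mcmc_config.draws,
            rng,
            target_accept=mcmc_config.target_accept,
            max_treedepth=mcmc_config.max_treedepth,
            dense_mass=mcmc_config.dense_mass,
        )
        all_draws.append(draws)
        divergences += cstats.divergences
        step_sizes.append(cstats.step_size)

    raw = np.stack(all_draws)  # (chains, draws, dim)
    names = post.layout.param_names(model_inputs)
    diag = pd.DataFrame(
        [
            {
                "parameter": names[j],
                "rhat": split_rhat(raw[:, :, j]),
                "ess": ess_mean(raw[:, :, j]),
            }
            for j in range(post.layout.dim)
        ]
    )
    meta = {
        "seed": seed,
        "chains": mcmc_config.chains,
        "warmup": mcmc_config.warmup,
        "draws": mcmc_config.draws,
        "debias": debias,
        "divergences": divergences,
        "step_sizes": step_sizes,
        "prior_mode": priors.mode,
    }
    out = PosteriorDraws(
        raw=raw,
        layout=post.layout,
        param_names=names,
        diagnostics=diag,
        metadata=meta,
    )
    out.metadata["convergence_warning"] = out.convergence_warning
    return out
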