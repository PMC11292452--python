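"""Model inputs and likelihood for the autoregressive negative-binomial panel model.

The observational unit is the state-year.  Counts are negative binomial with a
population offset; the linear predictor combines year effects, covariates,
first- and second-order autoregression on lagged log rates, and policy terms.
The autoregression operates on *counterfactually adjusted* lags — each lagged
log rate has that year's cumulative policy effect subtracted before it is
multiplied by its AR coefficient — so that the equilibrium effect of a fully
phased-in policy on the log rate is exactly its total effect, for any stable
AR coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .policy_coding import DEFAULT_HORIZON, POLICY_IDS

N_POLICIES = len(POLICY_IDS)
N_CONFOUNDERS = 5
N_OTHER = 23

DEFAULT_CONFOUNDERS: tuple[str, ...] = (
    "gun_ownership",
    "political_control",
    "violent_crime_rate",
    "incarceration_rate",
    "income_inequality",
)
DEFAULT_OTHERS: tuple[str, ...] = tuple(f"cov_{i:02d}" for i in range(1, N_OTHER + 1))

OUTCOME_COLUMNS = {
    "total": "deaths_total",
    "suicide": "deaths_suicide",
    "homicide": "deaths_homicide",
}


class ModelDataError(ValueError):
    """Raised when panel data violate the model's input contract."""


@dataclass(frozen=True)
class ModelConfig:
    """Configuration for assembling model inputs from a state-year panel."""

    outcome: str = "total"
    analysis_years: tuple[int, int] | None = None  # default: (min_year + 2, max_year)
    horizon: float = DEFAULT_HORIZON
    continuity: float = 0.5
    confounders: tuple[str, ...] = DEFAULT_CONFOUNDERS
    others: tuple[str, ...] = DEFAULT_OTHERS
    standardize: bool = True
    #: constant subtracted from the lagged log rates before they enter the
    #: autoregression.  Pure reparameterization (absorbed by the year effects)
    #: that decorrelates the AR coefficients from the intercept; None means
    #: "use the mean lagged log rate over analysis rows".
    lag_center: float | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ModelDataError(
                f"unknown outcome {self.outcome!r}; expected one of {sorted(OUTCOME_COLUMNS)}"
            )
        if len(self.confounders) != N_CONFOUNDERS:
            raise ModelDataError(f"expected {N_CONFOUNDERS} confounder columns")
        if len(self.others) != N_OTHER:
            raise ModelDataError(f"expected {N_OTHER} other covariate columns")
        if self.continuity <= 0:
            raise ModelDataError("continuity constant must be positive")

    @property
    def count_column(self) -> str:
        return OUTCOME_COLUMNS[self.outcome]


@dataclass
class ModelInputs:
    """Design arrays for the analysis rows, ordered by (state, year).

    Lag years (the two years before the first analysis year) are consumed only
    through the lagged log-rate and lagged policy columns.
    """

    states: list[str]
    years: np.ndarray            # analysis years, ascending
    row_state: np.ndarray        # (n,) state index
    row_year: np.ndarray         # (n,) year index into `years`
    y: np.ndarray                # (n,) counts
    log_pop: np.ndarray          # (n,) offset
    x_conf: np.ndarray           # (n, 5)
    x_other: np.ndarray          # (n, 23)
    a1: np.ndarray               # (n,) lagged log rate, t-1
    a2: np.ndarray               # (n,) lagged log rate, t-2
    E0: np.ndarray               # (n, 10) exposure, current year
    F0: np.ndarray               # (n, 10) phase, current year
    E1: np.ndarray               # (n, 10) exposure, lag 1
    F1: np.ndarray
    E2: np.ndarray               # (n, 10) exposure, lag 2
    F2: np.ndarray
    lag_center: float = 0.0
    config: ModelConfig = field(default_factory=ModelConfig)
    conf_names: tuple[str, ...] = DEFAULT_CONFOUNDERS
    other_names: tuple[str, ...] = DEFAULT_OTHERS
    conf_mean: np.ndarray | None = None
    conf_sd: np.ndarray | None = None
    other_mean: np.ndarray | None = None
    other_sd: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def n_years(self) -> int:
        return self.years.shape[0]


@dataclass
class ModelParams:
    """One full set of model parameters.

    ``gamma`` holds the absolute year effect for each analysis year; the first
    year is the reference level (its value doubles as the intercept).  The
    total policy effect ``theta`` is always derived, never free.
    """

    gamma: np.ndarray            # (n_years,)
    beta_conf: np.ndarray        # (5,)
    beta_other: np.ndarray       # (23,)
    rho1: float
    rho2: float
    beta_inst: np.ndarray        # (10,)
    beta_slope: np.ndarray       # (10,)
    phi: float

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta_conf = np.asarray(self.beta_conf, dtype=float)
        self.beta_other = np.asarray(self.beta_other, dtype=float)
        self.beta_inst = np.asarray(self.beta_inst, dtype=float)
        self.beta_slope = np.asarray(self.beta_slope, dtype=float)
        if self.beta_conf.shape != (N_CONFOUNDERS,):
            raise ModelDataError("beta_conf must have length 5")
        if self.beta_other.shape != (N_OTHER,):
            raise ModelDataError("beta_other must have length 23")
        if self.beta_inst.shape != (N_POLICIES,) or self.beta_slope.shape != (N_POLICIES,):
            raise ModelDataError("policy coefficient vectors must have length 10")
        if not self.phi > 0:
            raise ModelDataError(f"dispersion phi must be positive, got {self.phi}")

    @property
    def theta(self) -> np.ndarray:
        """Total (equilibrium) effect per policy: instant + fully phased slope."""
        return self.beta_inst + self.beta_slope


# ---------------------------------------------------------------------------
# Elementary operations

def lag_log_rate(y, N, continuity: float = 0.5):
    """Log rate ``ln((y + c) / N)`` with a continuity constant for zero counts."""
    y = np.asarray(y, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ModelDataError("population must be positive")
    if np.any(y < 0):
        raise ModelDataError("counts must be nonnegative")
    return np.log((y + continuity) / N)


def cumulative_policy_effect(beta_inst, beta_slope, e_row, f_row):
    """Cumulative log-scale policy effect: sum_p (beta_inst_p e_p + beta_slope_p f_p).

    Accepts single rows (length 10) or matrices (n, 10); returns scalar or (n,).
    """
    beta_inst = np.asarray(beta_inst, dtype=float)
    beta_slope = np.asarray(beta_slope, dtype=float)
    e_row = np.asarray(e_row, dtype=float)
    f_row = np.asarray(f_row, dtype=float)
    if beta_inst.shape[-1] != e_row.shape[-1] or beta_slope.shape[-1] != f_row.shape[-1]:
        raise ModelDataError(
            f"policy vector length mismatch: beta {beta_inst.shape[-1]}, "
            f"design {e_row.shape[-1]}"
        )
    return e_row @ beta_inst + f_row @ beta_slope


def linear_predictor(inputs: ModelInputs, params: ModelParams, debias: bool = True):
    """Linear predictor eta for every analysis row.

    eta = log N + gamma_t + x'beta + rho1 (a1 - c - D1) + rho2 (a2 - c - D2) + D0,
    where D_k is the cumulative policy effect at lag k and ``c`` the lag
    centering constant.  With ``debias=False`` the counterfactual adjustments
    D1, D2 are dropped (naive autoregression).
    """
    d0 = cumulative_policy_effect(params.beta_inst, params.beta_slope, inputs.E0, inputs.F0)
    if debias:
        d1 = cumulative_policy_effect(params.beta_inst, params.beta_slope, inputs.E1, inputs.F1)
        d2 = cumulative_policy_effect(params.beta_inst, params.beta_slope, inputs.E2, inputs.F2)
    else:
        d1 = d2 = 0.0
    c = inputs.lag_center
    return (
        inputs.log_pop
        + params.gamma[inputs.row_year]
        + inputs.x_conf @ params.beta_conf
        + inputs.x_other @ params.beta_other
        + params.rho1 * (inputs.a1 - c - d1)
        + params.rho2 * (inputs.a2 - c - d2)
        + d0
    )


def nb_log_density(y, mu, phi):
    """Negative-binomial log pmf, mean-dispersion form (Var = mu + mu^2/phi)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ModelDataError("y must be a nonnegative integer")
    if np.any(mu <= 0):
        raise ModelDataError("mu must be positive")
    if not phi > 0:
        raise ModelDataError("phi must be positive")
    return (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1)
        + phi * np.log(phi / (phi + mu))
        + y * np.log(mu / (phi + mu))
    )


def nb_dlogp_deta(y, mu, phi):
    """d log NB / d eta where mu = exp(eta)."""
    return y - (y + phi) * mu / (mu + phi)


def nb_dlogp_dphi(y, mu, phi):
    """d log NB / d phi at fixed mu."""
    return (
        digamma(y + phi)
        - digamma(phi)
        + np.log(phi / (phi + mu))
        + 1.0
        - (y + phi) / (mu + phi)
    )


def deterministic_recursion(
    const: float,
    rho1: float,
    rho2: float,
    deltas,
    n_steps: int,
    a_init: float = 0.0,
):
    """Noise-free forward recursion of the log rate.

    a_t = const + rho1 (a_{t-1} - d) + rho2 (a_{t-2} - d) + d, with ``d`` the
    cumulative policy effect (constant here).  Returns the path of length
    ``n_steps``.  Used to verify the equilibrium-effect property: at a stable
    fixed point the shift from ``d`` is exactly ``d``.
    """
    a_prev2 = a_prev1 = a_init
    path = np.empty(n_steps)
    for t in range(n_steps):
        a = const + rho1 * (a_prev1 - deltas) + rho2 * (a_prev2 - deltas) + deltas
        path[t] = a
        a_prev2, a_prev1 = a_prev1, a
    return path


# ---------------------------------------------------------------------------
# Input assembly

def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ModelDataError(f"{what} missing columns: {missing}")


def build_model_inputs(
    panel: pd.DataFrame,
    policy_panel: pd.DataFrame,
    config: ModelConfig | None = None,
) -> ModelInputs:
    """Assemble design arrays from a state-year panel and a policy panel.

    The panel must cover at least two years before the first analysis year
    (consumed as lags).  Covariates are standardized to mean 0 / SD 1 over the
    analysis rows (unless ``config.standardize`` is off).  Any missing
    state-year or covariate cell is rejected with the offending cells named.
    """
    config = config or ModelConfig()
    count_col = config.count_column
    _require_columns(
        panel,
        ["state", "year", "population", count_col, *config.confounders, *config.others],
        "panel",
    )
    _require_columns(
        policy_panel, ["state", "year", "policy_id", "exposure", "phase"], "policy panel"
    )

    panel = panel.sort_values(["state", "year"]).reset_index(drop=True)
    states = sorted(panel["state"].unique())
    all_years = np.sort(panel["year"].unique())
    if config.analysis_years is None:
        first, last = int(all_years[0]) + 2, int(all_years[-1])
    else:
        first, last = config.analysis_years
    if first - 2 < all_years[0]:
        raise ModelDataError(
            f"panel must start at or before {first - 2} to provide two lag years "
            f"for analysis starting {first}; panel starts {all_years[0]}"
        )
    if last > all_years[-1]:
        raise ModelDataError(f"analysis end {last} beyond panel end {all_years[-1]}")
    years = np.arange(first, last + 1)
    needed_years = np.arange(first - 2, last + 1)

    # Completeness: every state must have every needed year exactly once.
    cell_index = pd.MultiIndex.from_product(
        [states, needed_years], names=["state", "year"]
    )
    have = pd.MultiIndex.from_frame(panel[["state", "year"]])
    if have.has_duplicates:
        dups = panel[panel.duplicated(["state", "year"], keep=False)]
        raise ModelDataError(
            f"duplicate state-year rows: {dups[['state', 'year']].values.tolist()[:5]}"
        )
    missing_cells = cell_index.difference(have)
    if len(missing_cells):
        raise ModelDataError(
            f"missing state-year rows: {list(missing_cells[:5])}"
            + ("..." if len(missing_cells) > 5 else "")
        )

    sub = panel.set_index(["state", "year"]).loc[cell_index].reset_index()
    value_cols = ["population", count_col, *config.confounders, *config.others]
    bad = sub[value_cols].isna()
    if bad.any().any():
        locs = []
        for col in value_cols:
            for i in np.flatnonzero(bad[col].values)[:3]:
                locs.append((sub.loc[i, "state"], int(sub.loc[i, "year"]), col))
        raise ModelDataError(f"missing values at (state, year, column): {locs}")

    pop = sub["population"].to_numpy(dtype=float)
    counts = sub[count_col].to_numpy(dtype=float)
    if np.any(pop <= 0):
        raise ModelDataError("population must be positive in every state-year")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ModelDataError(f"{count_col} must be nonnegative integers")

    n_states = len(states)
    n_all = len(needed_years)
    # (state, year) grids, ordered by state then year.
    counts_g = counts.reshape(n_states, n_all)
    pop_g = pop.reshape(n_states, n_all)
    a_g = lag_log_rate(counts_g, pop_g, config.continuity)

    analysis = slice(2, n_all)
    y = counts_g[:, analysis].reshape(-1)
    log_pop = np.log(pop_g[:, analysis]).reshape(-1)
    a1 = a_g[:, 1:-1].reshape(-1)
    a2 = a_g[:, :-2].reshape(-1)

    def grab_cov(names):
        mats = [
            sub[c].to_numpy(dtype=float).reshape(n_states, n_all)[:, analysis].reshape(-1)
            for c in names
        ]
        return np.column_stack(mats)

    x_conf = grab_cov(config.confounders)
    x_other = grab_cov(config.others)
    conf_mean = conf_sd = other_mean = other_sd = None
    if config.standardize:
        conf_mean, conf_sd = x_conf.mean(axis=0), x_conf.std(axis=0)
        other_mean, other_sd = x_other.mean(axis=0), x_other.std(axis=0)
        for sd, names in ((conf_sd, config.confounders), (other_sd, config.others)):
            zero = [n for n, s in zip(names, sd) if s == 0]
            if zero:
                raise ModelDataError(f"constant covariate columns cannot be standardized: {zero}")
        x_conf = (x_conf - conf_mean) / conf_sd
        x_other = (x_other - other_mean) / other_sd

    # Policy matrices for analysis years and their two lags.
    pp = policy_panel.pivot_table(
        index=["state", "year"], columns="policy_id", values=["exposure", "phase"]
    )
    pol_have = pp.index
    pol_needed = cell_index.difference(pol_have)
    if len(pol_needed):
        raise ModelDataError(
            f"policy panel missing state-years: {list(pol_needed[:5])}"
        )

    def policy_mat(kind: str, lag: int) -> np.ndarray:
        idx = pd.MultiIndex.from_arrays(
            [
                np.repeat(states, len(years)),
                np.tile(years - lag, n_states),
            ]
        )
        mat = pp[kind].reindex(columns=list(POLICY_IDS)).loc[idx]
        if mat.isna().any().any():
            raise ModelDataError(f"policy panel has missing {kind} values")
        return mat.to_numpy(dtype=float)

    E0, F0 = policy_mat("exposure", 0), policy_mat("phase", 0)
    E1, F1 = policy_mat("exposure", 1), policy_mat("phase", 1)
    E2, F2 = policy_mat("exposure", 2), policy_mat("phase", 2)

    row_state = np.repeat(np.arange(n_states), len(years))
    row_year = np.tile(np.arange(len(years)), n_states)
    lag_center = (
        float(np.mean(a1)) if config.lag_center is None else float(config.lag_center)
    )
    return ModelInputs(
        states=states,
        years=years,
        row_state=row_state,
        row_year=row_year,
        y=y.astype(np.int64),
        log_pop=log_pop,
        x_conf=x_conf,
        x_other=x_other,
        a1=a1,
        a2=a2,
        E0=E0,
        F0=F0,
        E1=E1,
        F1=F1,
        E2=E2,
        F2=F2,
        lag_center=lag_center,
        config=config,
        conf_names=tuple(config.confounders),
        other_names=tuple(config.others),
        conf_mean=conf_mean,
        conf_sd=conf_sd,
        other_mean=other_mean,
        other_sd=other_sd,
    )
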