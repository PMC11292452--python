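import numpy as np
import pytest

import policyfx as px
from policyfx.evaluation import calibration_priors
from policyfx.model_core import ModelConfig, build_model_inputs
from policyfx.policy_coding import build_policy_panel


@pytest.fixture(scope="session")
def small_sim():
    """A small confounded synthetic dataset shared across tests."""
    cfg = px.SimConfig(
        n_states=8,
        start_year=1979,
        end_year=1994,
        burn_in=6,
        rho1=0.35,
        rho2=0.10,
        phi=33.0,
        adoption=(
            px.AdoptionConfig(policy_id="child_access_storage", intercept=-1.5),
        ),
    )
    panel, laws, truth = px.simulate_dataset(cfg, seed=7)
    return cfg, panel, laws, truth


@pytest.fixture(scope="session")
def small_inputs(small_sim):
    cfg, panel, laws, truth = small_sim
    pol = build_policy_panel(
        laws, sorted(panel["state"].unique()), sorted(panel["year"].unique())
    )
    return build_model_inputs(
        panel, pol, ModelConfig(standardize=False, lag_center=cfg.lag_center)
    )


@pytest.fixture(scope="session")
def small_fit(small_inputs):
    """One converged small fit, reused wherever posterior draws are needed."""
    return px.fit(
        small_inputs,
        calibration_priors(),
        px.McmcConfig(chains=2, warmup=300, draws=250),
        seed=3,
    )
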