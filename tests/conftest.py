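from __future__ import annotations

import numpy as np
import pytest

from yukon_ipm.inference import MCMCConfig, PosteriorEnsemble
from yukon_ipm.model import IPMModel
from yukon_ipm.synthetic import make_fixture


@pytest.fixture(scope="session")
def tiny_bundle():
    """8-year synthetic dataset for fast structural tests."""
    return make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def paper_bundle():
    """Full 21-year (2003-2023 layout) synthetic dataset."""
    return make_fixture("paper_scale", seed=11)


@pytest.fixture(scope="session")
def paper_model(paper_bundle):
    scn, truth, data = paper_bundle
    return IPMModel(scn.dims, data)


def make_pseudo_ensemble(truth, data, n_chains=2, n_draws=40, jitter=0.03,
                         seed=0) -> PosteriorEnsemble:
    """A posterior-like ensemble centered on the generating values.

    Packs the generator's parameters (plus small lognormal jitter on the
    positive quantities) into the sampler's unconstrained layout, giving a
    coherent draw set for scenario and projection machinery without any
    MCMC.  Draw 0 of chain 0 is exactly the generating configuration.
    """
    rng = np.random.default_rng(seed)
    scn = truth.scenario
    model = IPMModel(scn.dims, data)
    Y = scn.dims.n_years
    st = truth.state

    def logit(p):
        return np.log(p) - np.log1p(-p)

    base = {
        "log_alpha": truth.ricker.log_alpha,
        "beta": truth.ricker.beta,
        "sigma_R": truth.ricker.sigma_R,
        "sigma_M": truth.errors.sigma_M,
        "sigma_B_proc": truth.errors.sigma_B_proc,
        "sigma_lambda": truth.errors.sigma_lambda,
        "sigma_T": truth.errors.sigma_T,
        "sB": np.asarray(truth.schedules.sB),
        "v": np.asarray(truth.schedules.v),
        "sT": np.asarray(truth.schedules.sT),
        "M_init_log": float(np.log(truth.rates.M[0])),
        "FB_init_log": float(np.log(truth.rates.FB[0])),
        "lam_init": float(truth.rates.lam[0]),
        "FT_init_log": float(np.log(truth.rates.FT[0])),
        "muG": truth.muG,
        "sigmaG": truth.sigmaG,
        "z_M": truth.errors.eps_M / truth.errors.sigma_M,
        "z_B": truth.errors.eps_B / truth.errors.sigma_B_proc,
        "z_T": truth.errors.eps_T / truth.errors.sigma_T,
        "z_lambda": truth.errors.eps_lambda / truth.errors.sigma_lambda,
        "logit_vt": logit(truth.vartheta).ravel(),
        "log_N2": np.log(st.entering[:, 0]),
        "log_R0": np.log(truth.init.N_init_by_age),
    }
    u_center = model.pack(base)

    draws = np.empty((n_chains, n_draws, model.n_params))
    for c in range(n_chains):
        for d in range(n_draws):
            if c == 0 and d == 0:
                draws[c, d] = u_center
            else:
                draws[c, d] = u_center + jitter * rng.standard_normal(
                    model.n_params)

    zeros = np.zeros((n_chains, n_draws))
    return PosteriorEnsemble(
        model=model, u_draws=draws, logp=zeros.copy(), energy=zeros.copy(),
        divergent=zeros.astype(bool), tree_depth=zeros.astype(int),
        accept_stat=zeros.copy(), step_size=np.full(n_chains, 0.1),
        config=MCMCConfig(n_chains=n_chains, n_iter=2 * n_draws,
                          n_warmup=n_draws, seed=seed),
    )


@pytest.fixture(scope="session")
def pseudo_ensemble(paper_bundle):
    scn, truth, data = paper_bundle
    return make_pseudo_ensemble(truth, data, n_chains=2, n_draws=40, seed=3)
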