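"""Diagnostics, priors, and posterior predictive checks.

Full MCMC recovery runs live in the acceptance suite; here the diagnostic
report and predictive machinery are exercised on constructed ensembles whose
properties are known exactly.
"""

import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import norm

from yukon_ipm.inference import (MCMCConfig, diagnostics,
                                 posterior_predictive)
from yukon_ipm.priors import PriorConfig, TruncNormal, log_prior


def _with_draws(ens, u_draws):
    return dataclasses.replace(
        ens, u_draws=u_draws,
        logp=np.zeros(u_draws.shape[:2]),
        energy=np.zeros(u_draws.shape[:2]),
        divergent=np.zeros(u_draws.shape[:2], dtype=bool),
        tree_depth=np.zeros(u_draws.shape[:2], dtype=int),
        accept_stat=np.zeros(u_draws.shape[:2]),
        step_size=np.full(u_draws.shape[0], 0.1))


class TestDiagnostics:
    def test_iid_draws_pass_rhat_and_ess(self, pseudo_ensemble):
        rng = np.random.default_rng(0)
        d = pseudo_ensemble.model.n_params
        u = rng.standard_normal((4, 1000, d)) * 0.3
        ens = _with_draws(pseudo_ensemble, u)
        rep = diagnostics(ens, ess_limit=1000)
        assert rep["max_rhat"] <= 1.01
        # ESS of independent draws is close to the total draw count
        assert rep["min_ess_bulk"] > 0.7 * 4000
        assert rep["n_divergent"] == 0

    def test_shifted_chains_flagged(self, pseudo_ensemble):
        rng = np.random.default_rng(1)
        d = pseudo_ensemble.model.n_params
        u = rng.standard_normal((2, 400, d)) * 0.1
        u[1] += 2.0  # identical spread, different means
        rep = diagnostics(_with_draws(pseudo_ensemble, u))
        assert rep["max_rhat"] > 1.5
        assert not rep["passed"]

    def test_single_chain_rejected(self, pseudo_ensemble):
        u = pseudo_ensemble.u_draws[:1]
        with pytest.raises(ValueError, match="two chains"):
            diagnostics(_with_draws(pseudo_ensemble, u))

    def test_bfmi_detects_poor_energy_exploration(self):
        from yukon_ipm.inference import _bfmi
        rng = np.random.default_rng(2)
        # independent energies: consecutive differences match the spread
        good = rng.standard_normal((2, 500))
        assert np.all(_bfmi(good) > 0.5)
        # sticky energies: a slow random walk changes little per step
        sticky = rng.standard_normal((2, 500)).cumsum(axis=1) * 0.05
        assert np.all(_bfmi(sticky) < 0.3)


class TestPriors:
    def test_table_prior_log_densities(self):
        cfg = PriorConfig()
        # unbounded normal at its mean: -log(sd * sqrt(2 pi))
        got = log_prior({"log_alpha": 0.0}, cfg)
        assert got == pytest.approx(-math.log(12.5 * math.sqrt(2 * math.pi)),
                                    abs=1e-6)
        # half-normal includes the truncation constant log(2)
        half = log_prior({"sigma_R": 0.0}, cfg)
        assert half == pytest.approx(
            math.log(2) - math.log(5 * math.sqrt(2 * math.pi)), abs=1e-6)

    def test_bounds_closed_and_outside_rejected(self):
        cfg = PriorConfig()
        assert np.isfinite(log_prior({"v": np.array([0.5, 1.0, 0.7, 0.9])},
                                     cfg))
        assert log_prior({"v": np.array([0.4, 1.0, 0.7, 0.9])}, cfg) \
            == -math.inf

    def test_wider_priors_are_flatter_at_the_mean(self):
        narrow = TruncNormal(0.0, 1.0)
        wide = TruncNormal(0.0, 2.0)
        assert narrow.logpdf(0.0) > wide.logpdf(0.0)

    def test_truncated_sampling_respects_bounds_and_quantiles(self):
        tn = TruncNormal(0.0, 1.0, lower=0.0, upper=1.0)
        rng = np.random.default_rng(3)
        x = tn.sample(rng, 20000)
        assert x.min() >= 0 and x.max() <= 1
        # median of N(0,1) truncated to [0,1]: Phi^{-1}((Phi(0)+Phi(1))/2)
        expect = norm.ppf((norm.cdf(0) + norm.cdf(1)) / 2)
        assert np.median(x) == pytest.approx(expect, abs=0.01)


class TestPosteriorPredictive:
    def test_self_consistent_data_is_covered(self, paper_bundle,
                                             pseudo_ensemble):
        """Data simulated from the model at the generating parameters should
        fall inside the replicated 95% intervals at roughly the nominal
        rate."""
        scn, truth, data = paper_bundle
        out = posterior_predictive(pseudo_ensemble, data, n_rep=60,
                                   rng=np.random.default_rng(4))
        cov = out["coverage"]
        for stream in ("J", "E", "C", "b_total"):
            assert cov[stream] >= 0.8, (stream, cov)
        assert np.mean(list(cov.values())) >= 0.85

    def test_masked_streams_produce_no_replicates(self, paper_bundle,
                                                  pseudo_ensemble):
        scn, truth, data = paper_bundle
        out = posterior_predictive(pseudo_ensemble, data, n_rep=10,
                                   rng=np.random.default_rng(5))
        rep = out["replicates"]
        missing = ~data.J_mask
        assert np.isnan(rep["J"][:, missing]).all()
        assert np.isnan(rep["x"][:, ~data.gsi_mask]).all()

    def test_replicated_compositions_are_simplexes(self, paper_bundle,
                                                   pseudo_ensemble):
        scn, truth, data = paper_bundle
        out = posterior_predictive(pseudo_ensemble, data, n_rep=8,
                                   rng=np.random.default_rng(6))
        for key in ("qE", "qC", "qB"):
            q = out["replicates"][key]
            sums = np.nansum(q, axis=2)
            ok = ~np.isnan(q).any(axis=2)
            np.testing.assert_allclose(sums[ok], 1.0, atol=1e-9)


class TestFitContract:
    def test_same_seed_same_draw_summaries(self):
        from yukon_ipm.inference import fit
        from yukon_ipm.synthetic import make_fixture

        _, _, data = make_fixture("tiny", seed=6)
        cfg = MCMCConfig(n_chains=2, n_iter=300, n_warmup=150, seed=5,
                         target_accept=0.85, max_treedepth=8)
        a = fit(data, mcmc=cfg)
        b = fit(data, mcmc=cfg)
        np.testing.assert_array_equal(a.u_draws, b.u_draws)
        np.testing.assert_array_equal(a.energy, b.energy)

    def test_prior_only_fit_recovers_prior_marginals(self):
        """With every observation masked, the marginal posterior of each
        top-level parameter is its prior (the latent states integrate out
        along the causal recursion); checked against direct truncated-normal
        sampling within loose Monte Carlo error."""
        from yukon_ipm.inference import fit
        from yukon_ipm.priors import PriorConfig
        from yukon_ipm.synthetic import make_fixture

        scn, truth, data = make_fixture("tiny", seed=12)
        data.J_mask = np.zeros_like(data.J_mask)
        data.gsi_mask = np.zeros_like(data.gsi_mask)
        data.adult_mask = np.zeros_like(data.adult_mask)
        data.bycatch_mask = np.zeros_like(data.bycatch_mask)
        ens = fit(data, mcmc=MCMCConfig(n_chains=2, n_iter=1500,
                                        n_warmup=500, seed=3,
                                        target_accept=0.9,
                                        max_treedepth=9))
        p = PriorConfig()
        rng = np.random.default_rng(0)
        for name in ("log_alpha", "M_init_log", "lam_init"):
            draws = ens.flat_param(name)
            ref = getattr(p, name).sample(rng, 40000)
            sd = ref.std()
            assert abs(draws.mean() - ref.mean()) < 0.6 * sd, name
            assert 0.5 < draws.std() / sd < 1.6, name
        v = ens.flat_param("v")
        assert v.min() >= 0.5 and v.max() <= 1.0
        ref_v = p.v.sample(rng, 40000)
        assert abs(v.mean() - ref_v.mean()) < 0.1


class TestMCMCConfig:
    def test_paper_defaults(self):
        cfg = MCMCConfig()
        assert (cfg.n_chains, cfg.n_iter, cfg.n_warmup) == (5, 15000, 5000)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, n_warmup=100)
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=0)
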