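"""Likelihood terms vs generic scipy density oracles, and masking rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from yukon_ipm.observation import (ObservationErrorConfig,
                                   StockCompositionModel, joint_loglik,
                                   loglik_agecomp, loglik_lognormal_index,
                                   loglik_stock_assignment,
                                   loglik_stock_hierarchy,
                                   proportions_to_counts)


class TestLognormalIndex:
    def test_matches_scipy_at_the_median(self):
        # location log(pred): pred is the median of the sampling distribution
        got = loglik_lognormal_index(100.0, 100.0, 0.25)
        ref = stats.lognorm.logpdf(100.0, s=0.25, scale=100.0)
        assert got == pytest.approx(ref, abs=1e-12)
        assert got == pytest.approx(-4.13782, abs=1e-4)

    @given(obs=st.floats(1.0, 1e6), pred=st.floats(1.0, 1e6),
           sigma=st.floats(0.05, 1.5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_scipy_everywhere(self, obs, pred, sigma):
        got = loglik_lognormal_index(obs, pred, sigma)
        ref = stats.lognorm.logpdf(obs, s=sigma, scale=pred)
        assert got == pytest.approx(ref, abs=1e-8)

    def test_density_integrates_to_one(self):
        from scipy.integrate import quad
        val, _ = quad(lambda x: math.exp(
            loglik_lognormal_index(x, 50.0, 0.3)), 1e-6, 5000, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mode_at_median_times_shrink(self):
        pred, sigma = 100.0, 0.25
        mode = pred * math.exp(-sigma ** 2)
        dens = lambda x: loglik_lognormal_index(x, pred, sigma)
        assert dens(mode) > dens(mode * 1.01)
        assert dens(mode) > dens(mode * 0.99)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            loglik_lognormal_index(-1.0, 10.0, 0.2)
        with pytest.raises(ValueError):
            loglik_lognormal_index(1.0, 0.0, 0.2)


class TestAgecomp:
    def test_concentrated_composition_value(self):
        # all 100 effective samples in one age class against uniform
        # predictions: 100*log(0.25) and a trivial multinomial coefficient
        got = loglik_agecomp(np.array([1, 0, 0, 0.0]), 100,
                             np.full(4, 0.25))
        assert got == pytest.approx(100 * math.log(0.25), abs=1e-3)
        assert got == pytest.approx(-138.629, abs=1e-3)

    def test_matches_scipy_multinomial(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pi = rng.dirichlet(np.ones(4))
            counts = rng.multinomial(100, pi)
            q = counts / 100
            got = loglik_agecomp(q, 100, pi)
            ref = stats.multinomial.logpmf(counts, 100, pi)
            assert got == pytest.approx(ref, abs=1e-8)

    def test_observed_composition_maximizes_density(self):
        q = np.array([0.1, 0.4, 0.3, 0.2])
        at_truth = loglik_agecomp(q, 100, q)
        rng = np.random.default_rng(2)
        for _ in range(20):
            other = rng.dirichlet(np.ones(4))
            assert loglik_agecomp(q, 100, other) <= at_truth + 1e-12

    def test_permutation_invariance(self):
        q = np.array([0.5, 0.2, 0.2, 0.1])
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        perm = [2, 0, 3, 1]
        assert loglik_agecomp(q, 100, pi) == pytest.approx(
            loglik_agecomp(q[perm], 100, pi[perm]), abs=1e-12)

    def test_zero_prediction_with_positive_count_is_minus_inf(self):
        got = loglik_agecomp(np.array([0.5, 0.5, 0, 0.0]), 10,
                             np.array([1.0, 0.0, 0.0, 0.0]))
        assert got == -math.inf

    def test_count_repair_sums_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            q = rng.dirichlet(np.ones(4) * 0.4)
            c = proportions_to_counts(q, 100)
            assert c.sum() == 100
            assert np.all(c >= 0)
            assert np.abs(c - q * 100).max() < 1.0 + 1e-9


class TestStockAssignment:
    def test_matches_binomial_pmf(self):
        got = loglik_stock_assignment(5, 10, 0.5)
        assert got == pytest.approx(math.log(math.comb(10, 5) * 0.5 ** 10),
                                    abs=1e-12)
        assert got == pytest.approx(-1.40204, abs=1e-4)

    def test_zero_successes_low_proportion_limit(self):
        assert loglik_stock_assignment(0, 10, 1e-12) == pytest.approx(
            0.0, abs=1e-9)

    def test_pmf_normalizes(self):
        n, p = 10, 0.37
        total = sum(math.exp(loglik_stock_assignment(x, n, p))
                    for x in range(n + 1))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_x_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            loglik_stock_assignment(11, 10, 0.5)


class TestHierarchy:
    def test_standard_normal_cell(self):
        # logit(0.5) = 0 against Normal(0, 1)
        got = loglik_stock_hierarchy(np.full((1, 4), 0.5), np.zeros(4),
                                     np.ones(4))
        assert got == pytest.approx(4 * -0.918939, abs=1e-4)

    def test_matches_scipy_logit_normal(self):
        rng = np.random.default_rng(4)
        vt = rng.uniform(0.01, 0.4, (6, 4))
        muG = rng.normal(0, 1, 4)
        sigmaG = rng.uniform(0.2, 2.0, 4)
        from scipy.special import logit
        ref = stats.norm.logpdf(logit(vt), muG, sigmaG).sum()
        got = loglik_stock_hierarchy(vt, muG, sigmaG)
        assert got == pytest.approx(ref, abs=1e-8)

    def test_density_peaks_at_hierarchy_mean(self):
        from scipy.special import expit
        muG = np.array([-3.0, -2.5, -2.0, -3.5])
        sigmaG = np.full(4, 0.5)
        center = expit(muG)[None, :]
        at_center = loglik_stock_hierarchy(center, muG, sigmaG)
        # note: density over logit scale, maximum at logit(vt) = muG
        shifted = expit(muG + 0.3)[None, :]
        assert at_center > loglik_stock_hierarchy(shifted, muG, sigmaG)


class TestJointLoglik:
    def test_equals_sum_of_independent_terms(self, paper_bundle):
        scn, truth, data = paper_bundle
        st_ = truth.state
        cfg = scn.obs
        gsi = StockCompositionModel(vartheta=truth.vartheta, muG=truth.muG,
                                    sigmaG=truth.sigmaG)
        total = joint_loglik(st_, data, cfg, gsi)

        # independent accumulation with generic density calls
        acc = 0.0
        Y = scn.dims.n_years
        for y in range(Y):
            if data.J_mask[y]:
                acc += stats.lognorm.logpdf(data.J[y], s=cfg.sigma_J,
                                            scale=st_.entering[y, 0])
            acc += stats.lognorm.logpdf(data.E[y], s=cfg.sigma_E,
                                        scale=st_.S_total[y])
            acc += stats.lognorm.logpdf(data.C[y], s=cfg.sigma_C,
                                        scale=st_.H_total[y])
            acc += loglik_agecomp(data.qE[y], cfg.neff_E, st_.pi_S[y])
            acc += loglik_agecomp(data.qC[y], cfg.neff_C, st_.pi_H[y])
            acc += loglik_agecomp(data.qB[y], float(data.nB[y]), st_.pi_B[y])
            acc += stats.lognorm.logpdf(data.b_total[y], s=cfg.sigma_b,
                                        scale=st_.BA[y, 1:5].sum())
            for j in range(4):
                if data.gsi_mask[y, j]:
                    acc += stats.binom.logpmf(data.x[y, j],
                                              data.n[y, j],
                                              truth.vartheta[y, j])
        acc += loglik_stock_hierarchy(truth.vartheta, truth.muG, truth.sigmaG)
        assert total == pytest.approx(acc, abs=1e-8)

    def test_fully_masked_dataset_contributes_nothing(self, paper_bundle):
        scn, truth, data = paper_bundle
        import dataclasses
        masked = dataclasses.replace(
            data,
            J_mask=np.zeros_like(data.J_mask),
            gsi_mask=np.zeros_like(data.gsi_mask),
            adult_mask=np.zeros(scn.dims.n_years, dtype=bool),
            bycatch_mask=np.zeros(scn.dims.n_years, dtype=bool))
        gsi = StockCompositionModel(vartheta=truth.vartheta, muG=truth.muG,
                                    sigmaG=truth.sigmaG)
        assert joint_loglik(truth.state, masked, scn.obs, gsi,
                            include_hierarchy=False) == 0.0

    def test_masked_entries_do_not_change_value(self, paper_bundle):
        # corrupting a masked year's record must leave the value unchanged
        scn, truth, data = paper_bundle
        import dataclasses
        gsi = StockCompositionModel(vartheta=truth.vartheta, muG=truth.muG,
                                    sigmaG=truth.sigmaG)
        base = joint_loglik(truth.state, data, scn.obs, gsi)
        J2 = data.J.copy()
        J2[~data.J_mask] = 12345.0
        corrupted = dataclasses.replace(data, J=J2)
        assert joint_loglik(truth.state, corrupted, scn.obs, gsi) == base

    def test_wider_juvenile_error_lowers_peak(self, paper_bundle):
        scn, truth, data = paper_bundle
        import dataclasses
        gsi = StockCompositionModel(vartheta=truth.vartheta, muG=truth.muG,
                                    sigmaG=truth.sigmaG)
        # at obs == pred the lognormal peak height falls as sigma grows;
        # compare the juvenile term in isolation
        perfect = dataclasses.replace(
            data, J=truth.state.entering[:, 0].copy(),
            adult_mask=np.zeros(scn.dims.n_years, dtype=bool),
            bycatch_mask=np.zeros(scn.dims.n_years, dtype=bool),
            gsi_mask=np.zeros_like(data.gsi_mask))
        narrow = joint_loglik(truth.state, perfect,
                              ObservationErrorConfig(sigma_J=0.25), gsi,
                              include_hierarchy=False)
        wide = joint_loglik(truth.state, perfect,
                            ObservationErrorConfig(sigma_J=0.5), gsi,
                            include_hierarchy=False)
        assert wide < narrow


class TestDatasetValidation:
    def test_simplex_violation_names_year_and_sum(self, tiny_bundle):
        scn, truth, data = tiny_bundle
        import dataclasses
        qE = data.qE.copy()
        qE[2, 0] += 0.02
        bad = dataclasses.replace(data, qE=qE)
        with pytest.raises(ValueError, match="2005"):
            bad.validate()

    def test_assignment_exceeding_sample_rejected(self, tiny_bundle):
        scn, truth, data = tiny_bundle
        import dataclasses
        x = data.x.copy()
        m = np.argwhere(data.gsi_mask)[0]
        x[m[0], m[1]] = data.n[m[0], m[1]] + 1
        bad = dataclasses.replace(data, x=x)
        with pytest.raises(ValueError, match="exceed"):
            bad.validate()
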