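"""Forward projection machinery and recovery conditioning."""

import numpy as np
import pytest

from conftest import make_pseudo_ensemble
from yukon_ipm.dims import ModelDimensions
from yukon_ipm.process import TimeVaryingRates, simulate_population
from yukon_ipm.projection import (ProjectionConfig, ProjectionResult,
                                  classify_recovery,
                                  conditional_recovery_fraction,
                                  fixed_scenario_grid, project)
from yukon_ipm.retrospective import _draw_ingredients
from yukon_ipm.synthetic import (GeneratingScenario, generate_observations,
                                 generate_truth)


@pytest.fixture(scope="module")
def det_ensemble():
    """Ensemble whose walk SDs are (numerically) zero, for degenerate-noise
    equivalence with a point forward run."""
    scn = GeneratingScenario(sigma_M=1e-9, sigma_lambda=1e-9, sigma_T=1e-9,
                             sigma_B_proc=1e-9)
    truth = generate_truth(scn, 4)
    data = generate_observations(truth, 5)
    return truth, make_pseudo_ensemble(truth, data, n_chains=1, n_draws=3,
                                       jitter=0.0)


class TestProject:
    def test_history_replays_fitted_states(self, pseudo_ensemble):
        proj = project(pseudo_ensemble, ProjectionConfig(horizon_years=5),
                       max_draws=5, rng=np.random.default_rng(0))
        for i, (c, d) in enumerate(proj.draw_index):
            st = pseudo_ensemble.state_for(c, d)
            np.testing.assert_allclose(proj.run_size[i, :proj.n_hist],
                                       st.run_size, rtol=1e-9)

    def test_degenerate_noise_equals_point_forward_run(self, det_ensemble):
        """With all process SDs at zero and recruitment deviations fixed,
        the projection is the deterministic process model."""
        truth, ens = det_ensemble
        cfg = ProjectionConfig(horizon_years=7, eps_R_fixed=0.0)
        proj = project(ens, cfg, max_draws=1, rng=np.random.default_rng(1))

        # manual point forward run of the process model
        dims = ens.model.dims
        Y, h = dims.n_years, 7
        ricker, errors, rates, schedules, init, _ = _draw_ingredients(
            ens, *proj.draw_index[0])
        ext = ModelDimensions(first_year=dims.first_year, n_years=Y + h)
        fb_ref = np.array(dims.years) >= cfg.fb_reference_start
        man_rates = TimeVaryingRates(
            M=np.concatenate([rates.M, np.full(h, rates.M[-1])]),
            FB=np.concatenate([rates.FB,
                               np.full(h, rates.FB[fb_ref].mean())]),
            FT=np.concatenate([rates.FT, np.zeros(h)]),
            lam=np.concatenate([rates.lam, np.full(h, rates.lam[-1])]))
        man_err = type(errors)(
            eps_R=np.concatenate([errors.eps_R, np.zeros(h)]),
            eps_M=np.zeros(Y + h - 1), eps_B=np.zeros(Y + h - 1),
            eps_T=np.zeros(Y + h - 1), eps_lambda=np.zeros(Y + h - 1))
        manual = simulate_population(ext, ricker, man_err, man_rates,
                                     schedules, init)
        np.testing.assert_allclose(proj.run_size[0], manual.run_size,
                                   rtol=1e-6)

    def test_same_seed_same_ensemble(self, pseudo_ensemble):
        cfg = ProjectionConfig(horizon_years=7, seed=9)
        a = project(pseudo_ensemble, cfg, max_draws=6)
        b = project(pseudo_ensemble, cfg, max_draws=6)
        np.testing.assert_array_equal(a.run_size, b.run_size)

    def test_variance_grows_with_horizon(self, pseudo_ensemble):
        proj = project(pseudo_ensemble, ProjectionConfig(horizon_years=7),
                       max_draws=60, rng=np.random.default_rng(2))
        lr = np.log(proj.run_size[:, proj.n_hist:])
        assert lr[:, -1].var() > lr[:, 0].var()

    def test_14_year_horizon_supported(self, pseudo_ensemble):
        proj = project(pseudo_ensemble, ProjectionConfig(horizon_years=14),
                       max_draws=4, rng=np.random.default_rng(3))
        assert proj.run_size.shape[1] == proj.n_hist + 14
        assert proj.years[-1] == proj.years[proj.n_hist - 1] + 14


def _dummy_projection(final, M_proj, m_pre=None, m_recent=None):
    n = final.size
    h = M_proj.shape[1]
    return ProjectionResult(
        config=ProjectionConfig(), years=np.arange(2003, 2003 + 5 + h),
        n_hist=5,
        run_size=np.column_stack([np.tile(final[:, None], 4 + h), final]),
        M_proj=M_proj, eps_R_proj=np.zeros((n, h)),
        log_alpha=np.full(n, 3.8), beta=np.full(n, 1e-5),
        m_pre_ref=np.full(n, 1.1) if m_pre is None else m_pre,
        m_recent_ref=np.full(n, 1.5) if m_recent is None else m_recent,
        draw_index=[(0, i) for i in range(n)])


class TestClassifyRecovery:
    def test_identical_draws_degenerate_flagged(self):
        proj = _dummy_projection(np.full(50, 30000.0), np.ones((50, 3)))
        cls = classify_recovery(proj)
        assert cls.upper_threshold == 30000.0
        assert cls.degenerate is False
        assert set(cls.labels) == {"recovery"}  # all >= their own threshold

    def test_constructed_ten_percent_tail_recovers_cut(self):
        # 90 draws below, 10 draws above a known cut: the 90th percentile
        # lands at the cut (within interpolation between order statistics)
        final = np.concatenate([np.linspace(5000, 20000, 90),
                                np.linspace(50000, 60000, 10)])
        proj = _dummy_projection(final, np.ones((100, 3)))
        cls = classify_recovery(proj)
        assert 20000 <= cls.upper_threshold <= 50000
        assert (cls.labels == "recovery").sum() == 10

    def test_labels_partition(self):
        rng = np.random.default_rng(0)
        final = rng.lognormal(10, 0.8, 300)
        proj = _dummy_projection(final, np.ones((300, 3)))
        cls = classify_recovery(proj)
        rec = cls.labels == "recovery"
        non = cls.labels == "non-recovery"
        assert not np.any(rec & non)
        assert rec.sum() + non.sum() + (cls.labels == "intermediate").sum() \
            == 300


class TestConditionalRecovery:
    def test_low_mortality_paths_recover_more(self):
        # construct a strong negative M -> final-run link; mortality paths
        # are draw-level shifts with small wiggle (random-walk-like
        # coherence), so the pathwise conditions select real subsets
        rng = np.random.default_rng(1)
        level = rng.uniform(0.9, 1.7, 400)
        M = level[:, None] + rng.uniform(-0.04, 0.04, (400, 7))
        final = 60000.0 * np.exp(-3.0 * (level - 0.9)) \
            * rng.lognormal(0, 0.1, 400)
        proj = _dummy_projection(final, M)
        cls = classify_recovery(proj)
        lo = conditional_recovery_fraction(proj, "low", cls)
        hi = conditional_recovery_fraction(proj, "high", cls)
        assert not lo["undefined"] and not hi["undefined"]
        assert lo["fraction"] > hi["fraction"]

    def test_unconditional_fraction_is_ten_percent_by_construction(self):
        rng = np.random.default_rng(2)
        final = rng.lognormal(10, 0.5, 1000)
        proj = _dummy_projection(final, np.ones((1000, 3)))
        cls = classify_recovery(proj)
        out = conditional_recovery_fraction(proj, "all", cls)
        assert out["fraction"] == pytest.approx(0.1, abs=0.002)

    def test_empty_condition_flagged_undefined(self):
        proj = _dummy_projection(np.full(20, 1e4),
                                 np.full((20, 3), 2.0),
                                 m_pre=np.full(20, 0.5))
        out = conditional_recovery_fraction(proj, "low")
        assert out["undefined"] and np.isnan(out["fraction"])


class TestFixedScenarioGrid:
    def test_mortality_dominates_recruitment_in_grid(self, pseudo_ensemble):
        """At fixed favorable recruitment, low mortality cells end higher
        than high mortality cells -- the projected bottleneck."""
        grid = fixed_scenario_grid(
            pseudo_ensemble,
            eps_levels={"p95": 0.6, "zero": 0.0},
            M_levels={"pre2016": 1.0, "recent": 1.5},
            cfg=ProjectionConfig(horizon_years=7, seed=0),
            max_draws=15)
        for elab in ("p95", "zero"):
            lo = np.median(grid[(elab, "pre2016")].final_run)
            hi = np.median(grid[(elab, "recent")].final_run)
            assert lo > hi

    def test_cells_reproducible_given_seed_policy(self, pseudo_ensemble):
        kw = dict(eps_levels={"zero": 0.0}, M_levels={"lo": 1.0},
                  cfg=ProjectionConfig(horizon_years=4, seed=5),
                  max_draws=5)
        a = fixed_scenario_grid(pseudo_ensemble, **kw)
        b = fixed_scenario_grid(pseudo_ensemble, **kw)
        np.testing.assert_array_equal(a[("zero", "lo")].run_size,
                                      b[("zero", "lo")].run_size)
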