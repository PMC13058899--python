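"""Synthetic truth and observation generator.

The study's real inputs (survey index, run-reconstruction outputs, bycatch
census and genetics) are not distributed as flat files, so every stage of the
package is exercised against synthetic data with exactly the statistical
structure the likelihoods assume: lognormal abundance indices, multinomial
age compositions at fixed effective sample sizes, binomial genetic
assignments under a logit-normal among-year hierarchy, and the documented
missing-data patterns (no juvenile survey in 2005, 2008, 2020; genetic
stock-assignment data only from the full-observer-coverage era onward).

The default generating scenario is anchored to the reported posterior
medians where such values exist: Ricker productivity alpha = 48
juveniles/spawner and capacity 1/beta = 81,178 spawners; natural mortality
near 1.1 through 2015 rising to 1.5 by 2020; bycatch selectivity
(0.03, 0.15, 0.81, 0.21) over ages 3-6; vulnerability (1, 0.67, 0.60, 0.64,
0.93) over ages 3-7; roughly 1-in-10 genotyping of the bycatch.  Quantities
the study does not print (harvest-rate path, maturation-schedule path,
stock-proportion levels, recruitment-error SD) are package choices tuned to
produce realistic magnitudes -- run sizes of order 10^4-10^5 and
stock-specific bycatch of order 10^2-10^3 -- and are documented in
docs/methods.md; they are configuration, not oracles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy.special import expit, logit

from .dims import ModelDimensions
from .observation import ObservationDataset, ObservationErrorConfig
from .process import (AgeSchedules, InitialConditions, LatentPopulationState,
                      ProcessErrorSeries, RickerParameters, TimeVaryingRates,
                      simulate_population)

__all__ = ["GeneratingScenario", "SyntheticTruth", "generate_truth",
           "generate_observations", "make_fixture"]


@dataclass
class GeneratingScenario:
    """Everything needed to simulate one dataset.

    Rate "targets" are regime paths the log-space walks follow on average;
    the walk SDs add year-to-year wobble on top.  ``m_rise_start/stop``
    place the natural-mortality increase (default: flat at ``m_early``
    through 2015, climbing to ``m_late`` by 2020, flat after).
    """

    dims: ModelDimensions = field(default_factory=ModelDimensions)
    log_alpha: float = math.log(48.0)
    beta: float = 1.0 / 81178.0
    sigma_R: float = 0.5
    # natural mortality regime
    m_early: float = 1.1
    m_late: float = 1.5
    m_rise_start: int = 2016
    m_rise_stop: int = 2020
    sigma_M: float = 0.05
    # bycatch mortality regime (drops at the 2011 hard-cap era)
    fb_early: float = 0.01
    fb_late: float = 0.005
    fb_change_year: int = 2011
    sigma_B_proc: float = 0.15
    # harvest mortality: geometric decline tracking the shrinking runs
    ft_start: float = 0.45
    ft_end: float = 0.05
    sigma_T: float = 0.10
    # maturation schedule: slow drift toward younger maturation
    lam_start: float = 2.2
    lam_end: float = 1.8
    sigma_lambda: float = 0.05
    # age schedules
    sB: tuple = (0.03, 0.15, 0.81, 0.21)       # ages 3-6
    v: tuple = (0.67, 0.60, 0.64, 0.93)        # ages 4-7 (age 3 fixed at 1)
    sT: tuple = (0.5, 0.8, 0.95, 0.9)          # ages 4-7
    # bycatch stock composition hierarchy (focal stock is a minor share)
    vartheta_mean: tuple = (0.02, 0.03, 0.035, 0.03)   # ages 3-6
    sigmaG: tuple = (0.3, 0.3, 0.3, 0.3)
    # observation process
    obs: ObservationErrorConfig = field(default_factory=ObservationErrorConfig)
    nB_per_year: int = 500
    genotyping_rate: float = 0.1
    gsi_start_year: int = 2011
    missing_juvenile_years: tuple = (2005, 2008, 2020)
    spinup_years: int = 40

    # ------------------------------------------------------------------
    def rate_paths(self) -> dict[str, np.ndarray]:
        """Regime target paths for the four time-varying processes."""
        d = self.dims
        years = np.array(d.years)
        M = np.full(d.n_years, self.m_early)
        rise = (years >= self.m_rise_start) & (years <= self.m_rise_stop)
        span = max(self.m_rise_stop - self.m_rise_start, 1)
        M[rise] = self.m_early + (self.m_late - self.m_early) * (
            (years[rise] - self.m_rise_start) / span)
        M[years > self.m_rise_stop] = self.m_late

        FB = np.where(years < self.fb_change_year, self.fb_early, self.fb_late)
        FT = np.exp(np.linspace(math.log(self.ft_start),
                                math.log(self.ft_end), d.n_years))
        lam = np.linspace(self.lam_start, self.lam_end, d.n_years)
        return {"M": M, "FB": FB, "FT": FT, "lam": lam}

    def to_jsonable(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, ModelDimensions):
                out[k] = {"first_year": v.first_year, "n_years": v.n_years}
            elif isinstance(v, ObservationErrorConfig):
                out[k] = {f: getattr(v, f) for f in
                          ("sigma_J", "sigma_E", "sigma_C", "sigma_b",
                           "neff_E", "neff_C")}
            elif isinstance(v, tuple):
                out[k] = list(v)
            else:
                out[k] = v
        return out


@dataclass
class SyntheticTruth:
    """Latent truth plus the generating values, for recovery scoring."""

    scenario: GeneratingScenario
    state: LatentPopulationState
    ricker: RickerParameters
    errors: ProcessErrorSeries
    rates: TimeVaryingRates
    schedules: AgeSchedules
    init: InitialConditions
    vartheta: np.ndarray
    muG: np.ndarray
    sigmaG: np.ndarray

    @property
    def params(self) -> dict:
        """Generating values keyed like the sampler's parameter blocks."""
        return {
            "log_alpha": self.ricker.log_alpha,
            "beta": self.ricker.beta,
            "sigma_R": self.ricker.sigma_R,
            "sB": np.asarray(self.schedules.sB),
            "v": np.asarray(self.schedules.v),
            "sT": np.asarray(self.schedules.sT),
            "M_series": np.asarray(self.rates.M),
            "FB_series": np.asarray(self.rates.FB),
            "FT_series": np.asarray(self.rates.FT),
            "lam_series": np.asarray(self.rates.lam),
            "muG": self.muG,
            "sigmaG": self.sigmaG,
        }


def _spinup_init(scn: GeneratingScenario, rates: TimeVaryingRates,
                 schedules: AgeSchedules,
                 ricker: RickerParameters) -> InitialConditions:
    """Deterministic burn-in at first-year rates to a settled age structure.

    Runs the dynamics with zero process error for ``spinup_years`` plus the
    first two model years and takes the entering abundances of the final two
    years, giving initial conditions consistent with the generating
    parameters rather than arbitrary seeds.
    """
    n = scn.spinup_years + 2
    d0 = scn.dims
    dims = ModelDimensions(first_year=d0.first_year - scn.spinup_years,
                           n_years=n)
    const = TimeVaryingRates(
        M=np.full(n, rates.M[0]), FB=np.full(n, rates.FB[0]),
        FT=np.full(n, rates.FT[0]), lam=np.full(n, rates.lam[0]),
        M_init=rates.M[0], FB_init=rates.FB[0], FT_init=rates.FT[0],
        lam_init=rates.lam[0])
    errors = ProcessErrorSeries.zeros(dims)
    seed_run = 0.2 / ricker.beta  # any positive start; transient dies out
    init = InitialConditions(
        N_init_by_age=np.array([seed_run * f for f in
                                (1.0, 0.5, 0.25, 0.08, 0.005)]),
        free_recruits=np.array([seed_run, seed_run]),
    )
    st = simulate_population(dims, ricker, errors, const, schedules, init)
    return InitialConditions(
        N_init_by_age=st.entering[n - 2, 1:].copy(),
        free_recruits=st.entering[n - 2:, 0].copy(),
    )


def generate_truth(scn: GeneratingScenario,
                   rng: np.random.Generator | int | None = None
                   ) -> SyntheticTruth:
    """Draw process errors, run the dynamics, return latent truth."""
    rng = np.random.default_rng(rng)
    dims = scn.dims
    Y = dims.n_years
    paths = scn.rate_paths()

    ricker = RickerParameters(scn.log_alpha, scn.beta, scn.sigma_R)
    eps_R = rng.normal(0.0, scn.sigma_R, Y)
    errors = ProcessErrorSeries(
        eps_R=eps_R,
        eps_M=np.diff(np.log(paths["M"])) + rng.normal(0, scn.sigma_M, Y - 1),
        eps_B=np.diff(np.log(paths["FB"])) + rng.normal(0, scn.sigma_B_proc,
                                                        Y - 1),
        eps_T=np.diff(np.log(paths["FT"])) + rng.normal(0, scn.sigma_T, Y - 1),
        eps_lambda=np.diff(np.log(paths["lam"]))
        + rng.normal(0, scn.sigma_lambda, Y - 1),
        sigma_M=scn.sigma_M, sigma_B_proc=scn.sigma_B_proc,
        sigma_T=scn.sigma_T, sigma_lambda=scn.sigma_lambda,
    )
    rates = TimeVaryingRates.from_walks(
        errors, M_init=paths["M"][0], FB_init=paths["FB"][0],
        FT_init=paths["FT"][0], lam_init=paths["lam"][0])
    schedules = AgeSchedules(sB=np.array(scn.sB), v=np.array(scn.v),
                             sT=np.array(scn.sT))
    init = _spinup_init(scn, rates, schedules, ricker)

    muG = logit(np.array(scn.vartheta_mean))
    sigmaG = np.array(scn.sigmaG)
    vartheta = expit(muG[None, :] + sigmaG[None, :]
                     * rng.standard_normal((Y, 4)))

    state = simulate_population(dims, ricker, errors, rates, schedules, init,
                                vartheta=vartheta)
    return SyntheticTruth(scenario=scn, state=state, ricker=ricker,
                          errors=errors, rates=rates, schedules=schedules,
                          init=init, vartheta=vartheta, muG=muG,
                          sigmaG=sigmaG)


def generate_observations(truth: SyntheticTruth,
                          rng: np.random.Generator | int | None = None
                          ) -> ObservationDataset:
    """Sample the five data streams from the observation model at the truth."""
    rng = np.random.default_rng(rng)
    scn = truth.scenario
    dims, cfg = scn.dims, scn.obs
    Y = dims.n_years
    st = truth.state
    years = np.array(dims.years)
    bc = slice(dims.age_index(3), dims.age_index(6) + 1)

    N2 = st.entering[:, 0]
    J = N2 * np.exp(cfg.sigma_J * rng.standard_normal(Y))
    J_mask = ~np.isin(years, scn.missing_juvenile_years)
    J = np.where(J_mask, J, np.nan)

    E = st.S_total * np.exp(cfg.sigma_E * rng.standard_normal(Y))
    C = st.H_total * np.exp(cfg.sigma_C * rng.standard_normal(Y))

    neff_E, neff_C = int(round(cfg.neff_E)), int(round(cfg.neff_C))
    qE = np.stack([rng.multinomial(neff_E, st.pi_S[y]) / neff_E
                   for y in range(Y)])
    qC = np.stack([rng.multinomial(neff_C, st.pi_H[y]) / neff_C
                   for y in range(Y)])
    nB = np.full(Y, scn.nB_per_year)
    qB = np.stack([rng.multinomial(nB[y], st.pi_B[y]) / nB[y]
                   for y in range(Y)])

    BA_total = st.BA[:, bc].sum(axis=1)
    b_total = BA_total * np.exp(cfg.sigma_b * rng.standard_normal(Y))

    # roughly 1-in-10 of the aggregate bycatch-at-age is genotyped
    n = np.zeros((Y, 4))
    x = np.zeros((Y, 4))
    gsi_mask = np.zeros((Y, 4), dtype=bool)
    for y in range(Y):
        if years[y] < scn.gsi_start_year:
            continue
        for j in range(4):
            n_cell = rng.binomial(max(int(round(st.BA[y, bc][j])), 0),
                                  scn.genotyping_rate)
            if n_cell > 0:
                n[y, j] = n_cell
                x[y, j] = rng.binomial(n_cell, truth.vartheta[y, j])
                gsi_mask[y, j] = True

    data = ObservationDataset(
        dims=dims, J=J, J_mask=J_mask, E=E, C=C, qE=qE, qC=qC,
        b_total=b_total, qB=qB, nB=nB, x=x, n=n, gsi_mask=gsi_mask)
    data.validate()
    return data


def make_fixture(size: str = "tiny", seed: int = 0,
                 outdir: str | Path | None = None):
    """Generate a reproducible dataset bundle (optionally written as CSVs).

    ``tiny`` spans 8 years for fast tests; ``paper_scale`` spans the full
    2003-2023 window with the documented missing juvenile years.  Returns
    (scenario, truth, data); with ``outdir`` set, also writes the CSV bundle
    and a manifest recording the full generating scenario.
    """
    if size == "tiny":
        dims = ModelDimensions(first_year=2003, n_years=8)
        scn = GeneratingScenario(dims=dims, missing_juvenile_years=(2005,),
                                 gsi_start_year=2006)
    elif size == "paper_scale":
        scn = GeneratingScenario()
    else:
        raise ValueError("size must be 'tiny' or 'paper_scale'")
    ss = np.random.SeedSequence([seed, 7 if size == "tiny" else 21])
    r1, r2 = [np.random.default_rng(s) for s in ss.spawn(2)]
    truth = generate_truth(scn, r1)
    data = generate_observations(truth, r2)
    if outdir is not None:
        from .io import write_dataset
        outdir = Path(outdir)
        write_dataset(data, outdir)
        manifest = {"size": size, "seed": seed,
                    "scenario": scn.to_jsonable()}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
    return scn, truth, data
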