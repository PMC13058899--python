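"""Observation likelihoods for the five data streams.

The latent trajectory is confronted with (1) a juvenile marine abundance
index, (2) escapement and (3) terminal harvest abundances with age
compositions, (4) total (all-stock) bycatch counts with age compositions, and
(5) per-age genetic assignments of bycatch samples to the focal stock.
Abundance indices are lognormal around the model prediction (median
parameterization); age compositions are multinomial at fixed effective sample
sizes; genetic assignments are binomial with the focal-stock proportions tied
together across years by an age-specific logit-normal hierarchy, which is what
lets years without genetic data borrow strength.

Observation error SDs and effective sample sizes are fixed, not estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln, logit

from .dims import ModelDimensions
from .process import LatentPopulationState

__all__ = [
    "ObservationDataset",
    "ObservationErrorConfig",
    "StockCompositionModel",
    "loglik_lognormal_index",
    "loglik_agecomp",
    "loglik_stock_assignment",
    "loglik_stock_hierarchy",
    "joint_loglik",
    "proportions_to_counts",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class ObservationErrorConfig:
    """Fixed observation error SDs (log scale) and effective sample sizes.

    ``sigma_b`` is the total-bycatch count SD -- a distinct quantity from the
    bycatch-rate process-walk SD, despite sharing a symbol in places.
    """

    sigma_J: float = 0.25
    sigma_E: float = 0.10
    sigma_C: float = 0.15
    sigma_b: float = 0.10
    neff_E: float = 100.0
    neff_C: float = 100.0
    fractional_agecomp: bool = False

    def __post_init__(self) -> None:
        for name in ("sigma_J", "sigma_E", "sigma_C", "sigma_b",
                     "neff_E", "neff_C"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ObservationDataset:
    """The five observed data streams with missing-value masks.

    Missing entries are NaN with the matching mask False.  Compositions are
    fractions summing to 1 over their age range; ``x``/``n`` are genetic
    assignment successes/trials per year and bycatch age, with NaN/mask for
    year-age cells without genotyping data.
    """

    dims: ModelDimensions
    J: np.ndarray            # (Y,) juvenile index, NaN where missing
    J_mask: np.ndarray       # (Y,) True where observed
    E: np.ndarray            # (Y,) escapement
    C: np.ndarray            # (Y,) terminal harvest
    qE: np.ndarray           # (Y, 4) escapement age comps, ages 4-7
    qC: np.ndarray           # (Y, 4) harvest age comps, ages 4-7
    b_total: np.ndarray      # (Y,) total all-stock bycatch count
    qB: np.ndarray           # (Y, 4) bycatch age comps, ages 3-6
    nB: np.ndarray           # (Y,) scale-sample sizes behind qB
    x: np.ndarray            # (Y, 4) assignments to focal stock
    n: np.ndarray            # (Y, 4) genotyped sample sizes
    gsi_mask: np.ndarray     # (Y, 4) True where genotyping data exist
    adult_mask: Optional[np.ndarray] = None    # (Y,) covers E, C, qE, qC
    bycatch_mask: Optional[np.ndarray] = None  # (Y,) covers b_total, qB

    def __post_init__(self) -> None:
        Y = self.dims.n_years
        if self.adult_mask is None:
            self.adult_mask = np.ones(Y, dtype=bool)
        if self.bycatch_mask is None:
            self.bycatch_mask = np.ones(Y, dtype=bool)

    def validate(self) -> None:
        Y = self.dims.n_years
        shapes = {
            "J": (Y,), "J_mask": (Y,), "E": (Y,), "C": (Y,), "qE": (Y, 4),
            "qC": (Y, 4), "b_total": (Y,), "qB": (Y, 4), "nB": (Y,),
            "x": (Y, 4), "n": (Y, 4), "gsi_mask": (Y, 4),
        }
        for name, shape in shapes.items():
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
        if np.any(self.J[self.J_mask] <= 0):
            raise ValueError("observed juvenile abundances must be > 0")
        for name, mask in (("E", self.adult_mask), ("C", self.adult_mask),
                           ("b_total", self.bycatch_mask)):
            if np.any(np.asarray(getattr(self, name))[mask] <= 0):
                raise ValueError(f"observed {name} must be > 0")
        for name, mask in (("qE", self.adult_mask), ("qC", self.adult_mask),
                           ("qB", self.bycatch_mask)):
            q = np.asarray(getattr(self, name))[mask]
            years = np.array(self.dims.years)[mask]
            if np.any((q < 0) | (q > 1)):
                raise ValueError(f"{name} proportions must lie in [0, 1]")
            sums = q.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
            if bad.size:
                raise ValueError(
                    f"{name} row for year {years[bad[0]]} sums to "
                    f"{sums[bad[0]]:.6f}, not 1")
        m = self.gsi_mask
        if np.any(self.x[m] > self.n[m]):
            raise ValueError("genetic assignments x cannot exceed sample sizes n")
        if np.any(self.x[m] < 0) or np.any(self.n[m] < 0):
            raise ValueError("x and n must be >= 0")


@dataclass
class StockCompositionModel:
    """Focal-stock proportions of the bycatch and their among-year hierarchy.

    ``vartheta[y, a]``: proportion of the age-a aggregate bycatch belonging to
    the focal stock; logit(vartheta[., a]) ~ Normal(muG[a], sigmaG[a]).
    """

    vartheta: np.ndarray  # (Y, 4), in (0, 1)
    muG: np.ndarray       # (4,)
    sigmaG: np.ndarray    # (4,) >= 0

    def __post_init__(self) -> None:
        self.vartheta = np.asarray(self.vartheta, dtype=float)
        self.muG = np.asarray(self.muG, dtype=float)
        self.sigmaG = np.asarray(self.sigmaG, dtype=float)
        if np.any((self.vartheta <= 0) | (self.vartheta >= 1)):
            raise ValueError("vartheta must lie strictly in (0, 1)")
        if np.any(self.sigmaG < 0):
            raise ValueError("sigmaG must be >= 0")


# ---------------------------------------------------------------------------
# individual terms
# ---------------------------------------------------------------------------

def loglik_lognormal_index(obs, pred, sigma) -> float:
    """Lognormal log-density with log-scale location log(pred).

    ``pred`` is the median of the sampling distribution; ``sigma`` the
    log-scale SD.  Scalars or arrays; the sum is returned for arrays.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if np.any(obs <= 0) or np.any(pred <= 0) or not sigma > 0:
        raise ValueError("lognormal likelihood needs positive obs, pred, sigma")
    z = (np.log(obs) - np.log(pred)) / sigma
    ll = -np.log(obs) - math.log(sigma) - 0.5 * _LOG_2PI - 0.5 * z * z
    return float(np.sum(ll))


def proportions_to_counts(q: np.ndarray, neff: float) -> np.ndarray:
    """Integer counts from observed proportions at an effective sample size.

    round(q * neff), repaired by largest remainders so the counts sum to
    round(neff) exactly (keeps the multinomial pmf proper).
    """
    q = np.asarray(q, dtype=float)
    total = int(round(neff))
    raw = q * neff
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    elif short < 0:  # can only happen from float edge cases
        order = np.argsort(raw - base, kind="stable")
        for i in order:
            if short == 0:
                break
            if base[i] > 0:
                base[i] -= 1
                short += 1
    return base


def loglik_agecomp(q, neff, pi, fractional: bool = False) -> float:
    """Multinomial log-density of an observed age composition.

    Observed proportions ``q`` are converted to counts at effective sample
    size ``neff`` (largest-remainder rounding by default; ``fractional=True``
    uses q*neff directly with gamma-function coefficients as a sensitivity
    variant).  ``pi`` are the predicted proportions.  Cells with a positive
    count but a structurally zero prediction yield -inf.
    """
    q = np.asarray(q, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if q.shape != pi.shape:
        raise ValueError("q and pi must share a shape")
    if not neff > 0:
        raise ValueError("neff must be > 0")
    if np.any(pi < 0):
        raise ValueError("pi must be >= 0")
    if fractional:
        counts = q * neff
        coeff = gammaln(neff + 1.0) - np.sum(gammaln(counts + 1.0))
    else:
        counts = proportions_to_counts(q, neff)
        coeff = gammaln(counts.sum() + 1.0) - np.sum(gammaln(counts + 1.0))
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    terms = np.where(counts > 0, counts * logpi, 0.0)
    if np.any(np.isneginf(terms)):
        return float("-inf")
    return float(coeff + terms.sum())


def loglik_stock_assignment(x, n, vartheta) -> float:
    """Binomial log-pmf of genetic assignments to the focal stock."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    vt = np.asarray(vartheta, dtype=float)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("need 0 <= x <= n")
    if np.any((vt <= 0) | (vt >= 1)):
        raise ValueError("vartheta must lie strictly in (0, 1)")
    ll = (gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
          + x * np.log(vt) + (n - x) * np.log1p(-vt))
    return float(np.sum(ll))


def loglik_stock_hierarchy(vartheta, muG, sigmaG) -> float:
    """Logit-normal partial-pooling term for the stock proportions.

    Sum over year-age cells of Normal(logit(vartheta[y, a]); muG[a],
    sigmaG[a]).  This is what informs years with no genetic data.
    """
    vt = np.asarray(vartheta, dtype=float)
    muG = np.asarray(muG, dtype=float)
    sigmaG = np.asarray(sigmaG, dtype=float)
    if np.any((vt <= 0) | (vt >= 1)):
        raise ValueError("vartheta must lie strictly in (0, 1) (logit domain)")
    if np.any(sigmaG <= 0):
        raise ValueError("sigmaG must be > 0")
    z = (logit(vt) - muG[None, :]) / sigmaG[None, :]
    ll = -np.log(sigmaG[None, :]) - 0.5 * _LOG_2PI - 0.5 * z * z
    return float(np.sum(ll))


# ---------------------------------------------------------------------------
# joint likelihood
# ---------------------------------------------------------------------------

def joint_loglik(
    state: LatentPopulationState,
    data: ObservationDataset,
    cfg: ObservationErrorConfig,
    gsi: StockCompositionModel,
    include_hierarchy: bool = True,
) -> float:
    """Joint log-likelihood of all five data streams given a trajectory.

    Missing observations (masked juvenile years, masked adult or bycatch
    years, year-age cells without genotyping) contribute nothing.  The
    logit-normal hierarchy on the stock proportions -- a data-free
    partial-pooling term -- is included by default alongside the binomial
    assignment term; with every stream masked and ``include_hierarchy=False``
    the value is exactly 0.  The aggregate-scale bycatch in ``state`` must
    already use ``gsi.vartheta`` for the expansion.
    """
    dims = state.dims
    if data.dims.n_years != dims.n_years:
        raise ValueError("state and data dimensions disagree")
    bc = slice(dims.age_index(3), dims.age_index(6) + 1)

    total = 0.0
    # juvenile index vs age-2 abundance
    obs_y = np.where(data.J_mask)[0]
    if obs_y.size:
        total += loglik_lognormal_index(data.J[obs_y], state.entering[obs_y, 0],
                                        cfg.sigma_J)
    # escapement / harvest totals and adult age compositions
    for y in np.where(data.adult_mask)[0]:
        total += loglik_lognormal_index(data.E[y], state.S_total[y], cfg.sigma_E)
        total += loglik_lognormal_index(data.C[y], state.H_total[y], cfg.sigma_C)
        total += loglik_agecomp(data.qE[y], cfg.neff_E, state.pi_S[y],
                                fractional=cfg.fractional_agecomp)
        total += loglik_agecomp(data.qC[y], cfg.neff_C, state.pi_H[y],
                                fractional=cfg.fractional_agecomp)
    # total bycatch counts and bycatch age compositions
    for y in np.where(data.bycatch_mask)[0]:
        total += loglik_lognormal_index(data.b_total[y],
                                        state.BA[y, bc].sum(), cfg.sigma_b)
        total += loglik_agecomp(data.qB[y], float(data.nB[y]), state.pi_B[y],
                                fractional=cfg.fractional_agecomp)
    # genetic stock assignments (observed cells only) + hierarchy (all cells)
    m = data.gsi_mask
    if np.any(m):
        total += loglik_stock_assignment(data.x[m], data.n[m], gsi.vartheta[m])
    if include_hierarchy:
        total += loglik_stock_hierarchy(gsi.vartheta, gsi.muG, gsi.sigmaG)
    return float(total)
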