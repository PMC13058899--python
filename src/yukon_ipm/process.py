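"""Deterministic age-structured population dynamics.

The process model tracks a single Chinook salmon stock over calendar years and
ages 2-7.  Juveniles enter at age 2 through a Ricker spawner-recruit function
of the escapement two years earlier; at ages 3-7 immature fish experience two
competing instantaneous mortality sources per year -- trawl bycatch (rate
``FB_y`` scaled by selectivity ``sB_a``) and natural mortality (rate ``M_y``
scaled by vulnerability ``v_a``) -- after which a cohort-specific fraction
``theta`` matures and returns to the river.  Mature fish are harvested at rate
``FT_y`` scaled by ``sT_a``; survivors are the spawning escapement that closes
the recruitment loop.  All time-varying rates follow random walks in log
space; the maturation schedule is a modified logistic in age pinned to 0.99 at
age 7.

Everything here is pure, deterministic numpy: given parameters, process errors
and initial conditions it produces the full latent trajectory.  Stochastic
draws of the process errors live in :mod:`yukon_ipm.synthetic`; the sampler in
:mod:`yukon_ipm.inference` re-implements the same recursion on an autodiff
tape and is tested for exact agreement with this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dims import ModelDimensions

__all__ = [
    "RickerParameters",
    "ProcessErrorSeries",
    "TimeVaryingRates",
    "AgeSchedules",
    "InitialConditions",
    "LatentPopulationState",
    "maturation_prob",
    "recruit_juveniles",
    "advance_cohort",
    "bycatch_at_age",
    "expand_bycatch",
    "harvest_at_age",
    "step_random_walk",
    "simulate_population",
]

# Offset pinning the maturation logistic to 0.99 at age 7.
_MATURATION_OFFSET = math.log(1.0 / 0.99 - 1.0)
TERMINAL_MATURATION = 0.99


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class RickerParameters:
    """Spawner-to-juvenile recruitment: R = S * exp(log_alpha - beta*S + eps).

    ``log_alpha`` is log juveniles-per-spawner at low stock size, ``beta`` the
    inverse capacity (per spawner), ``sigma_R`` the SD of log recruitment
    errors.
    """

    log_alpha: float
    beta: float
    sigma_R: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.sigma_R < 0:
            raise ValueError("sigma_R must be >= 0")


@dataclass
class ProcessErrorSeries:
    """Per-year (or per-cohort) process errors and their walk SDs.

    ``eps_R`` has one entry per model year for calendar alignment; the first
    two entries are ignored because those juveniles' brood years predate the
    model and their abundances come from ``InitialConditions.free_recruits``.
    The walk innovations (``eps_M``, ``eps_B``, ``eps_T``) have n_years - 1
    entries (steps between consecutive years); ``eps_lambda`` has one entry
    per step between consecutive model cohorts.
    """

    eps_R: np.ndarray
    eps_M: np.ndarray
    eps_B: np.ndarray
    eps_T: np.ndarray
    eps_lambda: np.ndarray
    sigma_M: float = 0.0
    sigma_B_proc: float = 0.0
    sigma_T: float = 0.0
    sigma_lambda: float = 0.0

    @classmethod
    def zeros(cls, dims: ModelDimensions) -> "ProcessErrorSeries":
        n = dims.n_years
        return cls(
            eps_R=np.zeros(n),
            eps_M=np.zeros(n - 1),
            eps_B=np.zeros(n - 1),
            eps_T=np.zeros(n - 1),
            eps_lambda=np.zeros(n - 1),
        )

    def validate(self, dims: ModelDimensions) -> None:
        n = dims.n_years
        for name, arr, m in (
            ("eps_R", self.eps_R, n),
            ("eps_M", self.eps_M, n - 1),
            ("eps_B", self.eps_B, n - 1),
            ("eps_T", self.eps_T, n - 1),
            ("eps_lambda", self.eps_lambda, n - 1),
        ):
            if np.asarray(arr).shape != (m,):
                raise ValueError(f"{name} must have shape ({m},)")
        for name, s in (
            ("sigma_M", self.sigma_M),
            ("sigma_B_proc", self.sigma_B_proc),
            ("sigma_T", self.sigma_T),
            ("sigma_lambda", self.sigma_lambda),
        ):
            if s < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TimeVaryingRates:
    """Realized per-year rates (walks already exponentiated).

    ``M``, ``FB``, ``FT`` are per-year fully selected rates; ``lam`` is the
    per-cohort maturation-schedule parameter for cohorts recruited in model
    years (index 0 = cohort recruited in the first model year).
    """

    M: np.ndarray
    FB: np.ndarray
    FT: np.ndarray
    lam: np.ndarray
    M_init: float = float("nan")
    FB_init: float = float("nan")
    FT_init: float = float("nan")
    lam_init: float = float("nan")

    @classmethod
    def from_walks(
        cls,
        errors: ProcessErrorSeries,
        M_init: float,
        FB_init: float,
        FT_init: float,
        lam_init: float,
    ) -> "TimeVaryingRates":
        """Build rate series from initial values and log-space random walks."""
        for name, v in (("M_init", M_init), ("FB_init", FB_init),
                        ("FT_init", FT_init), ("lam_init", lam_init)):
            if not v > 0:
                raise ValueError(f"{name} must be > 0 (walks are in log space)")

        def walk(init: float, eps: np.ndarray) -> np.ndarray:
            logs = math.log(init) + np.concatenate([[0.0], np.cumsum(eps)])
            return np.exp(logs)

        return cls(
            M=walk(M_init, errors.eps_M),
            FB=walk(FB_init, errors.eps_B),
            FT=walk(FT_init, errors.eps_T),
            lam=walk(lam_init, errors.eps_lambda),
            M_init=M_init,
            FB_init=FB_init,
            FT_init=FT_init,
            lam_init=lam_init,
        )

    def validate(self, dims: ModelDimensions) -> None:
        n = dims.n_years
        # zero entries are allowed so counterfactuals can switch a mortality
        # source off entirely; walk-generated series are strictly positive
        for name, arr in (("M", self.M), ("FB", self.FB), ("FT", self.FT)):
            a = np.asarray(arr)
            if a.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            if not np.all(a >= 0):
                raise ValueError(f"{name} entries must be >= 0")
        lam = np.asarray(self.lam)
        if lam.shape != (n,):
            raise ValueError(f"lam must have shape ({n},)")
        if not np.all(lam > 0):
            raise ValueError("lam entries must be > 0")


@dataclass
class AgeSchedules:
    """Age-specific scalings of the three mortality sources.

    ``sB``: bycatch selectivity on ages 3-6 (fixed 0 at ages 2 and 7 -- no
    age-2 or age-7 fish of this stock appear in the bycatch); ``v``:
    vulnerability to natural mortality, fixed at 1 for age 3 and in [0.5, 1]
    for ages 4-7; ``sT``: harvest selectivity on ages 4-7 in [0, 1].
    """

    sB: np.ndarray  # ages 3-6
    v: np.ndarray   # ages 4-7 (age 3 is fixed at 1)
    sT: np.ndarray  # ages 4-7

    def __post_init__(self) -> None:
        self.sB = np.asarray(self.sB, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.sT = np.asarray(self.sT, dtype=float)
        if self.v.shape == (5,):  # accept an age 3-7 vector if v[3] == 1
            if not np.isclose(self.v[0], 1.0):
                raise ValueError("v at age 3 is fixed at 1")
            self.v = self.v[1:]
        if self.sB.shape != (4,) or self.v.shape != (4,) or self.sT.shape != (4,):
            raise ValueError("sB, v, sT must each cover four age classes")
        if np.any(self.sB < 0) or np.any(self.sB > 1):
            raise ValueError("sB must lie in [0, 1]")
        if np.any(self.v < 0.5) or np.any(self.v > 1):
            raise ValueError("v must lie in [0.5, 1]")
        if np.any(self.sT < 0) or np.any(self.sT > 1):
            raise ValueError("sT must lie in [0, 1]")

    def sB_full(self, dims: ModelDimensions) -> np.ndarray:
        """Selectivity over the full age axis (zeros at ages 2 and 7)."""
        out = np.zeros(dims.n_ages)
        out[dims.age_index(3):dims.age_index(6) + 1] = self.sB
        return out

    def v_full(self, dims: ModelDimensions) -> np.ndarray:
        """Vulnerability over the full age axis (0 at age 2, 1 at age 3)."""
        out = np.zeros(dims.n_ages)
        out[dims.age_index(3)] = 1.0
        out[dims.age_index(4):] = self.v
        return out

    def sT_full(self, dims: ModelDimensions) -> np.ndarray:
        out = np.zeros(dims.n_ages)
        out[dims.age_index(4):] = self.sT
        return out


@dataclass
class InitialConditions:
    """First-year state for quantities the recursion cannot produce itself.

    ``N_init_by_age``: abundance-at-age for ages 3-7 *entering* the first
    model year (before that year's mortality and maturation), i.e. the
    survivors of the unobserved prior year aged up.  ``free_recruits``:
    juvenile (age-2) abundances for the first two model years, whose brood
    years predate the data.  ``lam_pre``: maturation-schedule value applied to
    all cohorts recruited before the first model year (defaults to the walk's
    initial value when None).
    """

    N_init_by_age: np.ndarray  # ages 3-7, entering year 0
    free_recruits: np.ndarray  # age-2 abundance, years 0 and 1
    lam_pre: Optional[float] = None

    def __post_init__(self) -> None:
        self.N_init_by_age = np.asarray(self.N_init_by_age, dtype=float)
        self.free_recruits = np.asarray(self.free_recruits, dtype=float)
        if self.N_init_by_age.shape != (5,):
            raise ValueError("N_init_by_age must cover ages 3-7")
        if self.free_recruits.shape != (2,):
            raise ValueError("free_recruits must cover the first two years")
        if not (np.all(self.N_init_by_age > 0) and np.all(self.free_recruits > 0)):
            raise ValueError("initial abundances must be > 0")
        if self.lam_pre is not None and not self.lam_pre > 0:
            raise ValueError("lam_pre must be > 0")


@dataclass
class LatentPopulationState:
    """Full latent trajectory (year-major, full age axis, true fish counts).

    ``N``: immature abundance after that year's mortality and maturation
    split (the conventional N[y, a] of age-structured assessment models);
    ``A``: mature returns pre-harvest;
    ``H``/``S``: harvest and escapement; ``B``: stock-specific bycatch; ``D``:
    natural deaths; ``BA``: bycatch expanded to the aggregate (all-stock)
    scale; ``entering``: abundance entering each year before removals
    (entering[y, a] = N[y-1, a-1]); ``theta``: maturation probability applied
    in year y at age a (cohort-indexed via yc = y - (a - 2)); ``pi_*``:
    predicted composition proportions over their respective age ranges.
    """

    dims: ModelDimensions
    N: np.ndarray
    A: np.ndarray
    H: np.ndarray
    S: np.ndarray
    B: np.ndarray
    D: np.ndarray
    BA: np.ndarray
    entering: np.ndarray
    theta: np.ndarray
    pi_S: np.ndarray
    pi_H: np.ndarray
    pi_B: np.ndarray
    S_total: np.ndarray
    H_total: np.ndarray
    run_size: np.ndarray
    vartheta: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# elemental operations
# ---------------------------------------------------------------------------

def maturation_prob(lam, a):
    """Probability that an immature fish of age ``a`` matures this year.

    Modified logistic in age, pinned so that theta = 0.99 at age 7 for every
    positive schedule parameter ``lam``::

        theta = 1 / (1 + exp(lam*(7 - a) + log(1/0.99 - 1)))

    Larger ``lam`` steepens the schedule (older maturation); theta increases
    with age for fixed ``lam``.  Defined for the mature ages 4-7.
    """
    lam = np.asarray(lam, dtype=float)
    a = np.asarray(a)
    if np.any(lam <= 0):
        raise ValueError("maturation schedule parameter must be > 0")
    if np.any((a < 4) | (a > 7)):
        raise ValueError("maturation is defined for ages 4-7")
    z = lam * (7.0 - a) + _MATURATION_OFFSET
    out = 1.0 / (1.0 + np.exp(z))
    return out if out.shape else float(out)


def recruit_juveniles(S_brood, ricker: RickerParameters, eps=0.0):
    """Ricker recruitment: juveniles two years after their brood year.

    R = S * exp(log_alpha - beta*S + eps).  Zero spawners give zero recruits;
    negative spawners are a domain error.
    """
    S_brood = np.asarray(S_brood, dtype=float)
    if np.any(S_brood < 0):
        raise ValueError("spawner abundance must be >= 0")
    out = S_brood * np.exp(ricker.log_alpha - ricker.beta * S_brood + eps)
    return out if out.shape else float(out)


def advance_cohort(N_prev, FB, sB, M, v, theta):
    """One year of competing mortality then the maturation split.

    survivors = N_prev * exp(-(FB*sB + M*v)); the immature continuation is
    survivors*(1 - theta) and the mature return is survivors*theta, so the
    two outputs sum to the survivors exactly.
    """
    N_prev, FB, sB, M, v, theta = map(np.asarray, (N_prev, FB, sB, M, v, theta))
    if np.any(N_prev < 0) or np.any(FB < 0) or np.any(sB < 0) \
            or np.any(M < 0) or np.any(v < 0):
        raise ValueError("abundances and rates must be >= 0")
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta must lie in [0, 1]")
    survivors = N_prev * np.exp(-(FB * sB + M * v))
    A = survivors * theta
    return survivors - A, A


def bycatch_at_age(N_prev, FB, sB, M, v):
    """Baranov catch for the bycatch component of competing mortality.

    B = FB*sB / Z * N_prev * (1 - exp(-Z)) with Z = FB*sB + M*v; the Z -> 0
    limit is 0 (analytic, no division by zero).
    """
    N_prev, FB, sB, M, v = map(np.asarray, (N_prev, FB, sB, M, v))
    if np.any(N_prev < 0) or np.any(FB < 0) or np.any(sB < 0) \
            or np.any(M < 0) or np.any(v < 0):
        raise ValueError("abundances and rates must be >= 0")
    F = FB * sB
    Z = F + M * v
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(Z > 0, np.divide(F, np.where(Z > 0, Z, 1.0)), 0.0)
    out = frac * N_prev * -np.expm1(-Z)
    return out if out.shape else float(out)


def natural_deaths_at_age(N_prev, FB, sB, M, v):
    """Baranov catch for the natural-mortality component (bookkeeping term)."""
    N_prev, FB, sB, M, v = map(np.asarray, (N_prev, FB, sB, M, v))
    F = M * v
    Z = FB * sB + F
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(Z > 0, np.divide(F, np.where(Z > 0, Z, 1.0)), 0.0)
    out = frac * N_prev * -np.expm1(-Z)
    return out if out.shape else float(out)


def expand_bycatch(B, vartheta):
    """Scale stock-specific bycatch up to the aggregate all-stock level.

    ``vartheta`` is the proportion of the age-class bycatch belonging to the
    focal stock, so the aggregate abundance is BA = B / vartheta.
    """
    B, vartheta = np.asarray(B, dtype=float), np.asarray(vartheta, dtype=float)
    if np.any(vartheta <= 0) or np.any(vartheta > 1):
        raise ValueError("vartheta must lie in (0, 1]")
    out = B / vartheta
    return out if out.shape else float(out)


def harvest_at_age(A, FT, sT):
    """Terminal harvest of mature fish: H = A*(1 - exp(-FT*sT)), S = A - H."""
    A, FT, sT = map(np.asarray, (A, FT, sT))
    if np.any(A < 0) or np.any(FT < 0):
        raise ValueError("abundance and harvest rate must be >= 0")
    if np.any((sT < 0) | (sT > 1)):
        raise ValueError("sT must lie in [0, 1]")
    H = A * -np.expm1(-FT * sT)
    return H, A - H


def step_random_walk(prev, eps):
    """One step of a log-space random walk: next = exp(log(prev) + eps)."""
    prev = np.asarray(prev, dtype=float)
    if np.any(prev <= 0):
        raise ValueError("random-walk state must be > 0")
    out = np.exp(np.log(prev) + np.asarray(eps))
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# full trajectory
# ---------------------------------------------------------------------------

def _safe_props(x: np.ndarray, cols: slice) -> np.ndarray:
    """Row-normalize x[:, cols]; rows with zero total become uniform."""
    sub = x[:, cols]
    tot = sub.sum(axis=1, keepdims=True)
    k = sub.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, sub / np.where(tot > 0, tot, 1.0), 1.0 / k)
    return out


def simulate_population(
    dims: ModelDimensions,
    ricker: RickerParameters,
    errors: ProcessErrorSeries,
    rates: TimeVaryingRates,
    schedules: AgeSchedules,
    init: InitialConditions,
    vartheta: Optional[np.ndarray] = None,
    recruits: Optional[np.ndarray] = None,
) -> LatentPopulationState:
    """Run the deterministic forward dynamics for the whole model span.

    Recruitment for the first two model years comes from
    ``init.free_recruits``; from year 3 on it is the Ricker function of the
    model's own escapement two years earlier plus ``errors.eps_R``, which
    closes the recruitment feedback loop (counterfactual escapements
    propagate to future juvenile production).

    ``vartheta`` (years x bycatch ages, focal-stock proportions) is optional;
    when omitted, the aggregate-scale bycatch ``BA`` equals the stock bycatch
    ``B`` (expansion by 1) -- sufficient for scenario work that only tracks
    run sizes.

    ``recruits`` bypasses the Ricker recursion entirely by supplying the
    per-year age-2 abundances directly (the sampler's parameterization);
    recruitment deviations can then be recovered afterwards from the realized
    escapements.
    """
    errors.validate(dims)
    rates.validate(dims)

    Y, nA = dims.n_years, dims.n_ages
    i3, i4 = dims.age_index(3), dims.age_index(4)
    sB_full = schedules.sB_full(dims)
    v_full = schedules.v_full(dims)
    sT_full = schedules.sT_full(dims)
    lam_pre = init.lam_pre if init.lam_pre is not None else rates.lam[0]
    if not lam_pre > 0:
        raise ValueError("pre-model maturation schedule value must be > 0")

    # theta[y, a]: maturation probability in year y at age a (0 below age 4).
    theta = np.zeros((Y, nA))
    ages = np.array(dims.age_list)
    for y in range(Y):
        for a in range(4, dims.ages[1] + 1):
            yc = dims.cohort_of(y, a)
            lam_yc = rates.lam[yc] if yc >= 0 else lam_pre
            theta[y, dims.age_index(a)] = maturation_prob(lam_yc, a)

    Z = rates.FB[:, None] * sB_full[None, :] + rates.M[:, None] * v_full[None, :]
    Z[:, 0] = 0.0  # age-2 juveniles incur no modeled removals in their year

    N = np.zeros((Y, nA))
    A = np.zeros((Y, nA))
    B = np.zeros((Y, nA))
    D = np.zeros((Y, nA))
    entering = np.zeros((Y, nA))
    S_total = np.zeros(Y)

    if recruits is not None:
        recruits = np.asarray(recruits, dtype=float)
        if recruits.shape != (Y,):
            raise ValueError("recruits override must have one entry per year")

    for y in range(Y):
        # age-2 recruits
        if recruits is not None:
            rec = float(recruits[y])
        elif y < 2:
            rec = float(init.free_recruits[y])
        else:
            rec = recruit_juveniles(S_total[y - 2], ricker, errors.eps_R[y])
        enter = np.empty(nA)
        enter[0] = rec
        if y == 0:
            enter[1:] = init.N_init_by_age
        else:
            enter[1:] = N[y - 1, :-1]
        entering[y] = enter

        surv = enter * np.exp(-Z[y])
        A[y] = surv * theta[y]
        N[y] = surv - A[y]
        B[y] = bycatch_at_age(enter, rates.FB[y], sB_full, rates.M[y], v_full)
        D[y] = natural_deaths_at_age(enter, rates.FB[y], sB_full,
                                     rates.M[y], v_full)
        H_y = A[y] * -np.expm1(-rates.FT[y] * sT_full)
        S_total[y] = (A[y] - H_y)[i4:].sum()

    H = A * -np.expm1(-rates.FT[:, None] * sT_full[None, :])
    S = A - H
    run_size = A[:, i4:].sum(axis=1)
    H_total = H[:, i4:].sum(axis=1)

    BA = np.zeros_like(B)
    bc = slice(dims.age_index(dims.bycatch_ages[0]),
               dims.age_index(dims.bycatch_ages[1]) + 1)
    if vartheta is not None:
        vartheta = np.asarray(vartheta, dtype=float)
        if vartheta.shape != (Y, dims.bycatch_ages[1] - dims.bycatch_ages[0] + 1):
            raise ValueError("vartheta must be (n_years, n_bycatch_ages)")
        BA[:, bc] = expand_bycatch(B[:, bc], vartheta)
    else:
        BA[:, bc] = B[:, bc]

    pi_S = _safe_props(S, slice(i4, nA))
    pi_H = _safe_props(H, slice(i4, nA))
    pi_B = _safe_props(BA, bc)

    return LatentPopulationState(
        dims=dims, N=N, A=A, H=H, S=S, B=B, D=D, BA=BA, entering=entering,
        theta=theta, pi_S=pi_S, pi_H=pi_H, pi_B=pi_B, S_total=S_total,
        H_total=H_total, run_size=run_size, vartheta=vartheta,
    )
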