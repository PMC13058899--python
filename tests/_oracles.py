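"""Independent scalar oracles used to cross-check the vectorized model.

Everything here is deliberately written as naive per-fish-class scalar
bookkeeping -- explicit Python loops, fish-by-age dictionaries, no shared
code with the package's array implementations -- so that agreement between
the two is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def scalar_maturation(lam: float, age: int) -> float:
    return 1.0 / (1.0 + math.exp(lam * (7 - age) + math.log(1 / 0.99 - 1)))


def scalar_trajectory(dims, ricker, errors, rates, schedules, init,
                      recruits=None):
    """Per-cohort scalar bookkeeping of the full dynamics.

    Returns dict of year-major arrays comparable to LatentPopulationState.
    """
    Y = dims.n_years
    sB = {a: 0.0 for a in range(2, 8)}
    for j, a in enumerate(range(3, 7)):
        sB[a] = float(schedules.sB[j])
    v = {a: 0.0 for a in range(2, 8)}
    v[3] = 1.0
    for j, a in enumerate(range(4, 8)):
        v[a] = float(schedules.v[j])
    sT = {a: 0.0 for a in range(2, 8)}
    for j, a in enumerate(range(4, 8)):
        sT[a] = float(schedules.sT[j])

    lam_pre = init.lam_pre if init.lam_pre is not None else float(rates.lam[0])

    def theta(y, a):
        if a < 4:
            return 0.0
        yc = y - (a - 2)
        lam = float(rates.lam[yc]) if yc >= 0 else lam_pre
        return scalar_maturation(lam, a)

    N = np.zeros((Y, 6))        # post-split immature, ages 2..7
    A = np.zeros((Y, 6))
    B = np.zeros((Y, 6))
    D = np.zeros((Y, 6))
    H = np.zeros((Y, 6))
    S = np.zeros((Y, 6))
    enter = np.zeros((Y, 6))
    S_tot = np.zeros(Y)

    for y in range(Y):
        if recruits is not None:
            rec = float(recruits[y])
        elif y < 2:
            rec = float(init.free_recruits[y])
        else:
            sp = S_tot[y - 2]
            rec = sp * math.exp(ricker.log_alpha - ricker.beta * sp
                                + errors.eps_R[y])
        enter[y, 0] = rec
        N[y, 0] = rec
        for a in range(3, 8):
            prev = (init.N_init_by_age[a - 3] if y == 0
                    else N[y - 1, a - 1 - 2])
            enter[y, a - 2] = prev
            fb = float(rates.FB[y]) * sB[a]
            mv = float(rates.M[y]) * v[a]
            z = fb + mv
            surv = prev * math.exp(-z)
            th = theta(y, a)
            A[y, a - 2] = surv * th
            N[y, a - 2] = surv * (1 - th)
            if z > 0:
                B[y, a - 2] = fb / z * prev * (1 - math.exp(-z))
                D[y, a - 2] = mv / z * prev * (1 - math.exp(-z))
            ht = 1 - math.exp(-float(rates.FT[y]) * sT[a])
            H[y, a - 2] = A[y, a - 2] * ht
            S[y, a - 2] = A[y, a - 2] - H[y, a - 2]
        S_tot[y] = sum(S[y, a - 2] for a in range(4, 8))

    run = A[:, 2:].sum(axis=1)
    return {"N": N, "A": A, "B": B, "D": D, "H": H, "S": S,
            "entering": enter, "S_total": S_tot, "run_size": run}


def random_process_inputs(dims, rng):
    """A random but admissible parameter set for oracle comparisons."""
    from yukon_ipm.process import (AgeSchedules, InitialConditions,
                                   ProcessErrorSeries, RickerParameters,
                                   TimeVaryingRates)

    Y = dims.n_years
    errors = ProcessErrorSeries(
        eps_R=rng.normal(0, 0.5, Y),
        eps_M=rng.normal(0, 0.1, Y - 1),
        eps_B=rng.normal(0, 0.2, Y - 1),
        eps_T=rng.normal(0, 0.2, Y - 1),
        eps_lambda=rng.normal(0, 0.05, Y - 1),
        sigma_M=0.1, sigma_B_proc=0.2, sigma_T=0.2, sigma_lambda=0.05)
    rates = TimeVaryingRates.from_walks(
        errors,
        M_init=rng.uniform(0.5, 1.5),
        FB_init=rng.uniform(0.005, 0.05),
        FT_init=rng.uniform(0.05, 0.6),
        lam_init=rng.uniform(1.2, 3.0))
    schedules = AgeSchedules(
        sB=rng.uniform(0.01, 0.99, 4),
        v=rng.uniform(0.5, 1.0, 4),
        sT=rng.uniform(0.1, 0.99, 4))
    init = InitialConditions(
        N_init_by_age=rng.uniform(1e3, 1e6, 5),
        free_recruits=rng.uniform(1e5, 2e6, 2))
    ricker = RickerParameters(
        log_alpha=rng.uniform(2.5, 4.5),
        beta=1.0 / rng.uniform(3e4, 3e5),
        sigma_R=0.5)
    return ricker, errors, rates, schedules, init
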