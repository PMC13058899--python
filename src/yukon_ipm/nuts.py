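"""No-U-Turn Hamiltonian Monte Carlo with windowed warmup adaptation.

A self-contained NUTS implementation in the style popularized by Stan:
multinomial sampling over the leapfrog trajectory, dynamic tree doubling with
the no-U-turn termination criterion, dual-averaging step-size adaptation
toward a target acceptance statistic, and a diagonal mass matrix estimated
over expanding warmup windows.  It operates on any target supplying
``logp_grad(q) -> (float, ndarray)`` in an unconstrained space.

Divergences (energy error > 1000 on a leapfrog step) are recorded per draw,
never silently dropped; per-iteration Hamiltonian energies are kept so the
Bayesian fraction of missing information can be diagnosed afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NUTSConfig", "ChainResult", "sample_chain", "DiagonalMetric",
           "DenseMetric"]

_DIVERGENCE = 1000.0


@dataclass
class NUTSConfig:
    n_warmup: int = 1000
    n_draws: int = 1000
    target_accept: float = 0.95
    max_treedepth: int = 12
    init_step: float = 0.1
    init_buffer: int = 75
    term_buffer: int = 50
    base_window: int = 25


class DiagonalMetric:
    """Diagonal inverse-mass kinetic energy (the warmup-adapted default)."""

    def __init__(self, inv_diag: np.ndarray) -> None:
        self.inv_diag = np.asarray(inv_diag, dtype=float)
        self._sqrt_m = 1.0 / np.sqrt(self.inv_diag)

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(self.inv_diag.size) * self._sqrt_m

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.inv_diag * p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ (self.inv_diag * p))


class DenseMetric:
    """Dense inverse-mass matrix (a posterior covariance estimate).

    Useful when strong parameter correlations (e.g. productivity vs capacity
    ridges) make a diagonal metric force very deep trajectories; typically
    estimated from a pilot run and then held fixed.
    """

    def __init__(self, cov: np.ndarray, jitter: float = 1e-8) -> None:
        cov = np.asarray(cov, dtype=float)
        d = cov.shape[0]
        self.cov = cov + jitter * np.eye(d)
        self._L = np.linalg.cholesky(self.cov)
        # p ~ N(0, C^{-1}): p = L^{-T} z
        self._Lt_inv = np.linalg.inv(self._L).T
        self.inv_diag = np.diag(self.cov)  # for the u-turn heuristic

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return self._Lt_inv @ rng.standard_normal(self.cov.shape[0])

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.cov @ p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ (self.cov @ p))


@dataclass
class ChainResult:
    draws: np.ndarray        # (n_draws, dim), post-warmup
    logp: np.ndarray         # (n_draws,)
    energy: np.ndarray       # (n_draws,) Hamiltonian at the selected point
    divergent: np.ndarray    # (n_draws,) bool
    tree_depth: np.ndarray   # (n_draws,)
    accept_stat: np.ndarray  # (n_draws,) mean Metropolis statistic
    step_size: float
    inv_metric: np.ndarray   # diagonal of the inverse mass matrix
    n_leapfrog: int


class _Welford:
    def __init__(self, dim: int) -> None:
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # Stan-style regularization toward unit scale
        return (self.n / (self.n + 5.0)) * var + 1e-3 * (5.0 / (self.n + 5.0))


@dataclass(slots=True)
class _Tree:
    q_minus: np.ndarray
    p_minus: np.ndarray
    g_minus: np.ndarray
    v_minus: np.ndarray     # velocity (M^{-1} p) at the backward endpoint
    q_plus: np.ndarray
    p_plus: np.ndarray
    g_plus: np.ndarray
    v_plus: np.ndarray
    q_prop: np.ndarray
    lp_prop: float
    h_prop: float
    log_w: float
    sum_accept: float
    n_leap: int
    n_div: int
    ok: bool


def _leapfrog(logp_grad, q, p, g, eps, metric):
    """One step; also returns the velocity of the final momentum (reused
    for the kinetic energy and cached for the no-U-turn test)."""
    p1 = p + 0.5 * eps * g
    q1 = q + eps * metric.velocity(p1)
    lp1, g1 = logp_grad(q1)
    p2 = p1 + 0.5 * eps * g1
    return q1, p2, g1, lp1, metric.velocity(p2)


def _no_uturn(q_plus, q_minus, v_plus, v_minus) -> bool:
    dq = q_plus - q_minus
    return (dq @ v_minus >= 0) and (dq @ v_plus >= 0)


def _build_tree(logp_grad, q, p, g, direction, depth, eps, h0, metric,
                rng) -> _Tree:
    if depth == 0:
        q1, p1, g1, lp1, v1 = _leapfrog(logp_grad, q, p, g,
                                        direction * eps, metric)
        h1 = -lp1 + 0.5 * (p1 @ v1)
        if not np.isfinite(h1):
            h1 = np.inf
        log_w = h0 - h1
        divergent = log_w < -_DIVERGENCE
        accept = min(1.0, math.exp(min(log_w, 0.0)))
        return _Tree(q1, p1, g1, v1, q1, p1, g1, v1, q1, lp1, h1,
                     log_w if not divergent else -np.inf,
                     accept, 1, int(divergent), not divergent)

    left = _build_tree(logp_grad, q, p, g, direction, depth - 1, eps, h0,
                       metric, rng)
    if not left.ok:
        return left
    if direction == 1:
        right = _build_tree(logp_grad, left.q_plus, left.p_plus, left.g_plus,
                            direction, depth - 1, eps, h0, metric, rng)
        q_minus, p_minus, g_minus, v_minus = (left.q_minus, left.p_minus,
                                              left.g_minus, left.v_minus)
        q_plus, p_plus, g_plus, v_plus = (right.q_plus, right.p_plus,
                                          right.g_plus, right.v_plus)
    else:
        right = _build_tree(logp_grad, left.q_minus, left.p_minus,
                            left.g_minus, direction, depth - 1, eps, h0,
                            metric, rng)
        q_minus, p_minus, g_minus, v_minus = (right.q_minus, right.p_minus,
                                              right.g_minus, right.v_minus)
        q_plus, p_plus, g_plus, v_plus = (left.q_plus, left.p_plus,
                                          left.g_plus, left.v_plus)

    n_leap = left.n_leap + right.n_leap
    n_div = left.n_div + right.n_div
    sum_accept = left.sum_accept + right.sum_accept
    if not right.ok:
        return _Tree(q_minus, p_minus, g_minus, v_minus, q_plus, p_plus,
                     g_plus, v_plus, left.q_prop, left.lp_prop, left.h_prop,
                     left.log_w, sum_accept, n_leap, n_div, False)

    total_w = np.logaddexp(left.log_w, right.log_w)
    take_right = math.log(rng.uniform()) < right.log_w - total_w \
        if np.isfinite(total_w) else False
    pick = right if take_right else left
    ok = _no_uturn(q_plus, q_minus, v_plus, v_minus)
    return _Tree(q_minus, p_minus, g_minus, v_minus, q_plus, p_plus, g_plus,
                 v_plus, pick.q_prop, pick.lp_prop, pick.h_prop, total_w,
                 sum_accept, n_leap, n_div, ok)


def _warmup_schedule(cfg: NUTSConfig) -> list[int]:
    """Iteration indices at which the mass matrix is re-estimated."""
    w = cfg.n_warmup
    if w < 40:
        return []
    init_buf, term_buf, base = cfg.init_buffer, cfg.term_buffer, \
        cfg.base_window
    if init_buf + term_buf + base > w:
        init_buf = max(int(0.15 * w), 10)
        term_buf = max(int(0.1 * w), 10)
        base = w - init_buf - term_buf
    bounds = []
    start, size = init_buf, base
    while start + size < w - term_buf:
        bounds.append(start + size)
        start += size
        size *= 2
    bounds.append(w - term_buf)
    return bounds


def sample_chain(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    cfg: NUTSConfig,
    rng: np.random.Generator,
    inv_metric=None,
) -> ChainResult:
    """Run one NUTS chain (warmup + sampling) from ``q0``.

    ``inv_metric`` seeds the metric: a 1-D array (or None) gives a diagonal
    inverse mass matrix that warmup windows re-estimate from the chain's own
    draws; a :class:`DenseMetric` (or :class:`DiagonalMetric`) instance is
    held fixed, with warmup adapting the step size only.
    """
    dim = q0.size
    q = np.asarray(q0, dtype=float).copy()
    lp, g = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    if inv_metric is None:
        metric = DiagonalMetric(np.ones(dim))
        adapt_metric = True
    elif isinstance(inv_metric, (DiagonalMetric, DenseMetric)):
        metric = inv_metric
        adapt_metric = False
    else:
        metric = DiagonalMetric(np.asarray(inv_metric, dtype=float))
        adapt_metric = True
    eps = _find_initial_step(logp_grad, q, lp, g, metric, cfg.init_step, rng)

    # dual averaging state
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    windows = _warmup_schedule(cfg) if adapt_metric else []
    welford = _Welford(dim)
    n_total = cfg.n_warmup + cfg.n_draws
    draws = np.empty((cfg.n_draws, dim))
    out_lp = np.empty(cfg.n_draws)
    out_energy = np.empty(cfg.n_draws)
    out_div = np.zeros(cfg.n_draws, dtype=bool)
    out_depth = np.zeros(cfg.n_draws, dtype=int)
    out_accept = np.empty(cfg.n_draws)
    total_leap = 0
    window_start = min(cfg.init_buffer, cfg.n_warmup // 3)

    for it in range(n_total):
        p0 = metric.sample_momentum(rng)
        v0 = metric.velocity(p0)
        h0 = -lp + 0.5 * (p0 @ v0)
        q_minus = q_plus = q
        p_minus = p_plus = p0
        g_minus = g_plus = g
        v_minus = v_plus = v0
        q_prop, lp_prop, h_prop = q, lp, h0
        log_w = 0.0
        divergent = False
        sum_accept, n_leap = 0.0, 0
        depth = 0
        while depth < cfg.max_treedepth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == 1:
                sub = _build_tree(logp_grad, q_plus, p_plus, g_plus, 1,
                                  depth, eps, h0, metric, rng)
                q_plus, p_plus, g_plus, v_plus = (sub.q_plus, sub.p_plus,
                                                  sub.g_plus, sub.v_plus)
            else:
                sub = _build_tree(logp_grad, q_minus, p_minus, g_minus, -1,
                                  depth, eps, h0, metric, rng)
                q_minus, p_minus, g_minus, v_minus = (sub.q_minus,
                                                      sub.p_minus,
                                                      sub.g_minus,
                                                      sub.v_minus)
            sum_accept += sub.sum_accept
            n_leap += sub.n_leap
            divergent = divergent or sub.n_div > 0
            if not sub.ok:
                break
            if np.isfinite(sub.log_w) and \
                    math.log(rng.uniform()) < sub.log_w - log_w:
                q_prop, lp_prop, h_prop = sub.q_prop, sub.lp_prop, sub.h_prop
            log_w = np.logaddexp(log_w, sub.log_w)
            if not _no_uturn(q_plus, q_minus, v_plus, v_minus):
                break
            depth += 1

        q = q_prop
        lp = lp_prop
        _, g = logp_grad(q)
        accept_stat = sum_accept / max(n_leap, 1)
        total_leap += n_leap

        if it < cfg.n_warmup:
            # dual averaging
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (cfg.target_accept
                                                 - accept_stat)
            log_eps = mu - math.sqrt(da_count) / gamma * h_bar
            w_t = da_count ** -kappa
            log_eps_bar = w_t * log_eps + (1 - w_t) * log_eps_bar
            eps = math.exp(log_eps)
            # mass-matrix windows
            if it >= window_start and windows:
                welford.push(q)
            if windows and it + 1 == windows[0]:
                metric = DiagonalMetric(welford.variance())
                welford = _Welford(dim)
                windows.pop(0)
                eps = math.exp(log_eps_bar)
                mu = math.log(10.0 * eps)
                h_bar, log_eps_bar, da_count = 0.0, 0.0, 0
            if it + 1 == cfg.n_warmup:
                eps = math.exp(log_eps_bar)
        else:
            k = it - cfg.n_warmup
            draws[k] = q
            out_lp[k] = lp
            out_energy[k] = h_prop
            out_div[k] = divergent
            out_depth[k] = depth
            out_accept[k] = accept_stat

    return ChainResult(draws=draws, logp=out_lp, energy=out_energy,
                       divergent=out_div, tree_depth=out_depth,
                       accept_stat=out_accept, step_size=eps,
                       inv_metric=np.asarray(metric.inv_diag),
                       n_leapfrog=total_leap)


def _find_initial_step(logp_grad, q, lp, g, metric, eps0, rng) -> float:
    """Double/halve the step until one leapfrog's acceptance crosses 0.5."""
    eps = eps0
    p = metric.sample_momentum(rng)
    h0 = -lp + metric.kinetic(p)
    _, p1, _, lp1, v1 = _leapfrog(logp_grad, q, p, g, eps, metric)
    h1 = -lp1 + 0.5 * (p1 @ v1) if np.isfinite(lp1) else np.inf
    log_ratio = h0 - h1 if np.isfinite(h1) else -np.inf
    direction = 1 if log_ratio > math.log(0.5) else -1
    for _ in range(50):
        eps = eps * (2.0 ** direction)
        _, p1, _, lp1, v1 = _leapfrog(logp_grad, q, p, g, eps, metric)
        h1 = -lp1 + 0.5 * (p1 @ v1) if np.isfinite(lp1) else np.inf
        log_ratio = h0 - h1 if np.isfinite(h1) else -np.inf
        if (direction == 1 and log_ratio <= math.log(0.5)) or \
                (direction == -1 and log_ratio >= math.log(0.5)):
            break
    return eps
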