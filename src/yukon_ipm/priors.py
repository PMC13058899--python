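"""Prior distributions for every estimated parameter.

Each top-level parameter carries a (possibly truncated) normal prior; bounds
are honored by truncation, whose normalization constant is included so that
the log-prior is a proper log-density.  Random-walk innovations are standard
normal under the non-centered parameterization, and the first-year latent
abundances get diffuse lognormal priors (log-SD 5), which is what keeps the
state-space likelihood proper in the absence of any stated initialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["TruncNormal", "PriorConfig", "log_prior"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mean, sd) truncated to [lower, upper] (closed bounds)."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    @property
    def log_z(self) -> float:
        """Log of the truncation normalization constant."""
        hi = norm.cdf((self.upper - self.mean) / self.sd)
        lo = norm.cdf((self.lower - self.mean) / self.sd)
        return math.log(hi - lo)

    def logpdf(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if np.any((x < self.lower) | (x > self.upper)):
            return float("-inf")
        z = (x - self.mean) / self.sd
        ll = -math.log(self.sd) - 0.5 * _LOG_2PI - 0.5 * z * z - self.log_z
        return float(np.sum(ll))

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Draw by inverse-CDF through the truncated interval."""
        lo = norm.cdf((self.lower - self.mean) / self.sd)
        hi = norm.cdf((self.upper - self.mean) / self.sd)
        u = rng.uniform(lo, hi, size=size)
        return self.mean + self.sd * norm.ppf(u)


@dataclass
class PriorConfig:
    """One prior entry per estimated top-level parameter.

    The init entries for the mortality walks are priors on the *log* initial
    rates; the maturation-schedule init is a prior on the schedule value
    itself, bounded below by zero.
    """

    log_alpha: TruncNormal = TruncNormal(0.0, 12.5)
    beta: TruncNormal = TruncNormal(0.0, 5.0, lower=0.0)
    sigma_R: TruncNormal = TruncNormal(0.0, 5.0, lower=0.0)
    sigma_M: TruncNormal = TruncNormal(0.0, 5.0, lower=0.0)
    sigma_B_proc: TruncNormal = TruncNormal(0.0, 5.0, lower=0.0)
    sigma_lambda: TruncNormal = TruncNormal(0.0, 5.0, lower=0.0)
    sigma_T: TruncNormal = TruncNormal(0.0, 5.0, lower=0.0)
    sB: TruncNormal = TruncNormal(0.0, 1.0, lower=0.0, upper=1.0)
    v: TruncNormal = TruncNormal(0.0, 1.0, lower=0.5, upper=1.0)
    sT: TruncNormal = TruncNormal(0.0, 1.0, lower=0.0, upper=1.0)
    M_init_log: TruncNormal = TruncNormal(0.0, 5.0)
    FB_init_log: TruncNormal = TruncNormal(0.0, 7.5)
    lam_init: TruncNormal = TruncNormal(1.0, 1.0, lower=0.0)
    FT_init_log: TruncNormal = TruncNormal(0.0, 5.0)
    muG: TruncNormal = TruncNormal(0.0, 5.0)
    sigmaG: TruncNormal = TruncNormal(0.0, 5.0, lower=0.0)
    # artifact plumbing: diffuse lognormal initialization of latent states
    log_recruit_init: TruncNormal = TruncNormal(math.log(1e5), 5.0)
    log_pool_init: TruncNormal = TruncNormal(math.log(2e4), 5.0)

    def entries(self) -> dict[str, TruncNormal]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def log_prior(params: dict, cfg: PriorConfig | None = None) -> float:
    """Sum of prior log-densities over the supplied parameter values.

    ``params`` maps prior-entry names to scalars or arrays (vector-valued
    entries such as ``sB`` contribute one term per element).  Out-of-bounds
    values return -inf.  Walk innovations (standard normal under the
    non-centered parameterization) may be supplied under ``z_*`` keys.
    """
    cfg = cfg or PriorConfig()
    entries = cfg.entries()
    total = 0.0
    for name, value in params.items():
        if name.startswith("z_"):
            z = np.asarray(value, dtype=float)
            total += float(np.sum(-0.5 * _LOG_2PI - 0.5 * z * z))
            continue
        if name not in entries:
            raise KeyError(f"no prior entry for parameter {name!r}")
        total += entries[name].logpdf(value)
        if not np.isfinite(total):
            return float("-inf")
    return float(total)
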