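# yukon-ipm

An integrated, age-structured life-cycle population model for Canada-origin
Yukon River Chinook salmon (*Oncorhynchus tshawytscha*) — the stock whose
run sizes collapsed by roughly an order of magnitude over 2003-2023 — built
for quantitative fisheries scientists who want to estimate stage-specific
constraints on productivity (juvenile recruitment, post-juvenile natural
mortality, trawl bycatch, terminal harvest) from multiple noisy data
streams, and then ask counterfactual and forward-looking questions about
recovery.

## The model in brief

Fish enter at age 2 (ocean age 0) through a Ricker spawner-recruit map of
the escapement two brood years earlier,

```
N[y,2] = S[y-2] · exp(log α − β·S[y-2] + ε_R[y]),     ε_R ~ N(0, σ_R),
```

then, at ages a = 3..7, survive competing instantaneous mortality from
bycatch (F_B[y]·s_B[a]) and natural causes (M[y]·v[a]), mature with
cohort-specific probability

```
θ[yc,a] = 1 / (1 + exp(λ[yc]·(7 − a) + log(1/0.99 − 1)))     (θ = 0.99 at age 7),
```

and — once mature — are harvested at F_T[y]·s_T[a]; the survivors spawn and
close the loop.  M, F_B, F_T and λ follow random walks in log space.  The
joint likelihood integrates five data streams: a juvenile marine abundance
index, escapement and harvest with age compositions, total (all-stock)
bycatch counts with age compositions, and per-age genetic stock assignments
with a logit-normal among-year hierarchy.  Estimation is Bayesian via an
in-package No-U-Turn sampler with exact hand-derived gradients; the fitted
posterior feeds retrospective counterfactuals (zero bycatch, zero harvest,
baseline mortality, favorable recruitment, combinations) and stochastic
forward projections with recovery classification.

Because the study's input tables are not distributed as flat files, the
package ships a synthetic-data generator that reproduces the documented
statistical structure (lognormal indices, multinomial compositions,
binomial genetic assignments, missing survey years 2005/2008/2020) around
the reported parameter scales; see `docs/methods.md` for every default and
its provenance.

## Worked example

```python
import numpy as np
from yukon_ipm import make_fixture
from yukon_ipm.inference import fit, MCMCConfig, diagnostics
from yukon_ipm.retrospective import PAPER_SCENARIOS, run_scenario
from yukon_ipm.projection import (ProjectionConfig, project,
                                  classify_recovery,
                                  conditional_recovery_fraction)

scn, truth, data = make_fixture("paper_scale", seed=7)   # 2003-2023 layout
ens = fit(data, mcmc=MCMCConfig(n_chains=2, n_iter=1100, n_warmup=500,
                                seed=0, target_accept=0.92,
                                max_treedepth=10))
rep = diagnostics(ens)
print(f"max split R-hat: {rep['max_rhat']:.3f}   "
      f"divergences: {rep['n_divergent']}")

alpha = np.exp(ens.flat_param("log_alpha"))
print(f"alpha: median {np.median(alpha):.1f}  "
      f"[{np.quantile(alpha, 0.025):.1f}, {np.quantile(alpha, 0.975):.1f}]")

res = run_scenario(ens, PAPER_SCENARIOS["baseline_mortality"],
                   max_draws=200, rng=np.random.default_rng(1))
diff = np.median(res.run_size - res.fitted_run_size, axis=0)
print(f"baseline-mortality counterfactual, median run-size gain in 2023: "
      f"{diff[-1]:,.0f} fish")

proj = project(ens, ProjectionConfig(horizon_years=7, seed=2),
               max_draws=400)
cls = classify_recovery(proj)
```

The fit takes a few minutes on one CPU; the full script (including the
fixed-mortality projection grid) prints:

```
max split R-hat: 1.011   divergences: 0
alpha:  median 52.7  [27.3, 114.2]   (generating value 48)
1/beta: median 86,420 spawners   (generating value 81,178)
M 2003: median 0.96    M 2023: median 1.62   (generating 1.10 -> 1.68)
baseline-mortality counterfactual, median run-size gain in 2023: 112,992 fish
2030 recovery threshold (90th pct of projected run sizes): 188,258 fish
recovery fraction with M held at its pre-2016 level: 0.24
recovery fraction with M held at its recent level: 0.03
```

Reading the output: the posterior recovers the generating productivity
(α, juveniles per spawner at low stock) and capacity (1/β, in spawners)
within their credible intervals, and tracks the generator's rise in
post-juvenile natural mortality M across 2003-2023.  The
baseline-mortality counterfactual re-runs every posterior draw with
2016-2023 mortality capped at that draw's pre-2016 median: the printed
number is the median run-size gain in 2023 had the mortality rise not
happened.  The projection block continues each draw seven years with
harvest off and bycatch at its post-2011 mean, labels draws whose 2030 run
size reaches the ensemble's 90th percentile as recoveries, and then
contrasts recovery fractions between projections with natural mortality
held at the pre-2016 median versus the recent level in every projection
year — the mortality bottleneck in one pair of numbers.

The same pipeline is scriptable from the shell:

```
yukon-ipm simulate -o data/ --seed 7
yukon-ipm fit data/ -o fits/run1 --chains 4 --iter 1800 --warmup 800
yukon-ipm retrospective fits/run1 -o retro/ --scenario all
yukon-ipm project fits/run1 -o proj/ --horizon 7
```

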