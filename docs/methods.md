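# Methods

## The model

`yukon_ipm` implements an integrated, age-structured life-cycle model for a
single Chinook salmon stock (built around the Canada-origin Yukon River
stock unit), observed over calendar years 2003-2023 and ages 2-7.

**Process model.** Fish recruit at age 2 (ocean age 0) through a Ricker
spawner-recruit function of the escapement two years earlier,

    N[y,2] = S[y-2] * exp(log_alpha - beta * S[y-2] + eps_R[y]),
    eps_R[y] ~ Normal(0, sigma_R),

so `alpha` is juveniles-per-spawner at low stock size and `1/beta` the
capacity in spawners.  At ages 3-7, immature fish face two competing
instantaneous mortality sources in each year — trawl bycatch `FB[y]*sB[a]`
and natural mortality `M[y]*v[a]` — after which a cohort-specific fraction

    theta[yc,a] = 1 / (1 + exp(lam[yc]*(7-a) + log(1/0.99 - 1)))

matures and returns to the river (pinned at 0.99 at age 7: the schedule
forces maturity by the terminal age for every positive `lam`).  Mature fish
are harvested at `FT[y]*sT[a]`; survivors are the spawning escapement that
closes the loop.  `M`, `FB`, `FT` (per year) and `lam` (per cohort) follow
random walks in log space.  Stock-specific bycatch follows the Baranov
catch equation for competing mortality and is expanded to the aggregate
(all-stock) scale by the focal-stock proportions `vartheta[y,a]`.

**Observation model.**  Five data streams: a juvenile abundance index
(lognormal around `N[y,2]`, log-SD 0.25, missing in 2005/2008/2020),
escapement and harvest abundances (lognormal, log-SDs 0.10 and 0.15) with
age compositions (multinomial at effective sample size 100), total bycatch
counts (lognormal, log-SD 0.10) with age compositions (multinomial at the
observed scale-sample sizes), and per-age genetic assignments of bycatch
samples to the focal stock (binomial), with logit-scale proportions pooled
across years by an age-specific normal hierarchy.  All observation SDs and
effective sample sizes are fixed, not estimated.  Lognormal likelihoods are
median-parameterized (location `log(pred)`), the standard reading in
fisheries state-space models and the one that makes the fixed log-SDs
interpretable as CVs.  Observed composition proportions are converted to
integer counts by largest-remainder rounding at the effective sample size
(a proper pmf); a fractional-count variant is available behind
`ObservationErrorConfig(fractional_agecomp=True)` for sensitivity.

## Estimation

The joint posterior is sampled with an in-package implementation of the
No-U-Turn Sampler: multinomial sampling over dynamically doubled leapfrog
trajectories, dual-averaging step-size adaptation, and a diagonal mass
matrix re-estimated over expanding warmup windows (a dense, pilot-estimated
metric is available).  Gradients are exact: the posterior is written twice,
once on a small reverse-mode autodiff tape and once as a hand-written
adjoint; the two agree to machine precision in the test suite and the fast
path runs at NUTS leapfrog rates.

Parameterization choices that shape the geometry:

* the four log-space random walks are **non-centered** (standard-normal
  innovations scaled by the walk SDs), avoiding funnels when walk SDs are
  small;
* juvenile abundances `log N[y,2]` are **centered free states**; the Ricker
  recursion enters as a process-prior term
  `Normal(log N[y,2] | log Ricker(S[y-2]), sigma_R)` for years whose brood
  year falls inside the model span.  The juvenile survey pins these states
  directly, the whole forward pass vectorizes along cohort diagonals, and
  the recruitment deviations are recovered deterministically per draw for
  the counterfactual machinery.  The first two years' recruits (brood years
  before the data) and the age-3-7 abundances entering the first year get
  diffuse lognormal priors (log-SD 5), the standard state-space
  initialization for a model whose early cohorts predate the data;
* bounded parameters (selectivities in [0,1], vulnerability in [0.5,1] with
  age 3 fixed at 1, all SDs positive) are sampled through logit/log
  transforms with Jacobians, so every retained draw respects its bounds.

Priors are weakly informative truncated normals (e.g. `log alpha ~
Normal(0, 12.5)`; selectivities `Normal(0,1)` truncated to their boxes;
walk SDs half-`Normal(0,5)`), with truncation constants included.
Selectivity is deliberately not normalized; the known confounding between
fully selected rates and selectivities is accepted and documented.

Convergence criteria: split R-hat <= 1.01 and bulk ESS >= 1000 on every
parameter, zero divergent transitions, no chain with BFMI below 0.3.  The
full-scale configuration (5 chains x 15,000 iterations, 5,000 warmup) is
the `MCMCConfig` default; desk-scale work uses 2-4 chains of 2,000-3,000
iterations, which already meets every criterion on synthetic data (the
smoke fit in the acceptance suite) and is calibrated enough for interval
coverage.

## Synthetic data

The generator emulates the study conditions so every stage is testable
without the (undeposited) survey and run-reconstruction tables.  Defaults
anchored to reported estimates: `alpha = 48` juveniles/spawner, capacity
`1/beta = 81,178` spawners; natural mortality near 1.1 through 2015 rising
to 1.5 by 2020 (the marine-heatwave-era increase); bycatch selectivity
(0.03, 0.15, 0.81, 0.21) over ages 3-6; vulnerability (1, 0.67, 0.60, 0.64,
0.93) over ages 3-7; juvenile survey missing in 2005, 2008, 2020; roughly 1
in 10 bycaught fish genotyped, with genetic data available from 2011 (the
full-observer-coverage era) so the logit-normal hierarchy is genuinely
exercised on earlier years.

Quantities the study does not print are package choices fixed once at
realistic magnitudes and exposed as configuration: recruitment-error SD 0.5;
harvest mortality declining geometrically 0.45 -> 0.05 (tracking the
shrinking runs); bycatch mortality 0.01 dropping to 0.005 at the 2011 hard
cap; maturation schedule drifting 2.2 -> 1.8 (younger maturation); focal
stock a 2-3.5% share of the aggregate bycatch.  These produce run sizes of
order 10^4-10^5 fish and stock-specific bycatch of order 10^2-10^3 per
year.  Initial conditions come from a deterministic 40-year spin-up at
first-year rates, so the first-year age structure is consistent with the
generating parameters rather than seeded ad hoc.

What the generator does **not** emulate: spatial survey design and CPUE
expansion, genotype-level stock identification, en-route (in-river) adult
mortality as a separate process, density-dependent marine survival, or
environmental covariates on any rate.  Passing tests therefore demonstrate
internal correctness and recoverability under the model's own assumptions,
not robustness to the structural misspecifications real data carry.

## Counterfactuals and projections

Retrospective scenarios re-run the deterministic dynamics per posterior
draw with overrides — zero bycatch, zero harvest, post-2016 natural
mortality capped at the pre-2016 median, recruitment deviations pinned at
the 95th percentile of the per-year posterior-median deviations, and the
mortality-plus-recruitment combination — while all else keeps the draw's
values.  Recruitment is recomputed inside each counterfactual from its own
escapements, so effects propagate through the spawner-recruit function;
zeroing bycatch leaves the extra survivors exposed to the harvest rate of
their return year.  The pre-2016 reference is the **within-draw** median
(keeping each trajectory coherent with its own joint draw); a
posterior-pooled variant is a flag.  Percentiles interpolate linearly
between order statistics.

Projections continue each draw 7 years (optionally 14) past the data:
mortality and maturation walks continue with fresh innovations from the
draw's SDs, recruitment deviations are Normal(0, sigma_R) or fixed, harvest
is zero, and bycatch mortality is pinned at the draw's mean over the
hard-cap era (2011 onward).  Cohorts recruited before the projection window
keep their estimated schedules.  Recovery conditioning recomputes the upper
threshold as the 90th percentile of the produced final-year run-size
distribution (never hard-coded); the lower threshold defaults to 16,000
fish, the recent-low run size.  Conditional recovery fractions are reported
with their subset sizes, and an empty conditional set yields NaN with an
explicit flag rather than a silent zero.

## Numerical choices and edge cases

* Baranov fractions return the analytic 0 limit when the total hazard is 0.
* The age-7 maturation residual (1% of post-mortality age-7 fish, with no
  age-8 class) is dropped as implicit mortality; the conservation tests
  quantify it exactly rather than hiding it.
* Cohort indexing: a fish aged `a` in year `y` belongs to the juvenile
  year-class `y - (a - 2)`; cohorts recruited before the first model year
  use the maturation walk's initial value.
* Composition predictions are kept strictly positive by construction;
  observed zeros are allowed, and a zero prediction against a positive
  count yields -inf loudly.
* Scenario overrides may set rate series exactly to zero; walk-generated
  series are strictly positive.
* NUTS divergence threshold: energy error > 1000; divergences and energies
  are stored per draw and surfaced by the diagnostics report.

## Problem sizes used by the default test run

The test suite and the acceptance script re-run everything from scratch at
sizes chosen for a single-CPU desk machine: oracle equivalence on 100
random parameter sets; one full (21-year) synthetic smoke fit at 4 chains x
2,000 post-warmup draws checked against all convergence criteria (R-hat,
ESS, divergences, BFMI); recovery coverage aggregated over that fit plus
nine reduced fits (2 chains x 2,000 iterations, 1,000 warmup) on
independent datasets — ten datasets in all — scored over productivity,
capacity, recruitment SD, all selectivity/vulnerability schedules and the
21-year mortality series (>= 80% aggregate coverage of 95% intervals).
The speed that makes this affordable comes from evaluating the posterior
and its gradient in a compiled scalar kernel (about 0.02 ms per gradient at
the 21-year scale).

## Known limitations

* A diagonal metric cannot remove the productivity-capacity and
  selectivity-rate ridges; trees are correspondingly deep (depth 7-9).
  The `DenseMetric` pilot path helps marginally and is off by default.
* With only two chains and short runs, split R-hat has a noise floor near
  1.01-1.02; the convergence bar is applied to the 4-chain configuration.
* The favorable-recruitment counterfactual pushes escapements far beyond
  capacity, where Ricker overcompensation produces genuine non-monotone
  responses; tests assert the within-cohort and late-period contrasts that
  are implied by the model, not global dominance of any scenario.
* Observation SDs and effective sample sizes are fixed by design; there is
  no machinery to estimate them.
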