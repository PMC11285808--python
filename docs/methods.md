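# Methods

## The experiment being modelled

A natural-transmission design: wild-caught donor flies of one species
group (*D. melanogaster*, *D. immigrans*, or the *D. obscura* group — the
obscura species are pooled because females are hard to distinguish) are
co-housed with 20 laboratory *D. melanogaster* females per vial for a
3-day exposure window; a fourth arm co-houses laboratory males as a
handling control. Donor pools are assayed per vial for each virus;
recipients are followed individually for up to 72 days, their adult
offspring counted, and their infections assayed at death for the viruses
their donor pool carried. The package models ~43 vials (11 per wild group
plus 10 controls) with pools of 8–20 wild flies and nine transmissible
viruses.

## Pooled prevalence and support intervals

A pool of `n` flies tests positive iff at least one member carries the
virus, so the log-likelihood of individual prevalence `p` is
`Σ_pos log(1 − (1−p)^n_i) + Σ_neg n_i log(1−p)`. This is unimodal in `p`;
the MLE is found by bounded scalar minimization (tolerance 1e-10) and the
support interval is the set within **2 natural-log-likelihood units** of
the maximum, located by Brent root-finding on each flank. The 2-unit drop
corresponds to a likelihood-ratio statistic of 4, i.e. ~95.4% asymptotic
coverage under the χ²₁ calibration; this is verified by simulation (50
pools of size 8–20, prevalence 0.05, 2000 replicates). The alternative
reading (a drop of 2 in 2·ln L, i.e. χ² = 2) would give ~84% intervals
and can be obtained by passing `drop=1.0` to `estimate_prevalence`.
Boundary cases: all-negative data give `p̂ = 0` with a closed-form upper
bound; all-positive give `p̂ = 1`.

Transmission rates are the unit-pool special case, where the MLE reduces
exactly to the binomial proportion. Donor-group transmission is compared
with an exact Fisher–Freeman–Halton r×2 test: all tables with the
observed margins are enumerated and those with hypergeometric probability
at most the observed table's (log-scale comparison, tolerance 1e-12, so
equal-probability tables are always included) are summed. Exact
enumeration is feasible because the tables here are small (a handful of
viruses per donor group).

## MCMC engine

Both regression models run on a purpose-built sampler rather than a
generic PPL, because the variance structures (infected-only virus random
effect; per-trait hurdle variances with zero covariance) are specific and
conjugacy makes them fast.

**Gaussian LMM (`gibbs_lmm`).** Blocked Gibbs: fixed effects and each
random-effect block are drawn from conjugate multivariate-normal full
conditionals; each variance component from its conjugate inverse-gamma
full conditional. Priors default to N(0, 1e10) on fixed effects and
inverse-gamma with (V = 1, ν = 0.002) on variances — nearly flat, and
exposed in `PriorSpec` because an analyst may want proper alternatives.
Verified against the closed-form conjugate posterior (fixed residual
variance), against REML fits (statsmodels `MixedLM`), and by frequentist
HPD coverage in parameter-recovery simulations.

**Hurdle-Poisson (`hurdle_poisson_mcmc`).** Each observation carries two
latent values: the logit of the zero probability and the log rate of a
zero-truncated Poisson for positive counts. Latents are updated by
random-walk Metropolis, vectorized over observations (valid because they
are conditionally independent given the effects), with a scalar proposal
scale per trait adapted toward 44% acceptance during burn-in and frozen
afterwards to preserve detailed balance. For zero counts the count-trait
latent carries no likelihood and is Gibbs-drawn from its Gaussian prior.
Given the latents, both traits are Gaussian sub-models and reuse the
conjugate updates; the latent residual variances act as overdispersion
parameters and can be fixed via configuration. Between-trait covariance
is structurally zero.

**Diagnostics.** HPD intervals are the shortest contiguous window of
sorted draws containing ⌈mass·n⌉ draws, ties broken toward the smallest
lower endpoint. ESS uses the initial-positive-sequence autocorrelation
estimator, `n / (1 + 2Σρ_k)` truncated at the first non-positive ρ_k; a
zero-variance series is defined to have ESS = n. pMCMC is
`2·min(P(>0), P(<0))`, floored at `2/n` and capped at 1. Non-finite
draws abort the run with the iteration index. Thinning is
`⌊(total − burn) / recorded⌋`; burn-in defaults to a fixed fraction of
the chain. Summaries flag parameters whose ESS falls below a
configurable floor (production chains should use the `full` profile:
1e6 steps, 10k recorded).

## Lifespan models

Model A: `lifespan ~ 1 + virus indicators`, vial random effect. Model B:
`lifespan ~ 1 + n_infections`, with a per-virus random intercept applied
only to infected flies — a fly infected with k viruses receives the sum
of its k virus deviations — all deviations sharing one variance, plus the
vial effect. Viruses with zero infected flies are dropped (inestimable
contrast) and reported.

Censoring: day-72 survivors are included with lifespan recorded at the
limit (the Gaussian model has no censoring machinery; this treats the
limit as the observation, which slightly attenuates harmful effects), or
excluded via `include_censored=False`. With no censored flies the two
options are exactly equivalent.

Percent reduction for virus v is computed per draw as `100·(−β_v/μ₀)`
with μ₀ the model intercept (predicted uninfected lifespan at vial effect
zero), so the interval propagates uncertainty in both numerator and
denominator. Dividing by the observed uninfected mean instead would give
nearly identical values here; the intercept is the default because it is
the model's own uninfected prediction.

## Fecundity models

Count part: intercept (uninfected baseline) plus one log-rate indicator
effect per virus, so `100·(1 − e^{b_v})` is the percent reduction in
offspring conditional on any. Zero part: cell-means levels — one logit
for uninfected flies and one per estimable virus — with no shared
intercept, so each level maps directly to a probability of producing no
offspring. A virus is zero-part estimable iff at least one of its
infected flies produced zero offspring and at least one produced some;
excluded viruses are reported with a reason code. A fly infected only
with zero-part-excluded viruses contributes a zero row to the zero-part
design (its zero probability is predicted by the vial effect alone) — a
knowingly rough treatment of a rare case.

The early-life analysis uses the same model on the early-window count,
excluding flies that died before the window closed so lifespan cannot
mechanically drive the response. The early/late association is
summarized by a Pearson correlation with a Fisher-z interval.

The posterior-predictive zero check simulates, for each of `n_draws`
posterior draws, a full offspring vector at the observed covariates
(fixed effects, fitted vial effects, fresh latent residuals) and compares
the observed zero count with the central 95% band of the simulated
counts.

## Synthetic-experiment generator

The generator draws donor pools (pool positive iff ≥1 carrier, binomial
carriage per species group), exposes each recipient to its pool's
positive viruses, infects independently per exposed virus with
probability π_v, and generates lifespan (Gaussian, additive virus and
vial effects, observed as the ceiling day, truncated at day 72 with a
censored flag) and offspring (the hurdle process above). Detection
applies an assay sensitivity (default 1) at death only.

`paper_like_config()` freezes the study-like conditions: 43 vials, nine
viruses, lifespan effects of −30%, −37%, −23%, −17% and −11% of the
40-day baseline for DimmNV, Prestney Burn, galbut, DmelNV and Muthill;
count-part fecundity effects of log(1−0.46), log(1−0.39) and log(1−0.24)
for DmelNV, DimmNV and Muthill; a positive zero-part effect for Muthill.
Baseline lifespan 40 d with residual SD 21 d and vial SD 2 d (vial
variance ~1% of the total, matching the negligible vial contribution the
models should recover, and giving a closed-form required-n for a 1%
reduction in the tens of thousands); baseline fecundity e^{b₀} ≈ 102
offspring with ~10% zero probability. Carriage and transmission
probabilities are calibrated so that in expectation ~35% of exposed flies
acquire at least one infection, predominantly singly (closed-form
check in `expected_infection_summary`). Each fly's early-window share of
lifetime offspring is Beta-distributed (mean 0.4, concentration 5),
which reproduces a moderate early/late correlation (~0.3) rather than
the near-deterministic split a fixed fraction would give.

What the generator does **not** emulate: within-host dynamics or
clearance time-courses (sensitivity is a static end-of-life
misclassification), dependence between co-infecting viruses, any
lifespan–fecundity coupling beyond shared infections, and onward
transmission to partners or offspring. Passing tests therefore validate
the estimators under the assumed data-generating process, not the
biology of any real experiment; re-analyses of clearance-style
misclassification are supported generically through
`apply_reclassification`.

## Power analysis

`simulate_power` draws lifespans under the model-A generative process
with one virus at −pct·μ/100 days and applies a detection rule per
replicate: the default Welch two-sample t-test, or a full mixed-model
refit with pMCMC < α (slow; used to spot-check that the shortcut agrees
within a few percentage points). With σ_vial = 0 the simulation matches
the closed-form two-sample normal power formula. `required_n` inverts
power over n by bisection (or in closed form), and errors when the
target is unreachable (e.g. zero effect). Baseline mean and variance
components must be supplied explicitly, typically from a fitted model.

## Problem sizes and numerical choices

Test and validation runs use reduced problem sizes chosen so the whole
suite exercises every claim at useful precision: chains of 1.2k–3k steps
(recorded without thinning, since HPD endpoints estimated from too few
draws bias the interval short), 150–400 replicate fits for coverage and
calibration checks (tolerances stated as 3 binomial or Monte-Carlo SEs),
2000 replicates for interval calibration, and exhaustive enumeration
where feasible (unit-pool MLEs, Fisher tables). Variance draws are
floored at 1e-12 to keep degenerate inputs (e.g. a zero-variance
response) finite. All stage-level randomness derives from one integer
seed via named, independent streams.

## Known limitations

- The Gaussian lifespan model treats censored ages as observed; with
  ~5% of flies surviving past day 72 this slightly attenuates effects
  and shrinks the fitted residual variance relative to the generating
  value (visible as a modest underestimate of the required-n figure).
- The hurdle sampler's latent random-walk updates mix more slowly than
  the conjugate Gaussian blocks; ESS per recorded draw is ~0.2–0.5, so
  production runs should rely on the `full` chain profile.
- Prevalence estimation assumes perfect pool-level assays and a common
  prevalence across a species group's pools.
- The exact Fisher test enumerates r×2 tables only, which covers the
  donor-group comparison; it is not a general r×c implementation.
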