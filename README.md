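# flyvir

Statistical analysis of natural virus-exposure experiments in *Drosophila*.

Wild-caught "donor" flies carrying their natural virome are co-housed with
laboratory *D. melanogaster* females for a short exposure window; each
recipient female is then followed for life, her day of death and adult
offspring recorded, and her infections assayed at death. `flyvir`
implements the full statistical pipeline such an experiment needs, plus a
synthetic-experiment generator so every stage can be exercised and
validated without any raw data:

- **Pooled prevalence.** Donor vials are assayed as pools, so individual
  prevalence `p` is estimated by maximum likelihood from pool positivity,
  `P(pool of n positive) = 1 − (1 − p)^n`, with 2-log-likelihood support
  intervals (the values within two natural-log-likelihood units of the
  maximum; ~95.4% asymptotic coverage via the χ²₁ likelihood-ratio
  calibration).
- **Transmission rates** per virus — infected recipients as a proportion of
  those exposed — with the same support intervals, and an exact
  Fisher–Freeman–Halton r×2 test for comparing transmission between donor
  species groups.
- **Lifespan models.** Purpose-built blocked-Gibbs MCMC for Gaussian mixed
  models: model A fits each virus's presence/absence as a fixed effect
  (days) with an exposure-vial random effect; model B fits the number of
  infections as a continuous predictor with a per-virus random intercept
  (shared variance) restricted to infected flies.
- **Fecundity models.** A Metropolis-within-Gibbs hurdle-Poisson mixed
  model: a logit-scale probability of zero offspring (cell-means levels,
  estimable viruses only) and a zero-truncated Poisson log-rate for
  positive counts, each trait with its own vial effect and overdispersion
  variance, covariance fixed at zero; plus a posterior-predictive check of
  the observed number of zero counts.
- **Summaries.** Posterior means, 95% highest-posterior-density intervals,
  effective sample sizes, pMCMC (twice the smaller posterior tail
  probability against zero), and percent-reduction transforms
  (`100·(−β_v/μ₀)` for lifespan, `100·(1 − e^{b_v})` for offspring).
- **Power analysis.** Monte-Carlo power to detect a percentage lifespan
  reduction as a function of group size, checked against the closed-form
  two-sample formula, and the required group size for a target power.

## Worked example

```python
from flyvir import (RunConfig, generate_experiment, paper_like_config,
                    fit_lifespan_A, percent_reduction)

table = generate_experiment(paper_like_config(), seed=1)   # 43 vials, 860 flies
cfg = RunConfig(seed=1, chain_total=6000, burn_in=1500, chain_recorded=3000)
fit = fit_lifespan_A(table, cfg)
s = percent_reduction(fit, "DimmNV")
print(f"{s.mean:.1f}% ({s.hpd_low:.1f}-{s.hpd_high:.1f}), pMCMC={s.pmcmc:.3f}")
```

prints

```
32.2% (8.9-54.1), pMCMC=0.006
```

i.e. this synthetic experiment (generated with a 30% planted DimmNV
lifespan reduction) yields a posterior mean reduction of 32.2% with a 95%
HPD interval of 9–54% and a clearly significant pMCMC.

The same can be run end-to-end from the shell:

```sh
flyvir run --config config.yaml        # simulate -> estimate -> fit -> report
flyvir simulate --seed 1 --out data/   # just the synthetic tables
```

producing per-stage CSVs (`prevalence.csv`, `transmission.csv`,
`lifespan_A_summary.csv`, `offspring_effects.csv`, `power.csv`, ...) and a
per-virus `report.csv` combining transmission rate, lifespan and offspring
percent reductions and the probability of producing no offspring.

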