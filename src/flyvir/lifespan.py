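"""Bayesian mixed models of recipient lifespan.

Two parameterizations of the same Gaussian mixed model are provided.
Model A fits the presence/absence of each virus as a fixed effect with
the exposure vial as a random effect, so each virus gets its own additive
shift in days.  Model B instead fits the number of detected infections as
a continuous predictor, with a per-virus random intercept applied only to
infected flies (a fly infected with k viruses receives the sum of its k
virus deviations) and a single shared variance across viruses; it asks
whether infections act additively and whether any virus deviates from the
common per-infection effect.

Day-72 survivors (censored flies) are included with lifespan recorded at
the follow-up limit by default, as a Gaussian model requires; set
``RunConfig.include_censored = False`` to drop them instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExperimentTable, RunConfig
from .mcmc import (ChainResult, PosteriorSummary, effective_sample_size,
                   gibbs_lmm, hpd_interval, indicator_matrix, pmcmc,
                   summarize_chain)

__all__ = ["LifespanFitA", "LifespanFitB", "fit_lifespan_A", "fit_lifespan_B",
           "percent_reduction"]


@dataclass
class LifespanFitA:
    chain: ChainResult
    summaries: pd.DataFrame
    viruses: list[str]
    dropped: list[str]
    n_used: int
    cfg: RunConfig
    vial_ids: list[str] = field(default_factory=list)

    def virus_effect(self, virus: str) -> np.ndarray:
        if virus not in self.viruses:
            raise KeyError(f"virus {virus!r} was dropped from the model")
        return self.chain.col(f"b_{virus}")

    def intercept(self) -> np.ndarray:
        return self.chain.col("b_intercept")


@dataclass
class LifespanFitB:
    chain: ChainResult
    summaries: pd.DataFrame
    viruses: list[str]
    dropped: list[str]
    n_used: int
    cfg: RunConfig

    def slope(self) -> np.ndarray:
        """Per-additional-infection lifespan effect (days)."""
        return self.chain.col("b_n_infections")

    def virus_variance(self) -> np.ndarray:
        return self.chain.col("var_virus")


def _prepare(table: ExperimentTable, cfg: RunConfig):
    rec = table.recipients.reset_index(drop=True)
    wide = table.detection_wide().loc[rec["fly_id"]]
    if not cfg.include_censored:
        keep = ~rec["censored"].astype(bool).to_numpy()
        rec = rec[keep].reset_index(drop=True)
        wide = wide[keep.tolist()] if isinstance(keep, np.ndarray) else wide
        wide = wide.loc[rec["fly_id"]]
    counts = wide.sum(axis=0)
    fitted = [v for v in table.virus_panel if counts.get(v, 0) >= 1]
    dropped = [v for v in table.virus_panel if v not in fitted]
    if dropped:
        warnings.warn(f"viruses with no infected flies dropped: {dropped}",
                      stacklevel=3)
    if not fitted:
        raise ValueError("no infected flies for any virus: model is inestimable")
    vials = sorted(rec["vial_id"].unique())
    if len(vials) < 2:
        warnings.warn("fewer than 2 vials: vial variance is driven by its prior",
                      stacklevel=3)
    codes = rec["vial_id"].map({v: i for i, v in enumerate(vials)}).to_numpy()
    Z_vial = indicator_matrix(codes, len(vials))
    y = rec["lifespan_days"].to_numpy(dtype=float)
    return rec, wide, fitted, dropped, vials, Z_vial, y


def fit_lifespan_A(table: ExperimentTable, cfg: RunConfig,
                   seed: int | None = None) -> LifespanFitA:
    """Per-virus fixed effects (days) with a vial random effect."""
    rec, wide, fitted, dropped, vials, Z_vial, y = _prepare(table, cfg)
    X = np.column_stack([np.ones(len(rec))] +
                        [wide[v].to_numpy(dtype=float) for v in fitted])
    chain = gibbs_lmm(X, y, {"vial": Z_vial}, cfg.priors, cfg,
                      seed=cfg.seed if seed is None else seed,
                      fixed_names=["intercept"] + fitted)
    summaries = summarize_chain(chain, cfg.hpd_mass, cfg.ess_floor)
    return LifespanFitA(chain=chain, summaries=summaries, viruses=fitted,
                        dropped=dropped, n_used=len(rec), cfg=cfg,
                        vial_ids=vials)


def fit_lifespan_B(table: ExperimentTable, cfg: RunConfig,
                   seed: int | None = None) -> LifespanFitB:
    """Number of infections as a continuous predictor.

    Virus identity enters as a random intercept restricted to infected
    flies, all viruses sharing one variance.
    """
    rec, wide, fitted, dropped, vials, Z_vial, y = _prepare(table, cfg)
    n_inf = wide[fitted].sum(axis=1).to_numpy(dtype=float)
    if n_inf.max() == 0:
        raise ValueError("all flies uninfected: infected level is inestimable")
    X = np.column_stack([np.ones(len(rec)), n_inf])
    Z_virus = wide[fitted].to_numpy(dtype=float)
    chain = gibbs_lmm(X, y, {"virus": Z_virus, "vial": Z_vial}, cfg.priors, cfg,
                      seed=cfg.seed if seed is None else seed,
                      fixed_names=["intercept", "n_infections"])
    summaries = summarize_chain(chain, cfg.hpd_mass, cfg.ess_floor)
    return LifespanFitB(chain=chain, summaries=summaries, viruses=fitted,
                        dropped=dropped, n_used=len(rec), cfg=cfg)


def percent_reduction(fit: LifespanFitA, virus: str,
                      baseline: str = "intercept") -> PosteriorSummary:
    """Posterior percent lifespan reduction for one virus.

    Computed per draw as ``100 * (-beta_v / mu0)`` so the interval
    propagates uncertainty in both the effect and the baseline.  The
    baseline is the model intercept (predicted uninfected lifespan at
    vial effect zero); ``baseline="uninfected_mean"`` is not available
    here because the fit does not retain the raw data, so the intercept
    is the supported choice.
    """
    if baseline != "intercept":
        raise ValueError("only the intercept baseline is supported")
    beta = fit.virus_effect(virus)
    mu0 = fit.intercept()
    pct = 100.0 * (-beta / mu0)
    lo, hi = hpd_interval(pct, fit.cfg.hpd_mass)
    return PosteriorSummary(parameter=f"pct_reduction_{virus}",
                            mean=float(pct.mean()), hpd_low=lo, hpd_high=hi,
                            ess=effective_sample_size(pct), pmcmc=pmcmc(pct))
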