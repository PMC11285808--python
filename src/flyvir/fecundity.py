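"""Hurdle-Poisson models of offspring production and their checks.

Offspring counts have an excess of zeros (females that never produced
adult offspring), so the model is two-part: a logit-scale probability of
zero offspring and a zero-truncated Poisson for the positive counts.
Virus presence/absence enters the count part as additive log-rate effects
relative to an uninfected intercept; the zero part is parameterized as
cell means (no shared intercept), one logit level for uninfected flies
and one per estimable virus, so each level is directly interpretable as a
probability of sterility.  A virus's zero probability is estimable only
if, among its infected flies, at least one produced no offspring and at
least one produced some.  Both traits carry their own vial random effect
and latent overdispersion residual, with the between-trait covariance
fixed at zero.

The lifetime and early-life analyses share this machinery, differing only
in the response column (``offspring_total`` vs ``offspring_early``) and
in the exclusion of flies that died before the early window closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExperimentTable, RunConfig
from .mcmc import (ChainResult, PosteriorSummary, effective_sample_size,
                   hpd_interval, hurdle_poisson_mcmc, indicator_matrix, pmcmc,
                   sample_zt_poisson, summarize_chain)

__all__ = [
    "FecundityFit", "PPCResult", "detect_zero_estimable", "fit_fecundity",
    "percent_offspring_reduction", "posterior_predictive_zeros",
    "early_late_correlation",
]


@dataclass
class FecundityFit:
    chain: ChainResult
    summaries: pd.DataFrame
    count_viruses: list[str]
    zero_viruses: list[str]
    excluded_zero: dict[str, str]
    window: str
    n_used: int
    cfg: RunConfig
    # retained design for posterior-predictive simulation
    X_zero: np.ndarray = field(repr=False, default=None)
    X_count: np.ndarray = field(repr=False, default=None)
    vial_codes: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def count_effect(self, virus: str) -> np.ndarray:
        if virus not in self.count_viruses:
            raise KeyError(f"virus {virus!r} not in the count part")
        return self.chain.col(f"count_{virus}")

    def zero_level(self, level: str) -> np.ndarray:
        """Logit-scale zero-probability level ('uninfected' or a virus)."""
        if level != "uninfected" and level not in self.zero_viruses:
            raise KeyError(f"level {level!r} not in the zero part")
        return self.chain.col(f"zero_{level}")

    def p_zero(self, level: str) -> PosteriorSummary:
        """Predicted probability of zero offspring for a level, in [0, 1]."""
        draws = 1.0 / (1.0 + np.exp(-self.zero_level(level)))
        lo, hi = hpd_interval(draws, self.cfg.hpd_mass)
        return PosteriorSummary(parameter=f"p_zero_{level}",
                                mean=float(draws.mean()), hpd_low=lo,
                                hpd_high=hi, ess=effective_sample_size(draws),
                                pmcmc=pmcmc(draws))


@dataclass(frozen=True)
class PPCResult:
    observed_zeros: int
    simulated_zeros: np.ndarray
    band_low: float
    band_high: float
    inside_band: bool


def _window_frame(table: ExperimentTable, window: str) -> tuple[pd.DataFrame, str]:
    if window not in ("lifetime", "early"):
        raise ValueError("window must be 'lifetime' or 'early'")
    rec = table.recipients.reset_index(drop=True)
    if window == "early":
        rec = rec[~rec["excluded_early"].astype(bool)].reset_index(drop=True)
        return rec, "offspring_early"
    return rec, "offspring_total"


def detect_zero_estimable(
    table: ExperimentTable, window: str = "lifetime",
) -> tuple[list[str], dict[str, str]]:
    """Split the virus panel into zero-part estimable and excluded viruses.

    A virus is estimable iff at least one of its infected flies produced
    zero offspring and at least one produced some.  Excluded viruses map
    to a reason code: ``no_infected``, ``all_nonzero`` or ``all_zero``.
    """
    rec, resp = _window_frame(table, window)
    wide = table.detection_wide().loc[rec["fly_id"]]
    y = rec[resp].to_numpy()
    estimable, excluded = [], {}
    for v in table.virus_panel:
        mask = wide[v].to_numpy()
        if not mask.any():
            excluded[v] = "no_infected"
        elif (y[mask] == 0).all():
            excluded[v] = "all_zero"
        elif (y[mask] > 0).all():
            excluded[v] = "all_nonzero"
        else:
            estimable.append(v)
    return estimable, excluded


def fit_fecundity(table: ExperimentTable, cfg: RunConfig,
                  window: str = "lifetime",
                  seed: int | None = None) -> FecundityFit:
    """Fit the hurdle-Poisson mixed model for one offspring window."""
    rec, resp = _window_frame(table, window)
    wide = table.detection_wide().loc[rec["fly_id"]]
    y = rec[resp].to_numpy(dtype=int)
    if (y == 0).all():
        raise ValueError("all counts are zero: the zero-truncated count part "
                         "is inestimable")
    if (y > 0).all():
        raise ValueError("no zero counts: the zero (hurdle) part is inestimable")

    counts_per_virus = wide.sum(axis=0)
    count_viruses = [v for v in table.virus_panel if counts_per_virus.get(v, 0) >= 1]
    if not count_viruses:
        raise ValueError("no infected flies for any virus")
    zero_viruses, excluded_zero = detect_zero_estimable(table, window)
    zero_viruses = [v for v in zero_viruses if v in count_viruses]
    if excluded_zero:
        warnings.warn(
            f"viruses excluded from the zero part: {excluded_zero}", stacklevel=2)

    n = len(rec)
    X_count = np.column_stack([np.ones(n)] +
                              [wide[v].to_numpy(dtype=float) for v in count_viruses])
    uninfected = (wide[count_viruses].sum(axis=1) == 0).to_numpy(dtype=float)
    X_zero = np.column_stack([uninfected] +
                             [wide[v].to_numpy(dtype=float) for v in zero_viruses])
    vials = sorted(rec["vial_id"].unique())
    codes = rec["vial_id"].map({v: i for i, v in enumerate(vials)}).to_numpy()
    Z = indicator_matrix(codes, len(vials))
    chain = hurdle_poisson_mcmc(
        X_zero, X_count, y, {"vial": Z}, {"vial": Z}, cfg.priors, cfg,
        seed=cfg.seed if seed is None else seed,
        names_zero=["uninfected"] + zero_viruses,
        names_count=["intercept"] + count_viruses)
    summaries = summarize_chain(chain, cfg.hpd_mass, cfg.ess_floor)
    return FecundityFit(chain=chain, summaries=summaries,
                        count_viruses=count_viruses, zero_viruses=zero_viruses,
                        excluded_zero=excluded_zero, window=window,
                        n_used=n, cfg=cfg, X_zero=X_zero, X_count=X_count,
                        vial_codes=codes, y=y)


def percent_offspring_reduction(fit: FecundityFit, virus: str) -> PosteriorSummary:
    """Posterior percent reduction in (non-zero) offspring production.

    Per draw ``100 * (1 - exp(b_v))`` where ``b_v`` is the virus's
    count-part log-rate effect relative to uninfected flies.
    """
    b = fit.count_effect(virus)
    pct = 100.0 * (1.0 - np.exp(b))
    lo, hi = hpd_interval(pct, fit.cfg.hpd_mass)
    return PosteriorSummary(parameter=f"pct_offspring_reduction_{virus}",
                            mean=float(pct.mean()), hpd_low=lo, hpd_high=hi,
                            ess=effective_sample_size(pct), pmcmc=pmcmc(pct))


def posterior_predictive_zeros(fit: FecundityFit, n_draws: int = 200,
                               seed: int = 0) -> PPCResult:
    """Check the fitted model against the observed number of zero counts.

    For each of ``n_draws`` posterior draws, a full offspring vector is
    simulated at the observed covariates (fixed effects, fitted vial
    effects, fresh latent residuals) and its zeros counted; the observed
    zero count is compared with the central 95% band of the simulated
    distribution.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    if n_draws < 50:
        warnings.warn("n_draws < 50 gives a coarse posterior-predictive band",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    chain = fit.chain
    n_rec = chain.draws.shape[0]
    idx = rng.choice(n_rec, size=min(n_draws, n_rec), replace=n_draws > n_rec)
    gz_cols = [chain.names.index(f"zero_{s}")
               for s in ["uninfected"] + fit.zero_viruses]
    gc_cols = [chain.names.index(f"count_{s}")
               for s in ["intercept"] + fit.count_viruses]
    q = int(fit.vial_codes.max()) + 1
    uz_cols = [chain.names.index(f"u_vial_zero[{j}]") for j in range(q)]
    uc_cols = [chain.names.index(f"u_vial_count[{j}]") for j in range(q)]
    vz = chain.names.index("var_latent_zero")
    vc = chain.names.index("var_latent_count")

    zeros = np.empty(idx.size, dtype=int)
    n = fit.y.size
    for k, i in enumerate(idx):
        d = chain.draws[i]
        eta_z = fit.X_zero @ d[gz_cols] + d[uz_cols][fit.vial_codes]
        eta_z = eta_z + rng.normal(0.0, np.sqrt(d[vz]), n)
        eta_c = fit.X_count @ d[gc_cols] + d[uc_cols][fit.vial_codes]
        eta_c = eta_c + rng.normal(0.0, np.sqrt(d[vc]), n)
        is_zero = rng.random(n) < 1.0 / (1.0 + np.exp(-eta_z))
        y_sim = sample_zt_poisson(rng, np.exp(np.clip(eta_c, -30, 30)))
        y_sim[is_zero] = 0
        zeros[k] = int((y_sim == 0).sum())
    lo, hi = np.quantile(zeros, [0.025, 0.975])
    observed = int((fit.y == 0).sum())
    return PPCResult(observed_zeros=observed, simulated_zeros=zeros,
                     band_low=float(lo), band_high=float(hi),
                     inside_band=bool(lo <= observed <= hi))


def early_late_correlation(table: ExperimentTable) -> dict:
    """Pearson correlation between early and late offspring production.

    Late production is ``offspring_total - offspring_early``.  Flies that
    died before the early window closed are excluded.  Returns the
    correlation, its Fisher-z 95% confidence interval, the t statistic
    (n - 2 df) and the two-sided p-value.
    """
    rec = table.recipients
    rec = rec[~rec["excluded_early"].astype(bool)]
    early = rec["offspring_early"].to_numpy(dtype=float)
    late = (rec["offspring_total"] - rec["offspring_early"]).to_numpy(dtype=float)
    n = early.size
    if n < 3:
        raise ValueError("need at least 3 flies with both windows observed")
    if np.var(early) == 0 or np.var(late) == 0:
        raise ValueError("zero variance in an offspring window")
    r = float(stats.pearsonr(early, late).statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    t = r * np.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return {"r": r, "ci_low": float(np.tanh(z - half)),
            "ci_high": float(np.tanh(z + half)), "t": float(t),
            "p": float(p), "n": int(n)}
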