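"""Simulation-based power analysis for detecting lifespan reductions.

Lifespans are simulated under the same generative process the lifespan
model assumes -- Gaussian around a baseline, one virus shifting the
infected group's mean down by a percentage of the baseline, optional
vial-level random effects -- and a detection rule is applied per
replicate.  The default rule is a Welch two-sample t-test (fast and, with
no vial variance, analytically checkable); the ``model`` rule refits the
per-virus mixed model on every replicate and rejects when the effect's
pMCMC falls below alpha, which is slower and is used for
spot-calibration of the Welch shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mcmc import PriorSpec, gibbs_lmm, indicator_matrix, pmcmc

__all__ = [
    "PowerEstimate", "PowerCurve", "simulate_power", "power_grid",
    "analytic_power", "analytic_required_n", "required_n",
]

_RULES = ("welch", "model")


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    mc_se: float
    reps: int
    rule: str


@dataclass
class PowerCurve:
    """Power on a (group size x effect size) grid with Monte-Carlo error."""

    frame: pd.DataFrame  # columns: n_infected, pct_reduction, power, mc_se, reps
    rule: str
    mu: float
    sigma_vial: float
    sigma_e: float
    alpha: float


class _ChainCfg:
    """Minimal chain settings for the model-based detection rule."""

    def __init__(self, total=800, burn=200, recorded=300, seed=0):
        self.chain_total = total
        self.burn_in = burn
        self.chain_recorded = recorded
        self.seed = seed


def _simulate_groups(rng, reps, n_inf, n_uninf, delta, mu, sigma_vial, sigma_e,
                     vial_size=20):
    """(reps, n) lifespan matrices for the two groups, sharing vial effects."""
    n_tot = n_inf + n_uninf
    y = mu + sigma_e * rng.standard_normal((reps, n_tot))
    y[:, :n_inf] -= delta
    if sigma_vial > 0:
        n_vials = int(np.ceil(n_tot / vial_size))
        codes = rng.integers(0, n_vials, size=(reps, n_tot))
        effects = sigma_vial * rng.standard_normal((reps, n_vials))
        y += np.take_along_axis(effects, codes, axis=1)
    return y[:, :n_inf], y[:, n_inf:]


def _welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample t-test p-values."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * stats.t.sf(np.abs(t), df)


def simulate_power(
    n_infected: int,
    n_uninfected: int,
    pct_reduction: float,
    mu: float,
    sigma_vial: float,
    sigma_e: float,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
    rule: str = "welch",
) -> PowerEstimate:
    """Monte-Carlo power to detect a percentage lifespan reduction."""
    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {_RULES}")
    if n_infected < 1 or n_uninfected < 1:
        raise ValueError("group sizes must be positive")
    if not 0.0 <= pct_reduction < 100.0:
        raise ValueError("pct_reduction must be in [0, 100)")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    delta = pct_reduction * mu / 100.0
    if rule == "welch":
        a, b = _simulate_groups(rng, reps, n_infected, n_uninfected, delta,
                                mu, sigma_vial, sigma_e)
        rejections = int((_welch_pvalues(a, b) < alpha).sum())
    else:
        cfg = _ChainCfg()
        priors = PriorSpec()
        n_tot = n_infected + n_uninfected
        inf = np.zeros(n_tot)
        inf[:n_infected] = 1.0
        X = np.column_stack([np.ones(n_tot), inf])
        n_vials = max(2, int(np.ceil(n_tot / 20)))
        rejections = 0
        for r in range(reps):
            codes = rng.integers(0, n_vials, n_tot)
            y = (mu - delta * inf + sigma_vial * rng.standard_normal(n_vials)[codes]
                 + sigma_e * rng.standard_normal(n_tot))
            chain = gibbs_lmm(X, y, {"vial": indicator_matrix(codes, n_vials)},
                              priors, cfg, seed=int(rng.integers(2**31)),
                              fixed_names=["intercept", "virus"])
            if pmcmc(chain.col("b_virus")) < alpha:
                rejections += 1
    p = rejections / reps
    return PowerEstimate(power=p, mc_se=float(np.sqrt(p * (1 - p) / reps)),
                         reps=reps, rule=rule)


def power_grid(
    ns: list[int],
    pcts: list[float],
    mu: float,
    sigma_vial: float,
    sigma_e: float,
    n_uninfected: int | None = None,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
    rule: str = "welch",
) -> PowerCurve:
    """Power over the cartesian grid of infected-group sizes and effects.

    ``n_uninfected`` defaults to the infected-group size (balanced
    design).
    """
    rows = []
    for i, n in enumerate(ns):
        for j, pct in enumerate(pcts):
            est = simulate_power(n, n_uninfected or n, pct, mu, sigma_vial,
                                 sigma_e, alpha, reps,
                                 seed + 1000 * i + j, rule)
            rows.append({"n_infected": n, "pct_reduction": pct,
                         "power": est.power, "mc_se": est.mc_se,
                         "reps": reps})
    return PowerCurve(frame=pd.DataFrame(rows), rule=rule, mu=mu,
                      sigma_vial=sigma_vial, sigma_e=sigma_e, alpha=alpha)


def analytic_power(n1: int, n2: int, delta: float, sd: float,
                   alpha: float = 0.05) -> float:
    """Closed-form normal-approximation power of the two-sample test."""
    se = sd * np.sqrt(1.0 / n1 + 1.0 / n2)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ncp = abs(delta) / se
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))


def analytic_required_n(target_power: float, pct_reduction: float, mu: float,
                        sd: float, alpha: float = 0.05) -> int:
    """Per-group n for a balanced two-sample test, closed form."""
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    if pct_reduction <= 0:
        raise ValueError("pct_reduction = 0 gives no power above alpha: "
                         "target unreachable")
    delta = pct_reduction * mu / 100.0
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(target_power)
    return max(2, int(np.ceil(2.0 * (z * sd / delta) ** 2)))


def required_n(
    target_power: float,
    pct_reduction: float,
    mu: float,
    sigma_vial: float,
    sigma_e: float,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
    method: str = "simulation",
    n_ceiling: int = 200_000,
) -> int:
    """Smallest balanced per-group n achieving the target power.

    ``method="analytic"`` inverts the closed-form normal power (total sd
    combining vial and residual components); ``method="simulation"``
    bisects over n using Monte-Carlo power estimates (reps >= 1000 near
    the boundary for smoothing).
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    if pct_reduction <= 0:
        raise ValueError("pct_reduction = 0 gives no power above alpha: "
                         "target unreachable")
    sd_tot = float(np.hypot(sigma_vial, sigma_e))
    if method == "analytic":
        n = analytic_required_n(target_power, pct_reduction, mu, sd_tot, alpha)
        if n > n_ceiling:
            raise ValueError(f"target power needs n={n}, above ceiling {n_ceiling}")
        return n
    if method != "simulation":
        raise ValueError("method must be 'simulation' or 'analytic'")
    reps_final = max(reps, 1000)

    def power_at(n: int, r: int) -> float:
        return simulate_power(n, n, pct_reduction, mu, sigma_vial, sigma_e,
                              alpha, r, seed + n, "welch").power

    lo, hi = 2, 4
    while power_at(hi, reps) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_ceiling:
            raise ValueError(
                f"target power {target_power} unreachable below n={n_ceiling} "
                f"(power at ceiling ~{power_at(n_ceiling, reps):.3f})")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid, reps_final) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
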