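"""Purpose-built MCMC machinery for the Gaussian and hurdle-Poisson mixed models.

Two samplers are provided.  ``gibbs_lmm`` fits a Gaussian linear mixed
model

    y = X b + sum_g Z_g u_g + e,   u_g ~ N(0, s2_g I),  e ~ N(0, s2_e I)

by blocked Gibbs sampling: the fixed effects and each random-effect block
are drawn from their conjugate multivariate-normal full conditionals and
each variance component from its conjugate inverse-gamma full conditional.
``hurdle_poisson_mcmc`` fits a two-part count model in which a latent
logit linear predictor governs the probability of a zero count and a
latent log-rate linear predictor governs a zero-truncated Poisson for the
positive counts; the per-observation latent values are updated by adaptive
random-walk Metropolis (targeting 44% acceptance during burn-in, with the
proposal scale frozen afterwards to preserve detailed balance), and all
Gaussian effects and variances by their conjugate full conditionals.

Priors default to N(0, 1e10) on fixed effects and inverse-gamma with
(V = 1, nu = 0.002) on every variance component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = [
    "PriorSpec",
    "ChainResult",
    "PosteriorSummary",
    "hpd_interval",
    "effective_sample_size",
    "pmcmc",
    "gibbs_lmm",
    "hurdle_poisson_mcmc",
    "sample_zt_poisson",
    "summarize_chain",
    "indicator_matrix",
]

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class PriorSpec:
    """Priors for fixed effects (normal) and variances (inverse-gamma).

    The inverse-gamma is parameterized as shape ``nu/2`` and rate
    ``nu * V / 2``, so ``(V=1, nu=0.002)`` is a nearly flat prior on each
    variance component.
    """

    fixed_effect_var: float = 1e10
    variance_v: float = 1.0
    variance_nu: float = 0.002

    def __post_init__(self) -> None:
        if self.fixed_effect_var <= 0 or self.variance_v <= 0 or self.variance_nu <= 0:
            raise ValueError("prior variances and nu must be positive")


@dataclass
class ChainResult:
    """Recorded MCMC draws with parameter names and run provenance."""

    names: list[str]
    draws: np.ndarray  # (n_recorded, n_params)
    seed: int | None
    burn_in: int
    thin: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.shape[0] < 2:
            raise ValueError("need at least 2 recorded draws")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite draws in chain")

    def col(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def cols(self, prefix: str) -> dict[str, np.ndarray]:
        return {n: self.draws[:, i] for i, n in enumerate(self.names)
                if n.startswith(prefix)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)


@dataclass(frozen=True)
class PosteriorSummary:
    parameter: str
    mean: float
    hpd_low: float
    hpd_high: float
    ess: float
    pmcmc: float


def hpd_interval(draws: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted draws holding ``mass``.

    Ties in width are broken toward the smallest lower endpoint.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))  # first minimum -> smallest lower endpoint
    return float(x[i]), float(x[i + m - 1])


def effective_sample_size(draws: Sequence[float]) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator.

    ``n / (1 + 2 * sum(rho_k))`` with the sum truncated at the first
    non-positive autocorrelation.  A zero-variance series is defined to
    have ESS equal to its length.
    """
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws")
    d = x - x.mean()
    v = float(d @ d) / n
    if v == 0.0:
        return float(n)
    acov = np.correlate(d, d, mode="full")[n - 1:] / n
    rho = acov[1:] / v
    s = 0.0
    for r in rho:
        if r <= 0.0:
            break
        s += float(r)
    return float(n / (1.0 + 2.0 * s))


def pmcmc(draws: Sequence[float]) -> float:
    """Two-sided MCMC tail probability against zero.

    ``2 * min(P(draw > 0), P(draw < 0))``, floored at ``2/n`` so it is
    never exactly zero, and capped at 1.
    """
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    p = 2.0 * min(float(np.mean(x > 0)), float(np.mean(x < 0)))
    return float(min(max(p, 2.0 / n), 1.0))


def summarize_chain(
    chain: ChainResult,
    hpd_mass: float = 0.95,
    ess_floor: float | None = None,
) -> pd.DataFrame:
    """Posterior mean, HPD interval, ESS and pMCMC for every parameter."""
    rows = []
    for i, name in enumerate(chain.names):
        x = chain.draws[:, i]
        lo, hi = hpd_interval(x, hpd_mass)
        ess = effective_sample_size(x)
        rows.append({
            "parameter": name, "mean": float(x.mean()),
            "hpd_low": lo, "hpd_high": hi,
            "ess": ess, "pmcmc": pmcmc(x),
            "low_ess": bool(ess_floor is not None and ess < ess_floor),
        })
    return pd.DataFrame(rows)


def indicator_matrix(codes: Sequence[int], n_levels: int | None = None) -> np.ndarray:
    """Dense 0/1 membership matrix from integer level codes."""
    codes = np.asarray(codes, dtype=int)
    q = int(codes.max()) + 1 if n_levels is None else int(n_levels)
    Z = np.zeros((codes.size, q))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in range(len(diag)) if diag[i] <= tol]
    if len(diag) < X.shape[1]:
        bad += list(names[len(diag):])
    if bad:
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {bad}")


def _draw_mvn(rng: np.random.Generator, precision: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Draw from N(A^-1 rhs, A^-1) given precision A (symmetric PD)."""
    c, low = cho_factor(precision, lower=True)
    mean = cho_solve((c, low), rhs)
    z = rng.standard_normal(rhs.size)
    return mean + solve_triangular(c, z, lower=low, trans="T" if low else "N")


def _draw_inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return float(max(rate / rng.gamma(shape), _VAR_FLOOR))


def _thin_plan(cfg) -> tuple[int, int, int]:
    total, burn, rec = int(cfg.chain_total), int(cfg.burn_in), int(cfg.chain_recorded)
    if burn >= total:
        raise ValueError("burn_in must be smaller than chain_total")
    thin = max(1, (total - burn) // rec)
    return total, burn, thin


def gibbs_lmm(
    X: np.ndarray,
    y: np.ndarray,
    random_effects: Mapping[str, np.ndarray] | None,
    priors: PriorSpec,
    cfg,
    seed: int | None = None,
    fix_resid_var: float | None = None,
    fixed_names: Sequence[str] | None = None,
    record_random: bool = False,
) -> ChainResult:
    """Blocked Gibbs sampler for the Gaussian linear mixed model.

    ``random_effects`` maps a component name to its (n, q) design matrix.
    ``cfg`` supplies ``chain_total``, ``burn_in`` and ``chain_recorded``.
    ``fix_resid_var`` holds the residual variance fixed (used for
    closed-form validation); otherwise it is sampled.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have incompatible shapes")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in design or response")
    names_fixed = list(fixed_names) if fixed_names is not None else [f"b{j}" for j in range(p)]
    _check_full_rank(X, names_fixed)
    res = {k: np.asarray(Z, dtype=float) for k, Z in (random_effects or {}).items()}
    if n <= p:
        import warnings
        warnings.warn("fewer observations than fixed-effect parameters", stacklevel=2)

    total, burn, thin = _thin_plan(cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    XtX = X.T @ X
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    u = {k: np.zeros(Z.shape[1]) for k, Z in res.items()}
    yvar = float(np.var(y)) or 1.0
    s2e = fix_resid_var if fix_resid_var is not None else yvar
    s2g = {k: yvar / 2 or 1.0 for k in res}
    nu, V = priors.variance_nu, priors.variance_v
    prior_prec = 1.0 / priors.fixed_effect_var

    names = [f"b_{nm}" for nm in names_fixed]
    names += [f"var_{k}" for k in res] + ["var_residual"]
    if record_random:
        for k, Z in res.items():
            names += [f"u_{k}[{j}]" for j in range(Z.shape[1])]

    records = []
    for it in range(total):
        ran = sum((Z @ u[k] for k, Z in res.items()), np.zeros(n))
        # fixed effects
        A = XtX / s2e + prior_prec * np.eye(p)
        beta = _draw_mvn(rng, A, X.T @ (y - ran) / s2e)
        # random-effect blocks
        for k, Z in res.items():
            other = sum((res[h] @ u[h] for h in res if h != k), np.zeros(n))
            r = y - X @ beta - other
            q = Z.shape[1]
            A = Z.T @ Z / s2e + np.eye(q) / s2g[k]
            u[k] = _draw_mvn(rng, A, Z.T @ r / s2e)
            s2g[k] = _draw_inv_gamma(rng, (q + nu) / 2.0, (u[k] @ u[k] + nu * V) / 2.0)
        # residual variance
        ran = sum((Z @ u[k] for k, Z in res.items()), np.zeros(n))
        resid = y - X @ beta - ran
        if fix_resid_var is None:
            s2e = _draw_inv_gamma(rng, (n + nu) / 2.0, (resid @ resid + nu * V) / 2.0)
        if it >= burn and (it - burn) % thin == 0:
            row = list(beta) + [s2g[k] for k in res] + [s2e]
            if record_random:
                for k in res:
                    row += list(u[k])
            if not np.all(np.isfinite(row)):
                raise RuntimeError(f"non-finite draw at iteration {it}")
            records.append(row)

    return ChainResult(names=names, draws=np.asarray(records), seed=seed,
                       burn_in=burn, thin=thin,
                       meta={"sampler": "gibbs_lmm", "n_obs": n})


# ---------------------------------------------------------------------------
# Hurdle-Poisson machinery


def sample_zt_poisson(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Draw zero-truncated Poisson variates, vectorized, by rejection."""
    lam = np.asarray(lam, dtype=float)
    out = np.zeros(lam.shape, dtype=int)
    todo = np.ones(lam.shape, dtype=bool)
    # tiny rates are 1 with probability ~1
    tiny = lam < 1e-8
    out[tiny] = 1
    todo &= ~tiny
    while todo.any():
        draw = rng.poisson(lam[todo])
        idx = np.flatnonzero(todo)
        ok = draw > 0
        out[idx[ok]] = draw[ok]
        todo[idx[ok]] = False
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _zt_poisson_loglik(y: np.ndarray, log_lam: np.ndarray) -> np.ndarray:
    """log P(y | zero-truncated Poisson with log rate), dropping log(y!)."""
    with np.errstate(over="ignore"):
        lam = np.exp(log_lam)
    ll = y * log_lam - lam - np.log1p(-np.exp(-np.clip(lam, 1e-300, None)))
    ll[~np.isfinite(ll)] = -np.inf
    return ll


class _GaussianSide:
    """Conjugate Gaussian sub-model for one latent trait of the hurdle model."""

    def __init__(self, X, res, priors, rng, fix_latent_var, init_beta):
        self.X = X
        self.res = res
        self.n, self.p = X.shape
        self.XtX = X.T @ X
        self.beta = init_beta
        self.u = {k: np.zeros(Z.shape[1]) for k, Z in res.items()}
        self.s2_group = {k: 0.5 for k in res}
        self.s2_lat = 1.0 if fix_latent_var is None else float(fix_latent_var)
        self.fix_latent = fix_latent_var is not None
        self.priors = priors
        self.rng = rng

    def eta(self) -> np.ndarray:
        out = self.X @ self.beta
        for k, Z in self.res.items():
            out = out + Z @ self.u[k]
        return out

    def update(self, latent: np.ndarray) -> None:
        nu, V = self.priors.variance_nu, self.priors.variance_v
        prior_prec = 1.0 / self.priors.fixed_effect_var
        ran = sum((Z @ self.u[k] for k, Z in self.res.items()), np.zeros(self.n))
        A = self.XtX / self.s2_lat + prior_prec * np.eye(self.p)
        self.beta = _draw_mvn(self.rng, A, self.X.T @ (latent - ran) / self.s2_lat)
        for k, Z in self.res.items():
            other = sum((self.res[h] @ self.u[h] for h in self.res if h != k),
                        np.zeros(self.n))
            r = latent - self.X @ self.beta - other
            q = Z.shape[1]
            A = Z.T @ Z / self.s2_lat + np.eye(q) / self.s2_group[k]
            self.u[k] = _draw_mvn(self.rng, A, Z.T @ r / self.s2_lat)
            self.s2_group[k] = _draw_inv_gamma(
                self.rng, (q + nu) / 2.0, (self.u[k] @ self.u[k] + nu * V) / 2.0)
        if not self.fix_latent:
            resid = latent - self.eta()
            self.s2_lat = _draw_inv_gamma(
                self.rng, (self.n + nu) / 2.0, (resid @ resid + nu * V) / 2.0)


def hurdle_poisson_mcmc(
    X_zero: np.ndarray,
    X_count: np.ndarray,
    y: np.ndarray,
    random_effects_zero: Mapping[str, np.ndarray] | None,
    random_effects_count: Mapping[str, np.ndarray] | None,
    priors: PriorSpec,
    cfg,
    seed: int | None = None,
    names_zero: Sequence[str] | None = None,
    names_count: Sequence[str] | None = None,
    fix_latent_var_zero: float | None = None,
    fix_latent_var_count: float | None = None,
    record_random: bool = True,
) -> ChainResult:
    """Metropolis-within-Gibbs sampler for the hurdle-Poisson mixed model.

    Each observation carries two latent values: a logit-scale predictor of
    the probability of a zero count, and a log-scale rate for the
    zero-truncated Poisson governing positive counts.  The two traits have
    separate vial-level random effects and separate latent residual
    variances, with the between-trait covariance fixed at zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if not (y > 0).any():
        raise ValueError(
            "all counts are zero: the zero-truncated count part is "
            "inestimable; remove count-part terms or supply positive counts")
    X_zero = np.atleast_2d(np.asarray(X_zero, dtype=float))
    X_count = np.atleast_2d(np.asarray(X_count, dtype=float))
    n = y.size
    nz = names_zero if names_zero is not None else [f"z{j}" for j in range(X_zero.shape[1])]
    nc = names_count if names_count is not None else [f"c{j}" for j in range(X_count.shape[1])]
    _check_full_rank(X_zero, nz)
    _check_full_rank(X_count, nc)

    total, burn, thin = _thin_plan(cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    is_zero = y == 0
    is_pos = ~is_zero

    p0 = float(np.clip(is_zero.mean(), 1.0 / (n + 2), 1 - 1.0 / (n + 2)))
    beta_z0 = np.linalg.lstsq(X_zero, np.full(n, np.log(p0 / (1 - p0))), rcond=None)[0]
    mean_pos = float(y[is_pos].mean())
    beta_c0 = np.linalg.lstsq(X_count, np.full(n, np.log(max(mean_pos, 0.5))), rcond=None)[0]

    zero_side = _GaussianSide(X_zero, dict(random_effects_zero or {}), priors, rng,
                              fix_latent_var_zero, beta_z0)
    count_side = _GaussianSide(X_count, dict(random_effects_count or {}), priors, rng,
                               fix_latent_var_count, beta_c0)
    l_z = zero_side.eta() + 0.1 * rng.standard_normal(n)
    l_c = count_side.eta() + 0.1 * rng.standard_normal(n)

    scale_z, scale_c = 1.0, 0.5
    acc_z = acc_c = prop_z = prop_c = 0

    def zero_loglik(l: np.ndarray) -> np.ndarray:
        # log P(zero indicator | l); l is the logit of P(zero)
        return np.where(is_zero, _log_sigmoid(l), _log_sigmoid(-l))

    names = [f"zero_{s}" for s in nz] + [f"count_{s}" for s in nc]
    names += [f"var_{k}_zero" for k in zero_side.res]
    names += [f"var_{k}_count" for k in count_side.res]
    names += ["var_latent_zero", "var_latent_count"]
    if record_random:
        for k, Z in zero_side.res.items():
            names += [f"u_{k}_zero[{j}]" for j in range(Z.shape[1])]
        for k, Z in count_side.res.items():
            names += [f"u_{k}_count[{j}]" for j in range(Z.shape[1])]

    records = []
    for it in range(total):
        # --- latent update, zero trait (all observations, random walk)
        eta_z = zero_side.eta()
        prop = l_z + scale_z * rng.standard_normal(n)
        dlog = (zero_loglik(prop) - zero_loglik(l_z)
                + ((l_z - eta_z) ** 2 - (prop - eta_z) ** 2) / (2 * zero_side.s2_lat))
        accept = np.log(rng.random(n)) < dlog
        l_z = np.where(accept, prop, l_z)
        acc_z += int(accept.sum()); prop_z += n

        # --- latent update, count trait
        eta_c = count_side.eta()
        prop = l_c + scale_c * rng.standard_normal(n)
        ll_new = _zt_poisson_loglik(y[is_pos], prop[is_pos])
        ll_old = _zt_poisson_loglik(y[is_pos], l_c[is_pos])
        dlog = (ll_new - ll_old
                + ((l_c[is_pos] - eta_c[is_pos]) ** 2
                   - (prop[is_pos] - eta_c[is_pos]) ** 2) / (2 * count_side.s2_lat))
        accept = np.log(rng.random(int(is_pos.sum()))) < dlog
        l_c[is_pos] = np.where(accept, prop[is_pos], l_c[is_pos])
        acc_c += int(accept.sum()); prop_c += int(is_pos.sum())
        # zero-count observations carry no count-part information: Gibbs draw
        l_c[is_zero] = eta_c[is_zero] + np.sqrt(count_side.s2_lat) * rng.standard_normal(
            int(is_zero.sum()))

        # --- conjugate Gaussian updates per trait
        zero_side.update(l_z)
        count_side.update(l_c)

        # --- proposal-scale adaptation, frozen after burn-in
        if it < burn and (it + 1) % 50 == 0:
            if prop_z:
                scale_z = float(np.clip(scale_z * np.exp(2.0 * (acc_z / prop_z - 0.44)),
                                        1e-3, 20.0))
            if prop_c:
                scale_c = float(np.clip(scale_c * np.exp(2.0 * (acc_c / prop_c - 0.44)),
                                        1e-3, 20.0))
            acc_z = acc_c = prop_z = prop_c = 0

        if it >= burn and (it - burn) % thin == 0:
            row = list(zero_side.beta) + list(count_side.beta)
            row += [zero_side.s2_group[k] for k in zero_side.res]
            row += [count_side.s2_group[k] for k in count_side.res]
            row += [zero_side.s2_lat, count_side.s2_lat]
            if record_random:
                for k in zero_side.res:
                    row += list(zero_side.u[k])
                for k in count_side.res:
                    row += list(count_side.u[k])
            if not np.all(np.isfinite(row)):
                raise RuntimeError(f"non-finite draw at iteration {it}")
            records.append(row)

    acc_rate = {"zero": acc_z / prop_z if prop_z else float("nan"),
                "count": acc_c / prop_c if prop_c else float("nan")}
    return ChainResult(names=names, draws=np.asarray(records), seed=seed,
                       burn_in=burn, thin=thin,
                       meta={"sampler": "hurdle_poisson", "n_obs": n,
                             "acceptance": acc_rate,
                             "scales": {"zero": scale_z, "count": scale_c}})
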