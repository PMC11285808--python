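"""Pooled-sample prevalence estimation and transmission-rate summaries.

Donor flies were assayed for each virus as whole-vial pools, so individual
prevalence ``p`` is only observable through pool positivity: a pool of
``n`` flies tests positive iff at least one member carries the virus,
giving ``P(positive) = 1 - (1 - p)**n``.  The maximum-likelihood estimate
of ``p`` and its 2-log-likelihood support interval (the set of values
within two natural-log-likelihood units of the maximum, with ~95.4%
asymptotic coverage via the chi-square(1) likelihood-ratio distribution)
are computed here, together with recipient transmission rates (the
unit-pool special case) and an exact Fisher-Freeman-Halton test used to
compare transmission between donor species groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln

__all__ = [
    "PrevalenceEstimate",
    "TransmissionEstimate",
    "pooled_loglik",
    "estimate_prevalence",
    "estimate_transmission",
    "fisher_exact_rxc",
    "prevalence_by_group",
    "transmission_by_virus",
    "donor_group_transmission_table",
]

#: log-likelihood drop defining the support interval; 2 natural-log units
#: corresponds to ~95.4% asymptotic coverage (chi-square(1) quantile 4).
SUPPORT_DROP = 2.0


@dataclass(frozen=True)
class PrevalenceEstimate:
    virus: str
    p_hat: float
    lower: float
    upper: float
    n_pools: int
    n_flies: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.p_hat + 1e-12 and
                self.p_hat <= self.upper + 1e-12 and self.upper <= 1.0):
            raise ValueError(
                f"invalid interval for {self.virus}: "
                f"[{self.lower}, {self.p_hat}, {self.upper}]")


@dataclass(frozen=True)
class TransmissionEstimate:
    virus: str
    donor_group: str
    n_infected: int
    n_exposed: int
    rate: float
    lower: float
    upper: float


def _as_pool_arrays(pools: Iterable[tuple[int, bool]]) -> tuple[np.ndarray, np.ndarray]:
    pools = list(pools)
    if not pools:
        raise ValueError("at least one pool is required")
    sizes = np.asarray([int(n) for n, _ in pools], dtype=float)
    pos = np.asarray([bool(b) for _, b in pools], dtype=bool)
    if np.any(sizes < 1):
        raise ValueError("pool sizes must be >= 1")
    return sizes, pos


def pooled_loglik(p: float, pools: Iterable[tuple[int, bool]]) -> float:
    """Log-likelihood of individual prevalence ``p`` given pooled assays.

    ``pools`` is an iterable of ``(size, positive)`` tuples.  Positive
    pools contribute ``log(1 - (1-p)**n)``; negative pools ``n*log(1-p)``.
    Impossible configurations return ``-inf``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    sizes, pos = _as_pool_arrays(pools)
    with np.errstate(divide="ignore"):
        if p == 0.0:
            return float("-inf") if pos.any() else 0.0
        if p == 1.0:
            return 0.0 if pos.all() else float("-inf")
        log_q = np.log1p(-p)
        # log(1 - (1-p)^n) via log1p(-exp(n log q)) for numerical stability
        ll_pos = np.log1p(-np.exp(sizes[pos] * log_q)).sum()
        ll_neg = (sizes[~pos] * log_q).sum()
    return float(ll_pos + ll_neg)


def _loglik_vec(p: np.ndarray, sizes: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Vectorized pooled log-likelihood over an array of prevalences."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_q = np.log1p(-np.clip(p, 0.0, 1.0 - 1e-300))[:, None]
        pos_part = np.log1p(-np.exp(sizes[None, pos] * log_q)).sum(axis=1)
        neg_part = (sizes[None, ~pos] * log_q).sum(axis=1)
        out = pos_part + neg_part
    out[np.asarray(p) == 0.0] = 0.0 if not pos.any() else -np.inf
    out[np.asarray(p) == 1.0] = 0.0 if pos.all() else -np.inf
    return out


def estimate_prevalence(
    pools: Iterable[tuple[int, bool]],
    virus: str = "",
    drop: float = SUPPORT_DROP,
) -> PrevalenceEstimate:
    """MLE of individual prevalence from pooled assays with support bounds.

    The likelihood is unimodal in ``p``; the maximizer is found by bounded
    scalar optimization (tolerance 1e-10) and the support bounds by root
    bisection of ``loglik(p_hat) - loglik(p) - drop`` on either side.
    All-negative data give ``p_hat = 0``; all-positive give ``p_hat = 1``.
    """
    sizes, pos = _as_pool_arrays(pools)
    n_pools = len(sizes)
    n_flies = int(sizes.sum())

    def nll(p: float) -> float:
        return -pooled_loglik(p, zip(sizes.astype(int), pos))

    if not pos.any():
        p_hat, ll_max = 0.0, 0.0
    elif pos.all():
        p_hat, ll_max = 1.0, 0.0
    else:
        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-10})
        p_hat = float(res.x)
        ll_max = -float(res.fun)

    def g(p: float) -> float:
        return ll_max - pooled_loglik(p, zip(sizes.astype(int), pos)) - drop

    # lower bound
    if p_hat == 0.0:
        lower = 0.0
    else:
        eps = min(1e-12, p_hat / 2)
        lower = 0.0 if g(eps) <= 0.0 else float(brentq(g, eps, p_hat, xtol=1e-12))
        if pooled_loglik(0.0, zip(sizes.astype(int), pos)) >= ll_max - drop:
            lower = 0.0
    # upper bound
    if p_hat == 1.0:
        upper = 1.0
    else:
        hi = 1.0 - 1e-12
        upper = 1.0 if g(hi) <= 0.0 else float(brentq(g, p_hat, hi, xtol=1e-12))
        if pooled_loglik(1.0, zip(sizes.astype(int), pos)) >= ll_max - drop:
            upper = 1.0
    lower = min(lower, p_hat)
    upper = max(upper, p_hat)
    return PrevalenceEstimate(virus=virus, p_hat=p_hat, lower=lower,
                              upper=upper, n_pools=n_pools, n_flies=n_flies)


def estimate_transmission(
    n_infected: int,
    n_exposed: int,
    virus: str = "",
    donor_group: str = "",
) -> TransmissionEstimate:
    """Transmission rate (infected / exposed) with 2-log-likelihood bounds.

    Equivalent to pooled prevalence estimation with every pool of size 1,
    for which the MLE reduces to the binomial proportion.
    """
    if n_exposed < 1:
        raise ValueError("n_exposed must be >= 1")
    if not 0 <= n_infected <= n_exposed:
        raise ValueError("need 0 <= n_infected <= n_exposed")
    pools = [(1, True)] * n_infected + [(1, False)] * (n_exposed - n_infected)
    est = estimate_prevalence(pools, virus=virus)
    rate = n_infected / n_exposed
    return TransmissionEstimate(virus=virus, donor_group=donor_group,
                                n_infected=n_infected, n_exposed=n_exposed,
                                rate=rate, lower=est.lower, upper=est.upper)


def fisher_exact_rxc(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher-Freeman-Halton exact p for an r x 2 count table.

    Enumerates every table with the observed margins and sums the
    (multivariate hypergeometric) probabilities of all tables no more
    probable than the observed one, with a 1e-12 tolerance on the
    comparison of log-probabilities so that equal-probability tables are
    always included.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError("table must have 2 columns and at least 2 rows")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = np.round(t).astype(int)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all margins must be positive")
    n_total = int(row.sum())
    c1 = int(col[0])

    # log-probability of a first-column configuration a_1..a_r:
    #   sum_i log C(row_i, a_i) - log C(N, c1)
    log_denom = gammaln(n_total + 1) - gammaln(c1 + 1) - gammaln(n_total - c1 + 1)

    def log_prob(a: tuple[int, ...]) -> float:
        lp = -log_denom
        for r_i, a_i in zip(row, a):
            lp += (gammaln(r_i + 1) - gammaln(a_i + 1) - gammaln(r_i - a_i + 1))
        return lp

    lp_obs = log_prob(tuple(int(x) for x in t[:, 0]))

    total = 0.0
    stack = [((), c1)]
    r = len(row)
    while stack:
        prefix, remaining = stack.pop()
        i = len(prefix)
        if i == r - 1:
            if 0 <= remaining <= row[i]:
                lp = log_prob(prefix + (remaining,))
                if lp <= lp_obs + 1e-12:
                    total += float(np.exp(lp))
            continue
        tail_capacity = int(row[i + 1:].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(int(row[i]), remaining)
        for a_i in range(lo, hi + 1):
            stack.append((prefix + (a_i,), remaining - a_i))
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# Table-level wrappers


def prevalence_by_group(donors: pd.DataFrame) -> pd.DataFrame:
    """Per-virus, per-species-group prevalence estimates from donor pools.

    ``donors`` is the long-format donor table (vial_id, species_group,
    pool_size, virus, assay_positive).  Each (group, virus) combination is
    estimated across all of that group's pools.
    """
    rows = []
    for (group, virus), sub in donors.groupby(["species_group", "virus"], sort=True):
        pools = list(zip(sub["pool_size"].astype(int), sub["assay_positive"].astype(bool)))
        est = estimate_prevalence(pools, virus=str(virus))
        rows.append({
            "species_group": group, "virus": virus, "p_hat": est.p_hat,
            "lower": est.lower, "upper": est.upper,
            "n_pools": est.n_pools, "n_flies": est.n_flies,
        })
    return pd.DataFrame(rows)


def transmission_by_virus(
    detections: pd.DataFrame,
    donors: pd.DataFrame | None = None,
    recipients: pd.DataFrame | None = None,
    by_group: bool = False,
) -> pd.DataFrame:
    """Transmission-rate estimates per virus (optionally per donor group).

    Exposure is taken from the long detection table: a fly was exposed to
    every virus flagged ``exposed`` for it; it was infected if ``detected``.
    """
    det = detections[detections["exposed"].astype(bool)].copy()
    if by_group:
        if donors is None or recipients is None:
            raise ValueError("by_group requires donors and recipients tables")
        vial_group = donors.drop_duplicates("vial_id").set_index("vial_id")["species_group"]
        fly_vial = recipients.set_index("fly_id")["vial_id"]
        det["donor_group"] = det["fly_id"].map(fly_vial).map(vial_group)
        keys = ["virus", "donor_group"]
    else:
        keys = ["virus"]
    rows = []
    for key, sub in det.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n_exp = len(sub)
        n_inf = int(sub["detected"].astype(bool).sum())
        est = estimate_transmission(n_inf, n_exp, virus=str(key[0]),
                                    donor_group=str(key[1]) if by_group else "")
        rows.append({
            "virus": key[0],
            **({"donor_group": key[1]} if by_group else {}),
            "n_infected": n_inf, "n_exposed": n_exp, "rate": est.rate,
            "lower": est.lower, "upper": est.upper,
        })
    return pd.DataFrame(rows)


def donor_group_transmission_table(
    transmitted: dict[str, tuple[int, int]],
) -> np.ndarray:
    """Build the per-donor-group (transmitted, not transmitted) count table.

    ``transmitted`` maps donor group -> (number of viruses transmitted,
    number of viruses present in that group's pools).
    """
    rows = []
    for group in sorted(transmitted):
        k, n = transmitted[group]
        if not 0 <= k <= n:
            raise ValueError(f"group {group}: need 0 <= transmitted <= present")
        rows.append([k, n - k])
    return np.asarray(rows, dtype=int)
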