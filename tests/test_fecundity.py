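"""Hurdle-Poisson fecundity models, estimability and the zero-count check."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from flyvir.data import RunConfig
from flyvir.fecundity import (detect_zero_estimable, early_late_correlation,
                              fit_fecundity, percent_offspring_reduction,
                              posterior_predictive_zeros)
from flyvir.mcmc import sample_zt_poisson

from conftest import build_table


def make_fecundity_table(rng, n=400, effect=-0.6, g0=-1.2, b0=np.log(40),
                         p_inf=0.5, n_vials=20):
    vials = np.repeat(np.arange(n_vials), n // n_vials)
    infected = rng.random(n) < p_inf
    lam = np.exp(b0 + effect * infected + rng.normal(0, 0.2, n))
    y = sample_zt_poisson(rng, lam)
    y[rng.random(n) < 1 / (1 + np.exp(-g0))] = 0
    life = np.clip(rng.normal(40, 10, n), 14, None)
    return build_table(life, {"virA": infected}, vials, offspring_total=y,
                       offspring_early=np.minimum(y, 1)), infected, y


class TestZeroEstimable:
    def test_three_reason_codes(self):
        n = 30
        vials = np.zeros(n, int)
        infs = {
            "allpos": np.r_[np.ones(10, bool), np.zeros(20, bool)],
            "mixed": np.r_[np.zeros(10, bool), np.ones(10, bool), np.zeros(10, bool)],
            "never": np.zeros(n, bool),
        }
        y = np.r_[np.full(10, 20), np.full(5, 0), np.full(5, 15), np.full(10, 7)]
        table = build_table(np.full(n, 30.0), infs, vials, offspring_total=y)
        estimable, excluded = detect_zero_estimable(table)
        assert estimable == ["mixed"]
        assert excluded == {"allpos": "all_nonzero", "never": "no_infected"}

    def test_all_zero_reason(self):
        infs = {"sterile": np.r_[np.ones(5, bool), np.zeros(15, bool)]}
        y = np.r_[np.zeros(5, int), np.full(15, 10)]
        table = build_table(np.full(20, 30.0), infs, np.zeros(20, int),
                            offspring_total=y)
        _, excluded = detect_zero_estimable(table)
        assert excluded == {"sterile": "all_zero"}


class TestFitFecundity:
    def test_early_window_filters_flagged_flies(self, fast_cfg):
        rng = np.random.default_rng(0)
        table, _, _ = make_fecundity_table(rng)
        table.recipients.loc[table.recipients.index[:10], "excluded_early"] = True
        fit = fit_fecundity(table, fast_cfg, window="early", seed=1)
        assert fit.n_used == len(table.recipients) - 10

    def test_windows_differ_only_by_response_and_filter(self, fast_cfg):
        """With identical early/total counts and no exclusions the two
        windows give identical chains."""
        rng = np.random.default_rng(1)
        table, _, y = make_fecundity_table(rng)
        table.recipients["offspring_early"] = y
        a = fit_fecundity(table, fast_cfg, window="lifetime", seed=2)
        b = fit_fecundity(table, fast_cfg, window="early", seed=2)
        assert np.array_equal(a.chain.draws, b.chain.draws)

    def test_all_nonzero_counts_rejected(self, fast_cfg):
        rng = np.random.default_rng(2)
        table, _, y = make_fecundity_table(rng)
        table.recipients["offspring_total"] = np.maximum(y, 1)
        with pytest.raises(ValueError, match="hurdle"):
            fit_fecundity(table, fast_cfg)

    def test_count_posterior_matches_truncated_poisson_mle(self, fast_cfg):
        """No virus effects, intercept-only: posterior rate vs direct
        zero-truncated Poisson ML oracle."""
        rng = np.random.default_rng(3)
        n = 800
        lam_true = 25.0
        y = sample_zt_poisson(rng, np.full(n, lam_true))
        y[rng.random(n) < 0.2] = 0
        table = build_table(np.full(n, 30.0),
                            {"virA": np.r_[np.ones(2, bool), np.zeros(n - 2, bool)]},
                            np.repeat(np.arange(20), n // 20), offspring_total=y)
        cfg = RunConfig(seed=0, chain_total=2500, burn_in=1000, chain_recorded=600)
        fit = fit_fecundity(table, cfg, seed=4)
        pos = y[y > 0].astype(float)

        def nll(loglam):
            lam = np.exp(loglam)
            return -(pos * loglam - lam - np.log1p(-np.exp(-lam))).sum()

        mle = np.exp(minimize_scalar(nll, bounds=(0, 6), method="bounded").x)
        rate = np.exp(fit.chain.col("count_intercept"))
        assert rate.mean() == pytest.approx(mle, abs=3 * rate.std())


class TestPercentReduction:
    def test_arithmetic_on_frozen_draws(self, fast_cfg):
        rng = np.random.default_rng(4)
        table, _, _ = make_fecundity_table(rng)
        fit = fit_fecundity(table, fast_cfg, seed=5)
        fit.chain.draws[:, fit.chain.names.index("count_virA")] = -0.616
        s = percent_offspring_reduction(fit, "virA")
        assert s.mean == pytest.approx(100 * (1 - np.exp(-0.616)), abs=1e-9)
        assert s.mean == pytest.approx(46.0, abs=0.1)
        fit.chain.draws[:, fit.chain.names.index("count_virA")] = 0.0
        assert percent_offspring_reduction(fit, "virA").mean == 0.0

    def test_unknown_virus_rejected(self, fast_cfg):
        rng = np.random.default_rng(5)
        table, _, _ = make_fecundity_table(rng)
        fit = fit_fecundity(table, fast_cfg, seed=6)
        with pytest.raises(KeyError):
            percent_offspring_reduction(fit, "ghost")


class TestPosteriorPredictiveZeros:
    def test_doubling_zeros_falls_above_band(self, fast_cfg):
        rng = np.random.default_rng(6)
        table, _, y = make_fecundity_table(rng)
        fit = fit_fecundity(table, fast_cfg, seed=7)
        # corrupt the observed data after fitting: zeros doubled post hoc
        extra = (y > 0) & (rng.random(y.size) < 0.5)
        fit.y = np.where(extra, 0, fit.y)
        ppc = posterior_predictive_zeros(fit, n_draws=150, seed=8)
        assert ppc.observed_zeros > ppc.band_high
        assert not ppc.inside_band

    def test_self_consistent_data_inside_band(self, fast_cfg):
        rng = np.random.default_rng(7)
        table, _, _ = make_fecundity_table(rng)
        fit = fit_fecundity(table, fast_cfg, seed=9)
        ppc = posterior_predictive_zeros(fit, n_draws=200, seed=10)
        assert ppc.inside_band

    def test_draw_count_validation(self, fast_cfg):
        rng = np.random.default_rng(8)
        table, _, _ = make_fecundity_table(rng)
        fit = fit_fecundity(table, fast_cfg, seed=11)
        with pytest.raises(ValueError):
            posterior_predictive_zeros(fit, n_draws=0)
        with pytest.warns(UserWarning, match="coarse"):
            posterior_predictive_zeros(fit, n_draws=10, seed=12)


class TestEarlyLateCorrelation:
    def _table(self, early, late):
        early = np.asarray(early, int)
        late = np.asarray(late, int)
        n = early.size
        return build_table(np.full(n, 30.0), {"virA": np.zeros(n, bool) | (np.arange(n) == 0)},
                           np.zeros(n, int), offspring_total=early + late,
                           offspring_early=early)

    def test_identical_windows_give_unit_correlation(self):
        x = np.arange(1, 21)
        res = early_late_correlation(self._table(x, x))
        assert res["r"] == pytest.approx(1.0)

    def test_orthogonal_windows_give_zero(self):
        early = np.tile([0, 0, 10, 10], 5)
        late = np.tile([0, 10, 0, 10], 5)
        res = early_late_correlation(self._table(early, late))
        assert res["r"] == pytest.approx(0.0, abs=1e-12)

    def test_bivariate_simulation_recovers_rho(self):
        rng = np.random.default_rng(9)
        n, rho = 596, 0.32
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        early = np.round(50 + 10 * z1).astype(int).clip(0)
        late = np.round(50 + 10 * z2).astype(int).clip(0)
        res = early_late_correlation(self._table(early, late))
        se = (1 - rho**2) / np.sqrt(n)
        assert res["r"] == pytest.approx(rho, abs=3 * se)
        assert res["ci_low"] < res["r"] < res["ci_high"]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            early_late_correlation(self._table(np.full(10, 5), np.arange(10)))
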