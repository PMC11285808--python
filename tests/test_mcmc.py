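"""MCMC engine: diagnostics, conjugate correctness, samplers."""

import numpy as np
import pytest

from flyvir.mcmc import (ChainResult, PriorSpec, effective_sample_size,
                         gibbs_lmm, hpd_interval, hurdle_poisson_mcmc,
                         indicator_matrix, pmcmc, sample_zt_poisson,
                         summarize_chain)


class Cfg:
    chain_total = 1500
    burn_in = 400
    chain_recorded = 500
    seed = 0


class TestHpd:
    def test_degenerate_constant_draws(self):
        assert hpd_interval([3.0, 3.0, 3.0], 0.95) == (3.0, 3.0)

    def test_uniform_grid_tie_break_to_lowest_start(self):
        # all windows of 95 consecutive integers have equal width
        assert hpd_interval(np.arange(1, 101), 0.95) == (1.0, 95.0)

    def test_point_mass_with_outliers(self):
        draws = [0.0] * 97 + [10.0] * 3
        assert hpd_interval(draws, 0.95) == (0.0, 0.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hpd_interval([1.0], 0.95)
        with pytest.raises(ValueError):
            hpd_interval([1.0, 2.0], 1.5)


class TestEss:
    def test_independent_draws_near_n(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        assert abs(effective_sample_size(x) - 10_000) < 1000

    def test_ar1_matches_closed_form(self):
        # AR(1) with phi: ESS/n -> (1-phi)/(1+phi) = 1/3 at phi = 0.5
        rng = np.random.default_rng(1)
        n = 200_000
        x = np.empty(n)
        x[0] = 0.0
        e = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = 0.5 * x[i - 1] + e[i]
        assert effective_sample_size(x) / n == pytest.approx(1 / 3, abs=0.03)

    def test_constant_series_defined_as_n(self):
        assert effective_sample_size(np.ones(100)) == 100.0

    def test_agrees_with_arviz_on_correlated_chain(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        x = np.convolve(rng.standard_normal(20_000), np.ones(5) / 5, "same")
        ours = effective_sample_size(x)
        theirs = float(az.ess(x[None, :]))
        assert ours == pytest.approx(theirs, rel=0.25)


class TestPmcmc:
    def test_symmetric_draws(self):
        assert pmcmc(np.r_[np.ones(500), -np.ones(500)]) == 1.0

    def test_tail_arithmetic(self):
        x = np.r_[np.ones(250), -np.ones(9750)]
        assert pmcmc(x) == pytest.approx(0.05)

    def test_floor_rule(self):
        assert pmcmc(-np.ones(10_000)) == pytest.approx(2e-4)


class TestGibbsLmm:
    def test_matches_conjugate_normal_posterior(self):
        """Known residual variance, intercept-only: closed-form posterior."""
        rng = np.random.default_rng(3)
        n, s2 = 80, 4.0
        y = rng.normal(2.5, 2.0, n)

        class C(Cfg):
            chain_total = 20_000
            burn_in = 2000
            chain_recorded = 4000

        ch = gibbs_lmm(np.ones((n, 1)), y, None, PriorSpec(), C, seed=4,
                       fix_resid_var=s2)
        v_post = 1.0 / (n / s2 + 1e-10)
        m_post = v_post * y.sum() / s2
        d = ch.col("b_b0")
        mc_se = d.std() / np.sqrt(effective_sample_size(d))
        assert d.mean() == pytest.approx(m_post, abs=3 * mc_se)
        assert d.var() == pytest.approx(v_post, rel=0.15)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 50)
        X = np.c_[np.ones(50), rng.random(50)]
        a = gibbs_lmm(X, y, None, PriorSpec(), Cfg, seed=9)
        b = gibbs_lmm(X, y, None, PriorSpec(), Cfg, seed=9)
        assert np.array_equal(a.draws, b.draws)

    def test_rank_deficient_design_names_columns(self):
        X = np.c_[np.ones(20), np.ones(20)]
        with pytest.raises(ValueError, match="dup"):
            gibbs_lmm(X, np.zeros(20), None, PriorSpec(), Cfg,
                      fixed_names=["intercept", "dup"])

    def test_zero_variance_response_tolerated(self):
        y = np.full(30, 5.0)
        ch = gibbs_lmm(np.ones((30, 1)), y, None, PriorSpec(), Cfg, seed=6)
        # residual variance collapses toward its (nearly flat) prior floor
        assert ch.col("var_residual").mean() < 0.01
        assert np.all(np.isfinite(ch.draws))

    def test_posterior_mean_matches_reml_oracle(self):
        """Random-intercept model vs statsmodels MixedLM on 5 datasets."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        for rep in range(5):
            q, per = 8, 15
            n = q * per
            codes = np.repeat(np.arange(q), per)
            x = rng.random(n)
            y = (1.0 + 2.0 * x + rng.normal(0, 1.0, q)[codes]
                 + rng.normal(0, 1.5, n))
            X = np.c_[np.ones(n), x]

            class C(Cfg):
                chain_total = 4000
                burn_in = 1000
                chain_recorded = 1000

            ch = gibbs_lmm(X, y, {"g": indicator_matrix(codes)}, PriorSpec(),
                           C, seed=100 + rep, fixed_names=["int", "x"])
            fit = sm.MixedLM(y, X, groups=codes).fit(reml=True)
            for j, name in enumerate(["b_int", "b_x"]):
                d = ch.col(name)
                assert d.mean() == pytest.approx(fit.fe_params[j],
                                                 abs=3 * d.std())


class TestZtPoisson:
    def test_mean_matches_closed_form(self):
        lam = 2.0
        s = sample_zt_poisson(np.random.default_rng(8), np.full(100_000, lam))
        target = lam / (1 - np.exp(-lam))
        mc_se = s.std() / np.sqrt(s.size)
        assert s.mean() == pytest.approx(target, abs=3 * mc_se)
        assert s.min() >= 1

    def test_tiny_rate_returns_one(self):
        s = sample_zt_poisson(np.random.default_rng(9), np.full(100, 1e-12))
        assert np.all(s == 1)


class TestHurdlePoisson:
    def test_no_zeros_gives_small_hurdle_probability(self):
        rng = np.random.default_rng(10)
        y = sample_zt_poisson(rng, np.full(400, 30.0))

        class C(Cfg):
            chain_total = 2500
            burn_in = 1000
            chain_recorded = 600

        ch = hurdle_poisson_mcmc(np.ones((400, 1)), np.ones((400, 1)), y,
                                 None, None, PriorSpec(), C, seed=11)
        p_zero = 1 / (1 + np.exp(-ch.col("zero_z0")))
        assert p_zero.mean() < 0.05

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            hurdle_poisson_mcmc(np.ones((20, 1)), np.ones((20, 1)),
                                np.zeros(20), None, None, PriorSpec(), Cfg)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hurdle_poisson_mcmc(np.ones((5, 1)), np.ones((5, 1)),
                                np.array([1, 2, -1, 0, 3]), None, None,
                                PriorSpec(), Cfg)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(12)
        y = sample_zt_poisson(rng, np.full(100, 10.0))
        y[rng.random(100) < 0.3] = 0
        a = hurdle_poisson_mcmc(np.ones((100, 1)), np.ones((100, 1)), y,
                                None, None, PriorSpec(), Cfg, seed=13)
        b = hurdle_poisson_mcmc(np.ones((100, 1)), np.ones((100, 1)), y,
                                None, None, PriorSpec(), Cfg, seed=13)
        assert np.array_equal(a.draws, b.draws)


def test_summarize_chain_flags_low_ess():
    draws = np.random.default_rng(14).standard_normal((500, 2))
    ch = ChainResult(names=["a", "b"], draws=draws, seed=0, burn_in=0, thin=1)
    s = summarize_chain(ch, ess_floor=1e6)
    assert s["low_ess"].all()
    assert set(s.columns) >= {"parameter", "mean", "hpd_low", "hpd_high",
                              "ess", "pmcmc"}
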