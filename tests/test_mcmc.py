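"""Gibbs samplers against conjugate/enumeration oracles, and diagnostics."""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist, ks_2samp

from _oracles import posterior_mean_p_grid, posterior_mean_p_nonignorable
from blackboxnr import (
    ChainConfig,
    HyperParams,
    PriorSpec,
    assess_convergence,
    batch_means_mcse,
    fit_ignorable,
    fit_naive,
    fit_nonignorable_eb,
    gelman_rubin_multivariate,
)

FIXED = HyperParams.ignorable(0.5, 2.0, 0.5, 2.0)


class TestNaive:
    def test_conjugate_closed_form(self, mkpanel):
        # fixed hyperparameters: p | data ~ Beta(1, 11) exactly
        panel = mkpanel([(10, 10, 0)])
        cfg = ChainConfig(n_chains=2, n_iter=9000, n_burn=1000, seed=5)
        draws = fit_naive(panel, config=cfg, hyper=FIXED)
        x = draws.flat("p")[:, 0]
        mcse = batch_means_mcse(x)
        assert abs(x.mean() - 1 / 12) < 4 * mcse
        q = beta_dist.ppf([0.25, 0.75], 1, 11)
        emp = np.quantile(x, [0.25, 0.75])
        assert np.allclose(emp, q, atol=0.01)

    def test_two_examiner_grid_oracle(self, mkpanel):
        panel = mkpanel([(8, 8, 1), (10, 10, 0)])
        pri = PriorSpec()
        cfg = ChainConfig(n_chains=2, n_iter=15_000, n_burn=5_000, seed=6)
        draws = fit_naive(panel, pri, cfg)
        oracle = posterior_mean_p_grid([1, 0], [8, 10], pri)
        assert abs(draws.flat("p")[:, 0].mean() - oracle) < 0.01

    def test_seed_determinism_bit_identical(self, mkpanel):
        panel = mkpanel([(6, 5, 1), (6, 6, 0)])
        cfg = ChainConfig(n_chains=2, n_iter=600, n_burn=100, seed=42)
        a = fit_naive(panel, config=cfg)
        b = fit_naive(panel, config=cfg)
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.hyper["mu_p"], b.hyper["mu_p"])

    def test_chains_exchangeable(self, mkpanel):
        panel = mkpanel([(20, 18, 2)])
        cfg = ChainConfig(n_chains=2, n_iter=12_000, n_burn=2_000, seed=7)
        draws = fit_naive(panel, config=cfg, hyper=FIXED)
        stat = ks_2samp(draws.p[0, ::20, 0], draws.p[1, ::20, 0]).statistic
        assert stat < 0.12

    def test_rejects_empty(self, mkpanel):
        with pytest.raises(ValueError):
            fit_naive(mkpanel([(5, 0, 0)]))


@pytest.fixture(scope="module")
def ignorable_fit():
    from conftest import make_panel
    panel = make_panel([(10, 8, 1), (12, 2, 0)])
    pri = PriorSpec()
    cfg = ChainConfig(n_chains=2, n_iter=15_000, n_burn=5_000, seed=8)
    return panel, pri, fit_ignorable(panel, pri, cfg)


class TestIgnorable:
    def test_grid_oracle_p_and_pi(self, ignorable_fit):
        panel, pri, draws = ignorable_fit
        # the p-block and pi-block posteriors factorize; each matches the
        # dense-grid marginalization of its own conjugate hierarchy
        assert abs(draws.flat("p")[:, 0].mean()
                   - posterior_mean_p_grid([1, 0], [8, 2], pri)) < 0.01
        assert abs(draws.flat("pi")[:, 0].mean()
                   - posterior_mean_p_grid([8, 2], [10, 12], pri)) < 0.01

    def test_zero_responder_draws_from_population(self, mkpanel):
        panel = mkpanel([(22, 0, 0), (22, 20, 1)])
        cfg = ChainConfig(n_chains=2, n_iter=8000, n_burn=1000, seed=9)
        h = HyperParams.ignorable(0.3, 10.0, 0.6, 10.0)
        draws = fit_ignorable(panel, config=cfg, hyper=h)
        x = draws.flat("p")[:, 0]
        assert abs(x.mean() - 0.3) < 4 * batch_means_mcse(x) + 0.005

    def test_response_rate_monotonicity(self, mkpanel):
        panel = mkpanel([(22, 22, 0), (22, 2, 0)])
        cfg = ChainConfig(n_chains=2, n_iter=10_000, n_burn=2_000, seed=10)
        draws = fit_ignorable(panel, config=cfg)
        pi = draws.flat("pi")
        assert pi[:, 0].mean() > pi[:, 1].mean()


class TestNonignorableEB:
    def test_toy_panel_matches_quadrature(self, mkpanel):
        panel = mkpanel([(3, 2, 1), (3, 1, 0)])
        h = HyperParams(0.3, 2.0, 0.6, 2.0, 0.4, 2.0)
        cfg = ChainConfig(n_chains=2, n_iter=22_000, n_burn=2_000, seed=11)
        draws = fit_nonignorable_eb(panel, h, cfg)
        for i, stats in enumerate([(3, 2, 1), (3, 1, 0)]):
            oracle = posterior_mean_p_nonignorable(*stats, h)
            assert abs(draws.flat("p")[:, i].mean() - oracle) < 0.01

    def test_no_missingness_collapse(self, mkpanel):
        # R = J: z is identically 0 and pi2 | . ~ Beta(a2 + E, b2)
        panel = mkpanel([(6, 6, 2)])
        h = HyperParams(0.3, 2.0, 0.6, 2.0, 0.4, 5.0)
        cfg = ChainConfig(n_chains=2, n_iter=10_000, n_burn=1_000, seed=12)
        draws = fit_nonignorable_eb(panel, h, cfg)
        a2, b2 = h.ab_pi2()
        x = draws.flat("pi2")[:, 0]
        assert abs(x.mean() - (a2 + 2) / (a2 + 2 + b2)) \
            < 4 * batch_means_mcse(x) + 0.003
        # p | . ~ Beta(a_p + E, b_p + J - E)
        a_p, b_p = h.ab_p()
        y = draws.flat("p")[:, 0]
        assert abs(y.mean() - (a_p + 2) / (a_p + b_p + 6)) \
            < 4 * batch_means_mcse(y) + 0.003

    def test_forced_equal_response_blocks_match_conjugate(self, mkpanel):
        # pi1 = pi2 = 0.7 (huge tau): augmentation adds no information and
        # the p-marginal is the conjugate Beta(a_p + E, b_p + R - E)
        panel = mkpanel([(12, 5, 1)])
        h = HyperParams(0.2, 4.0, 0.7, 1e8, 0.7, 1e8)
        cfg = ChainConfig(n_chains=2, n_iter=15_000, n_burn=2_000, seed=13)
        draws = fit_nonignorable_eb(panel, h, cfg)
        a_p, b_p = h.ab_p()
        x = draws.flat("p")[:, 0]
        assert abs(x.mean() - (a_p + 1) / (a_p + b_p + 5)) \
            < 4 * batch_means_mcse(x) + 0.003

    def test_draws_in_open_interval(self, mkpanel):
        panel = mkpanel([(5, 2, 1), (5, 5, 0), (5, 0, 0)])
        h = HyperParams(0.2, 1.0, 0.6, 0.5, 0.05, 1.0)
        cfg = ChainConfig(n_chains=2, n_iter=3000, n_burn=500, seed=14)
        draws = fit_nonignorable_eb(panel, h, cfg)
        for name in ("p", "pi1", "pi2"):
            x = draws.flat(name)
            assert np.all((x > 0) & (x < 1))


class TestBatchMeans:
    def test_constant_chain_is_zero(self):
        assert batch_means_mcse(np.full(100, 3.3)) == 0.0

    def test_iid_normal_scales_like_sqrt_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        mcse = batch_means_mcse(x)
        assert 0.01 / 1.5 < mcse < 0.01 * 1.5

    def test_autocorrelated_chain_inflates_mcse(self):
        rng = np.random.default_rng(1)
        n, rho = 20_000, 0.9
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0]
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        iid = rng.normal(size=n) * np.std(x)
        assert batch_means_mcse(x) > 2 * batch_means_mcse(iid)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            batch_means_mcse(np.ones(3))


class TestGelmanRubin:
    def test_identical_chains_unity(self):
        rng = np.random.default_rng(2)
        one = rng.normal(size=(1000, 3))
        val, _ = gelman_rubin_multivariate(np.stack([one, one]))
        assert val == pytest.approx(1.0, abs=0.01)

    def test_stationary_chains_below_threshold(self):
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(2, 5000, 4))
        val, fb = gelman_rubin_multivariate(chains)
        assert not fb and val < 1.1

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(3000, 2))
        b = rng.normal(size=(3000, 2)) + 1.5
        val, _ = gelman_rubin_multivariate(np.stack([a, b]))
        assert val > 1.1

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin_multivariate(np.zeros((1, 100, 2)))


class TestConvergenceReport:
    def test_default_settings_fit_passes(self, mkpanel):
        panel = mkpanel([(22, 20, 1), (22, 15, 0), (22, 8, 0), (22, 22, 2)])
        cfg = ChainConfig(n_chains=2, n_iter=6000, n_burn=1000, seed=15)
        draws = fit_naive(panel, config=cfg)
        rep = assess_convergence(draws)
        assert rep.max_mcse < 0.01
        assert rep.mpsrf < 1.1
        assert rep.passed
        d = rep.to_dict()
        assert set(d) >= {"max_mcse", "mpsrf", "passed"}

    def test_default_chain_lengths_match_reanalysis_settings(self):
        assert ChainConfig().n_iter == 15_000 and ChainConfig().n_burn == 5_000
        from blackboxnr.mcmc import PSRF_THRESHOLD
        assert PSRF_THRESHOLD == {"naive": 1.1, "ignorable": 1.1,
                                  "nonignorable": 1.2}
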