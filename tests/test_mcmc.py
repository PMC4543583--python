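import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import binom, invwishart, kstest, multivariate_normal, poisson

from multinmix import (
    McmcConfig,
    SimulationConfig,
    marginal_moments,
    run_mcmc,
    simulate,
    summarize_correlations,
    survey_loglik,
)
from multinmix.mcmc import CommunitySampler, PosteriorSamples, batch_means_mcse, sample_invwishart


def oracle_joint_log_density(sampler, state, include_prior=True):
    """Independently coded evaluator of log p(Y, N, eps, params): plain loops,
    full multinomial pmf, scipy building blocks."""
    I, K, J = sampler.I, sampler.K, sampler.J
    total = 0.0
    for i in range(I):
        for k in range(K):
            lam = np.exp(state.mu[i, k] + state.eps[i, k])
            p = 1 / (1 + np.exp(-state.logit_p[i, k]))
            pi = binom.pmf(np.arange(J + 1), J, p)
            n = state.N[i, k]
            y = sampler.Y[i, k]
            if n < y.sum():
                return -np.inf
            total += poisson.logpmf(n, lam)
            counts = np.concatenate([[n - y.sum()], y])
            from scipy.stats import multinomial

            total += multinomial.logpmf(counts, n=n, p=pi)
        total += multivariate_normal.logpdf(state.eps[i], mean=np.zeros(K),
                                            cov=state.Sigma)
    if include_prior:
        for k in range(K):
            total += -0.5 * state.beta[k] @ state.beta[k] / 100.0
            total += -0.5 * state.alpha[k] @ state.alpha[k] / 100.0
        total += invwishart.logpdf(state.Sigma, sampler.nu0, sampler.S0)
    return total


def make_sampler(counts, config=None, K=None):
    K = counts.shape[1] if K is None else K
    I = counts.shape[0]
    X = [np.ones((I, 1))] * K
    W = [np.ones((I, 1))] * K
    return CommunitySampler(counts, X, W, config or McmcConfig(n_iter=10, n_burn=2))


class TestJointLogDensity:
    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(n_locations=6, n_dates=1, K=2, J=4,
                               beta=[[0.5], [0.3]], alpha=[[0.2], [-0.2]],
                               Sigma=np.array([[0.5, 0.2], [0.2, 0.5]]), seed=1)
        ds = simulate(cfg)
        sampler = make_sampler(ds.frequency_table.counts)
        state = sampler.init_state()
        state.eps = rng.normal(scale=0.3, size=state.eps.shape)
        state.N = sampler.D + rng.integers(0, 3, size=state.N.shape)
        state.Sigma = np.array([[0.8, 0.3], [0.3, 0.6]])
        for prior in (True, False):
            assert sampler.joint_log_density(state, include_prior=prior) == \
                pytest.approx(oracle_joint_log_density(sampler, state, prior),
                              abs=1e-8)

    def test_mvn_term_at_zero_residuals_identity_sigma(self):
        counts = np.zeros((3, 2, 4), dtype=int)
        sampler = make_sampler(counts)
        state = sampler.init_state()
        state.N = np.zeros_like(state.N)
        base = sampler.joint_log_density(state, include_prior=False)
        # with N=0, eps=0, Sigma=I the only nonzero pieces are -lam per cell
        # and the MVN normalizing constant -(K/2) log(2 pi) per survey
        lam_term = -np.exp(state.mu).sum()
        assert base - lam_term == pytest.approx(
            -3 * (2 / 2) * 2 * np.log(2 * np.pi) / 2, abs=1e-10)

    def test_latent_below_observed_impossible(self):
        counts = np.zeros((2, 1, 4), dtype=int)
        counts[0, 0, 0] = 2
        sampler = make_sampler(counts)
        state = sampler.init_state()
        state.N[0, 0] = 1  # fewer birds than were detected
        assert sampler.joint_log_density(state) == -np.inf

    def test_marginalizing_latent_recovers_single_species_loglik(self):
        # K=1, eps fixed at 0 (the sigma^2 -> 0 limit): summing the joint over
        # N must reproduce the closed-form marginal likelihood
        counts = np.zeros((1, 1, 4), dtype=int)
        counts[0, 0] = [2, 1, 0, 0]
        sampler = make_sampler(counts)
        state = sampler.init_state()
        lam = np.exp(state.mu[0, 0])
        p = 1 / (1 + np.exp(-state.logit_p[0, 0]))
        terms = []
        for n in range(3, 200):
            state.N[0, 0] = n
            terms.append(sampler.joint_log_density(state, include_prior=False))
        # remove the eps-term constant: eps=0, Sigma=I contributes -0.5 log(2pi)
        mvn_const = -0.5 * np.log(2 * np.pi)
        marginal = logsumexp(terms) - mvn_const
        assert marginal == pytest.approx(
            survey_loglik([2, 1, 0, 0], lam, p), abs=1e-8)


class TestUpdateN:
    def test_perfect_detection_pins_latent_at_observed(self):
        cfg = SimulationConfig(n_locations=20, n_dates=1, K=1, J=4,
                               beta=[[1.0]], alpha=[[30.0]], seed=2)
        ds = simulate(cfg)
        sampler = make_sampler(ds.frequency_table.counts)
        state = sampler.init_state()
        state.logit_p[:] = 30.0  # p ~ 1
        state.N = sampler.D.copy()
        rng = np.random.default_rng(3)
        for _ in range(200):
            sampler.update_N(state, rng)
        np.testing.assert_array_equal(state.N, sampler.D)

    def test_proposals_below_observed_always_rejected(self):
        counts = np.zeros((50, 1, 4), dtype=int)
        counts[:, 0, 0] = 3
        sampler = make_sampler(counts)
        state = sampler.init_state()
        rng = np.random.default_rng(4)
        for _ in range(500):
            sampler.update_N(state, rng)
            assert (state.N >= sampler.D).all()

    def test_single_cell_matches_enumerated_conditional(self):
        # one survey, one species: the chain's stationary law of N must match
        # the truncated conditional computed by enumeration
        counts = np.zeros((1, 1, 4), dtype=int)
        counts[0, 0] = [1, 1, 0, 0]
        sampler = make_sampler(counts)
        state = sampler.init_state()
        state.mu[:] = np.log(4.0)  # lambda = 4
        state.logit_p[:] = np.log(0.3 / 0.7)  # p = 0.3
        lam, p = 4.0, 0.3
        ns = np.arange(2, 80)
        logw = (poisson.logpmf(ns, lam)
                + np.array([np.sum(np.log(np.arange(n - 1, n + 1)))  # n!/(n-2)!
                            for n in ns])
                + (ns - 2) * 4 * np.log(1 - p))
        w = np.exp(logw - logsumexp(logw))
        cdf_target = np.cumsum(w)
        rng = np.random.default_rng(5)
        draws = []
        for it in range(40000):
            sampler.update_N(state, rng)
            if it >= 2000:
                draws.append(state.N[0, 0])
        draws = np.asarray(draws)
        emp_cdf = np.array([(draws <= n).mean() for n in ns])
        ks = np.abs(emp_cdf - cdf_target).max()
        assert ks < 0.02


class TestUpdateEpsilon:
    def test_prior_only_recovers_sigma_correlation(self):
        rho = 0.8
        Sigma = np.array([[1.0, rho], [rho, 1.0]])
        counts = np.zeros((800, 2, 4), dtype=int)
        sampler = make_sampler(counts)
        state = sampler.init_state()
        state.Sigma = Sigma
        state.s_eps = 0.0
        rng = np.random.default_rng(6)
        for _ in range(600):
            sampler.update_epsilon(state, rng, use_data=False)
        r = np.corrcoef(state.eps[:, 0], state.eps[:, 1])[0, 1]
        assert r == pytest.approx(rho, abs=0.06)
        # conditional-mean structure: slope of eps1 on eps2 is rho*s1/s2
        slope = np.polyfit(state.eps[:, 1], state.eps[:, 0], 1)[0]
        assert slope == pytest.approx(rho, abs=0.1)

    def test_diagonal_sigma_gives_uncorrelated_chains(self):
        counts = np.zeros((800, 2, 4), dtype=int)
        sampler = make_sampler(counts)
        state = sampler.init_state()
        state.s_eps = 0.0
        rng = np.random.default_rng(7)
        for _ in range(600):
            sampler.update_epsilon(state, rng, use_data=False)
        r = np.corrcoef(state.eps[:, 0], state.eps[:, 1])[0, 1]
        assert abs(r) < 0.1


class TestUpdateSigma:
    def test_zero_residuals_match_analytic_iw_mean(self):
        K, I = 2, 40
        counts = np.zeros((I, K, 4), dtype=int)
        cfg = McmcConfig(n_iter=10, n_burn=2, nu0=K + 3)
        sampler = make_sampler(counts, cfg)
        state = sampler.init_state()
        state.eps[:] = 0.0
        rng = np.random.default_rng(8)
        draws = []
        for _ in range(4000):
            sampler.update_Sigma(state, rng)
            draws.append(state.Sigma.copy())
        mean = np.mean(draws, axis=0)
        expect = sampler.S0 / (sampler.nu0 + I - K - 1)
        np.testing.assert_allclose(mean, expect, atol=0.004)

    def test_concentration_around_generating_sigma(self):
        rng = np.random.default_rng(9)
        Sigma_true = np.array([[1.0, -0.5], [-0.5, 0.8]])
        L = np.linalg.cholesky(Sigma_true)
        eps = rng.standard_normal((2000, 2)) @ L.T
        counts = np.zeros((2000, 2, 4), dtype=int)
        sampler = make_sampler(counts)
        state = sampler.init_state()
        state.eps = eps
        draws = [sampler.update_Sigma(state, rng) or state.Sigma.copy()
                 for _ in range(200)]
        mean = np.mean(draws, axis=0)
        np.testing.assert_allclose(mean, Sigma_true, rtol=0.10, atol=0.03)

    def test_non_positive_definite_scale_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            sample_invwishart(5, np.array([[1.0, 2.0], [2.0, 1.0]]), rng)

    def test_no_observations_draws_from_prior(self):
        # df = nu0, scale = S0: the conjugate update with zero surveys
        rng = np.random.default_rng(11)
        draws = np.array([sample_invwishart(6, np.eye(2), rng)[0, 0]
                          for _ in range(2000)])
        # IW marginal diagonal: S0_kk * invgamma((nu0 - K + 1)/2)
        from scipy.stats import invgamma

        ks = kstest(draws, invgamma(a=(6 - 2 + 1) / 2, scale=0.5).cdf)
        assert ks.pvalue > 0.01


class TestUpdateRegression:
    def test_zero_proposal_scale_freezes_chain(self):
        counts = np.zeros((30, 1, 4), dtype=int)
        counts[:, 0, 0] = 1
        sampler = make_sampler(counts)
        state = sampler.init_state()
        state.s_beta[:] = -np.inf
        state.s_alpha[:] = -np.inf
        b0, a0 = state.beta[0].copy(), state.alpha[0].copy()
        rng = np.random.default_rng(12)
        for _ in range(50):
            sampler.update_regression(state, rng)
        np.testing.assert_array_equal(state.beta[0], b0)
        np.testing.assert_array_equal(state.alpha[0], a0)

    def test_posterior_covers_truth_two_species(self):
        cfg = SimulationConfig(n_locations=200, n_dates=2, K=2, J=4,
                               beta=[[1.0], [0.6]], alpha=[[0.0], [0.5]],
                               Sigma=0.3 * np.eye(2), seed=13)
        ds = simulate(cfg)
        I = cfg.I
        mc = McmcConfig(n_chains=2, n_iter=2500, n_burn=1000, thin=2, seed=14)
        samples = run_mcmc(ds.frequency_table.counts,
                           [np.ones((I, 1))] * 2, [np.ones((I, 1))] * 2, mc)
        for k, (bt, at) in enumerate([(1.0, 0.0), (0.6, 0.5)]):
            bd = samples.beta[k][..., 0].ravel()
            ad = samples.alpha[k][..., 0].ravel()
            assert abs(bd.mean() - bt) < 3 * bd.std() + 0.05
            assert abs(ad.mean() - at) < 3 * ad.std() + 0.05


class TestRunMcmc:
    def test_same_seed_identical_draws(self):
        cfg = SimulationConfig(n_locations=20, n_dates=2, K=2, J=4,
                               beta=[[0.8], [0.6]], alpha=[[0.0], [0.0]],
                               Sigma=0.4 * np.eye(2), seed=15)
        ds = simulate(cfg)
        sampler = CommunitySampler(ds.frequency_table.counts,
                                   [np.ones((40, 1))] * 2, [np.ones((40, 1))] * 2,
                                   McmcConfig(n_iter=300, n_burn=100, thin=1))
        a = sampler.run_chain(123)
        b = sampler.run_chain(123)
        np.testing.assert_array_equal(a["Sigma"], b["Sigma"])
        for k in range(2):
            np.testing.assert_array_equal(a["beta"][k], b["beta"][k])

    def test_single_species_lognormal_variance_recovery(self):
        s2_true = 0.8
        cfg = SimulationConfig(n_locations=300, n_dates=2, K=1, J=4,
                               beta=[[1.2]], alpha=[[0.0]],
                               Sigma=np.array([[s2_true]]), seed=16)
        ds = simulate(cfg)
        mc = McmcConfig(n_chains=2, n_iter=3000, n_burn=1500, thin=2, seed=17)
        samples = run_mcmc(ds.frequency_table.counts, [np.ones((600, 1))],
                           [np.ones((600, 1))], mc)
        s2 = samples.Sigma[..., 0, 0].ravel()
        lo, hi = np.quantile(s2, [0.025, 0.975])
        assert lo < s2_true < hi
        assert abs(s2.mean() - s2_true) < 0.3


class TestMarginalMoments:
    def test_poisson_limit(self):
        m, v, c = marginal_moments(0.0, 0.0, np.zeros((2, 2)))
        assert (m, v, c) == (1.0, 1.0, 0.0)

    def test_lognormal_inflation(self):
        s2 = np.log(2.0)
        m, v, _ = marginal_moments(0.0, 0.0, np.diag([s2, s2]))
        assert m == pytest.approx(np.sqrt(2))
        assert v == pytest.approx(np.sqrt(2) + 2)

    def test_perfect_correlation_covariance(self):
        s2 = np.log(2.0)
        S = np.array([[s2, s2], [s2, s2]])  # rho = 1
        _, _, c = marginal_moments(0.0, 0.0, S)
        assert c == pytest.approx(2.0)


class TestSummaries:
    def _samples_from_rho(self, rho_draws):
        """Wrap scalar correlation draws for a 2-species community."""
        n = len(rho_draws)
        Sigma = np.empty((1, n, 2, 2))
        Sigma[0, :, 0, 0] = Sigma[0, :, 1, 1] = 1.0
        Sigma[0, :, 0, 1] = Sigma[0, :, 1, 0] = rho_draws
        return PosteriorSamples(beta=[np.zeros((1, n, 1))] * 2,
                                alpha=[np.zeros((1, n, 1))] * 2,
                                Sigma=Sigma, N=None,
                                config=McmcConfig(n_iter=2, n_burn=1),
                                chain_seeds=[0])

    def test_constant_draws_degenerate(self):
        s = self._samples_from_rho(np.full(500, 0.4))
        out = summarize_correlations(s)
        assert out.loc[0, "mcse"] == 0.0
        assert out.loc[0, "ci_lo"] == out.loc[0, "ci_hi"] == pytest.approx(0.4)

    def test_iid_draw_mcse_is_sd_over_sqrt_n(self):
        rng = np.random.default_rng(18)
        d = rng.normal(0.5, 0.1, size=10000)
        s = self._samples_from_rho(np.clip(d, -1, 1))
        out = summarize_correlations(s)
        assert out.loc[0, "mcse"] == pytest.approx(0.001, rel=0.3)

    def test_draws_straddling_zero_not_significant(self):
        rng = np.random.default_rng(19)
        s = self._samples_from_rho(rng.normal(0.0, 0.2, size=2000).clip(-1, 1))
        out = summarize_correlations(s)
        assert not out.loc[0, "significant"]

    def test_batch_means_mcse_constant_zero(self):
        assert batch_means_mcse(np.ones(100)) == 0.0

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(20)
        n, K = 400, 3
        A = rng.normal(size=(n, K, K))
        Sigma = np.einsum("nij,nkj->nik", A, A) + 3 * np.eye(K)
        perm = [2, 0, 1]
        base = PosteriorSamples(beta=[np.zeros((1, n, 1))] * K,
                                alpha=[np.zeros((1, n, 1))] * K,
                                Sigma=Sigma[None], N=None,
                                config=McmcConfig(n_iter=2, n_burn=1),
                                chain_seeds=[0])
        permuted = PosteriorSamples(beta=[np.zeros((1, n, 1))] * K,
                                    alpha=[np.zeros((1, n, 1))] * K,
                                    Sigma=Sigma[None][:, :, perm][:, :, :, perm],
                                    N=None,
                                    config=McmcConfig(n_iter=2, n_burn=1),
                                    chain_seeds=[0])
        names = ["a", "b", "c"]
        t1 = summarize_correlations(base, species=names)
        t2 = summarize_correlations(permuted, species=[names[p] for p in perm])
        key = lambda df: df.assign(
            pair=[tuple(sorted(x)) for x in zip(df.species_a, df.species_b)]
        ).set_index("pair").sort_index()
        a, b = key(t1), key(t2)
        np.testing.assert_allclose(a["mean"].to_numpy(), b["mean"].to_numpy(),
                                   atol=1e-12)

    def test_stored_sigma_draws_positive_definite(self):
        cfg = SimulationConfig(n_locations=30, n_dates=2, K=2, J=4,
                               beta=[[0.8], [0.8]], alpha=[[0.0], [0.0]],
                               Sigma=0.5 * np.eye(2), seed=21)
        ds = simulate(cfg)
        mc = McmcConfig(n_chains=2, n_iter=400, n_burn=200, thin=2, seed=22)
        samples = run_mcmc(ds.frequency_table.counts, [np.ones((60, 1))] * 2,
                           [np.ones((60, 1))] * 2, mc)
        for S in samples.Sigma.reshape(-1, 2, 2):
            assert np.linalg.eigvalsh(S).min() > 0


class TestPriorRecovery:
    def test_sigma_posterior_matches_prior_without_data(self):
        # all species absent everywhere and detection forced off: the Sigma
        # chain must reproduce its inverse-Wishart prior
        K, I = 2, 50
        counts = np.zeros((I, K, 4), dtype=int)
        cfg = McmcConfig(n_iter=10, n_burn=2, nu0=K + 3)
        sampler = make_sampler(counts, cfg)
        state = sampler.init_state()
        state.N[:] = 0
        state.logit_p[:] = -30.0  # p ~ 0: observation layer carries no signal
        state.s_eps = 0.0
        rng = np.random.default_rng(23)
        diag = []
        for it in range(6000):
            sampler.update_N(state, rng)
            sampler.update_epsilon(state, rng)
            sampler.update_Sigma(state, rng)
            if it >= 1000 and it % 2 == 0:
                diag.append(state.Sigma[0, 0])
        # prior mean of Sigma_00 under IW(nu0, I): 1/(nu0 - K - 1) = 0.5
        assert np.mean(diag) == pytest.approx(0.5, abs=0.08)
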