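import numpy as np
import pytest
from scipy.special import ive

from ystrpopgen.markers import MarkerPanel
from ystrpopgen.synthetic_c3star import C3STAR_MARKERS, c3star_profiles
from ystrpopgen.tmrca import (
    CoalescentModelConfig,
    run_tmrca_mcmc,
    smm_branch_likelihood,
)

PANEL = MarkerPanel(
    C3STAR_MARKERS,
    {
        "DYS19": 2.2e-3,
        "DYS389I": 2.5e-3,
        "DYS389II": 3.6e-3,
        "DYS390": 2.1e-3,
        "DYS391": 2.6e-3,
        "DYS392": 4e-4,
        "DYS393": 1.1e-3,
        "DYS439": 5.1e-3,
    },
)


class TestSmmBranchLikelihood:
    def test_zero_branch_limits(self):
        assert smm_branch_likelihood(0, 0.0) == 1.0
        assert smm_branch_likelihood(3, 0.0) == 0.0
        assert smm_branch_likelihood(-2, 0.0) == 0.0

    def test_matches_monte_carlo_random_walk(self):
        """Direct Monte-Carlo of Poisson(0.5) +-1 steps vs the Bessel form."""
        lam, draws = 0.5, 1_000_000
        rng = np.random.default_rng(0)
        k = rng.poisson(lam, size=draws)
        net = 2 * rng.binomial(k, 0.5) - k
        for j in range(-6, 7):
            p_mc = np.mean(net == j)
            p = smm_branch_likelihood(j, lam)
            se = np.sqrt(max(p_mc, 1e-12) * (1 - p_mc) / draws)
            assert abs(p - p_mc) <= 3 * se + 1e-6, j

    def test_distribution_sums_to_one_with_tail_bound(self):
        lam = 2.0
        total = smm_branch_likelihood(0, lam) + 2 * sum(
            smm_branch_likelihood(k, lam) for k in range(1, 40)
        )
        assert total == pytest.approx(1.0, abs=1e-10)
        assert sum(smm_branch_likelihood(k, lam) for k in range(5)) <= 1.0

    def test_kernel_series_matches_scipy_bessel(self):
        from ystrpopgen._tmrca_kernels import _pk_vector

        for lam in (0.01, 0.7, 3.0, 15.0, 29.0):
            out = np.zeros(10)
            _pk_vector(lam, 10, out)
            ref = np.array([float(ive(k, lam)) for k in range(10)])
            assert out == pytest.approx(ref, rel=1e-10)


class TestMcmc:
    def test_reproducible_from_seed(self):
        cfg = CoalescentModelConfig(iterations=500, burn_in=100, seed=42)
        a = run_tmrca_mcmc(c3star_profiles(), cfg, PANEL, C3STAR_MARKERS)
        b = run_tmrca_mcmc(c3star_profiles(), cfg, PANEL, C3STAR_MARKERS)
        assert np.array_equal(a.draws["tmrca"], b.draws["tmrca"])
        assert np.array_equal(a.draws["N"], b.draws["N"])

    def test_prior_recovery_with_flat_likelihood(self):
        """With the likelihood switched off and N fixed, the TMRCA draws must
        recover the coalescent prior mean 2N(1 - 1/n) (detailed balance)."""
        n = 14
        N = 500.0
        cfg = CoalescentModelConfig(
            iterations=40_000, burn_in=5_000, seed=3,
            likelihood_on=False, fix_n=True, fix_mu=True, prior_n_mean=N,
        )
        post = run_tmrca_mcmc(c3star_profiles(), cfg, PANEL, C3STAR_MARKERS)
        draws = post.draws["tmrca"]
        expect = 2.0 * N * (1.0 - 1.0 / n)
        # batch-means standard error for the autocorrelated chain
        batches = draws.reshape(10, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(draws.mean() - expect) < max(4 * se, 0.1 * expect)

    def test_prior_recovery_of_population_size(self):
        """Likelihood off, N free: the N draws must recover the configured
        exponential prior mean."""
        cfg = CoalescentModelConfig(
            iterations=40_000, burn_in=5_000, seed=4,
            likelihood_on=False, fix_mu=True, prior_n_mean=800.0,
        )
        post = run_tmrca_mcmc(c3star_profiles(), cfg, PANEL, C3STAR_MARKERS)
        draws = post.draws["N"]
        batches = draws.reshape(10, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(draws.mean() - 800.0) < max(4 * se, 80.0)

    def test_matches_rejection_sampling_oracle(self):
        """n = 3, one marker: the MCMC posterior must agree with an
        independent importance-sampling oracle (trees from the coalescent
        prior, weighted by the SMM likelihood with explicit root-state
        enumeration)."""
        marker = ("M1",)
        panel = MarkerPanel(marker, {"M1": 5e-3})
        obs = np.array([16, 16, 18])
        N, mu, pad = 200.0, 5e-3, 5
        cfg = CoalescentModelConfig(
            iterations=40_000, burn_in=10_000, seed=5,
            fix_n=True, fix_mu=True, prior_n_mean=N, window_pad=pad,
        )
        profs = [{"M1": int(v)} for v in obs]
        post = run_tmrca_mcmc(profs, cfg, panel, marker)

        rng = np.random.default_rng(6)
        draws = 120_000
        t3 = rng.exponential(N / 3.0, size=draws)  # 3 lineages, rate 3/N
        t2 = t3 + rng.exponential(N, size=draws)  # 2 lineages, rate 1/N
        topo = rng.integers(3, size=draws)  # which pair coalesces first
        lo, hi = obs.min() - pad, obs.max() + pad
        states = np.arange(lo, hi + 1)
        W = len(states)

        def pk(lams, dmat):
            # (draws, W, W) transition probabilities; ive is the
            # exponentially scaled Bessel, i.e. already exp(-lam)*I_k(lam)
            return ive(dmat[None, :, :], lams[:, None, None])

        dmat = np.abs(states[:, None] - states[None, :]).astype(float)
        pairs = [(0, 1, 2), (0, 2, 1), (1, 2, 0)]
        like = np.zeros(draws)
        for tp, (a, b, c) in enumerate(pairs):
            sel = topo == tp
            if not sel.any():
                continue
            lam_leaf = mu * t3[sel]
            lam_third = mu * t2[sel]
            lam_anc = mu * (t2[sel] - t3[sel])
            ia, ib, ic = obs[a] - lo, obs[b] - lo, obs[c] - lo
            p_inner = pk(lam_leaf, dmat)  # inner node -> leaf a, b
            inner = p_inner[:, :, ia] * p_inner[:, :, ib]  # (sel, W)
            p_anc = pk(lam_anc, dmat)
            root_to_inner = np.einsum("dsw,dw->ds", p_anc, inner)
            p_c = pk(lam_third, dmat)[:, :, ic]
            like[sel] = (root_to_inner * p_c).mean(axis=1)  # uniform root state
        w = like / like.sum()
        order = np.argsort(t2)
        cdf = np.cumsum(w[order])
        oracle_med = t2[order][np.searchsorted(cdf, 0.5)]
        oracle_q1 = t2[order][np.searchsorted(cdf, 0.25)]
        oracle_q3 = t2[order][np.searchsorted(cdf, 0.75)]
        assert post.median == pytest.approx(oracle_med, rel=0.10)
        assert post.q1 == pytest.approx(oracle_q1, rel=0.15)
        assert post.q3 == pytest.approx(oracle_q3, rel=0.15)

    def test_tenfold_rates_shrink_tmrca(self):
        fast = MarkerPanel(
            C3STAR_MARKERS, {m: min(10 * r, 0.049) for m, r in PANEL.mutation_rate.items()}
        )
        cfg = CoalescentModelConfig(iterations=6000, burn_in=3000, seed=7)
        slow_post = run_tmrca_mcmc(c3star_profiles(), cfg, PANEL, C3STAR_MARKERS)
        fast_post = run_tmrca_mcmc(c3star_profiles(), cfg, fast, C3STAR_MARKERS)
        assert fast_post.median < slow_post.median
        assert (slow_post.draws["tmrca"] > 0).all()

    def test_two_identical_haplotypes_prior_dominated(self):
        """n = 2 with a negligible mutation rate: the posterior TMRCA matches
        the prior pairwise coalescent expectation N."""
        panel = MarkerPanel(("M1",), {"M1": 1e-8})
        cfg = CoalescentModelConfig(
            iterations=30_000, burn_in=5_000, seed=8, fix_n=True, fix_mu=True,
            prior_n_mean=300.0,
        )
        post = run_tmrca_mcmc([{"M1": 14}, {"M1": 14}], cfg, panel, ("M1",))
        draws = post.draws["tmrca"]
        batches = draws.reshape(10, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(10)
        assert abs(draws.mean() - 300.0) < max(4 * se, 45.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CoalescentModelConfig(model=1)
        with pytest.raises(ValueError):
            CoalescentModelConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            CoalescentModelConfig(prior_n_mean=-5.0)
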