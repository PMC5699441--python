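"""Checks of the posterior machinery against independent oracles."""

import math

import numpy as np
import pytest
import scipy.stats as st
from scipy import integrate
from scipy.optimize import minimize_scalar

from crmgraph import (
    GGPParams,
    GraphData,
    MCMCConfig,
    MCMCState,
    grad_log_conditional_weights,
    hmc_update,
    hyper_log_accept_ratio,
    log_conditional_weights,
    mh_update_hyper,
    run_chains,
    sample_latent_counts,
    sample_ztpoisson,
    simulate_ggp_graph,
)
from crmgraph.inference import initialize_state


def brute_log_conditional(omega, m, sigma, tau, w_star):
    """Direct evaluation of the weight conditional from its defining form:
    prod w^m * rho(w) * jacobian(w->omega), times exp(-(sum w + w*)^2).
    Includes the phi-dependent constants the implementation drops."""
    w = np.exp(omega)
    dens = (
        m * np.log(w)
        + (-1 - sigma) * np.log(w)
        - tau * w
        - math.lgamma(1 - sigma)
        + np.log(w)  # d w / d omega
    )
    return float(dens.sum() - (w.sum() + w_star) ** 2)


class TestWeightConditional:
    def test_single_node_maximizer(self):
        """m=2, sigma=0, tau=1: mode solves 2 - w - 2w^2 = 0."""
        res = minimize_scalar(
            lambda om: -log_conditional_weights(
                np.array([om]), np.array([2]), 0.0, 1.0, 0.0
            ),
            bounds=(-5, 2),
            method="bounded",
        )
        assert math.exp(res.x) == pytest.approx((-1 + math.sqrt(17)) / 4, rel=1e-4)

    def test_linear_in_degree_shift(self, rng):
        omega = rng.normal(size=6)
        m = rng.integers(1, 5, size=6)
        base = log_conditional_weights(omega, m, 0.3, 1.0, 0.5)
        shifted = log_conditional_weights(omega, m + 3, 0.3, 1.0, 0.5)
        assert shifted - base == pytest.approx(3 * omega.sum(), rel=1e-12)

    def test_matches_brute_force_up_to_constant(self, rng):
        """Differences between states agree with the defining-formula oracle."""
        for _ in range(100):
            n = int(rng.integers(1, 8))
            m = rng.integers(1, 6, size=n)
            sigma = float(rng.uniform(-1, 0.9))
            tau = float(rng.uniform(0.1, 3))
            ws = float(rng.uniform(0, 2))
            om1, om2 = rng.normal(size=n), rng.normal(size=n)
            mine = log_conditional_weights(om1, m, sigma, tau, ws) - (
                log_conditional_weights(om2, m, sigma, tau, ws)
            )
            brute = brute_log_conditional(om1, m, sigma, tau, ws) - (
                brute_log_conditional(om2, m, sigma, tau, ws)
            )
            assert mine == pytest.approx(brute, abs=1e-10 * max(1, abs(brute)))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            log_conditional_weights(np.array([np.inf]), np.array([1]), 0.0, 1.0, 0.0)


class TestGradient:
    def test_printed_example(self):
        g = grad_log_conditional_weights(np.array([0.0]), np.array([2]), 0.5, 1.0, 0.0)
        assert g[0] == pytest.approx(-1.5, rel=1e-12)

    def test_small_weight_limit(self):
        g = grad_log_conditional_weights(
            np.array([-40.0]), np.array([1]), 0.5, 1.0, 0.0
        )
        assert g[0] == pytest.approx(1 - 0.5, rel=1e-6)

    def test_finite_differences(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 10))
            omega = rng.normal(size=n)
            m = rng.integers(1, 6, size=n)
            sigma = float(rng.uniform(-1, 0.9))
            tau = float(rng.uniform(0.1, 3))
            ws = float(rng.uniform(0, 2))
            g = grad_log_conditional_weights(omega, m, sigma, tau, ws)
            eps = 1e-6
            for i in range(n):
                e = np.zeros(n)
                e[i] = eps
                fd = (
                    log_conditional_weights(omega + e, m, sigma, tau, ws)
                    - log_conditional_weights(omega - e, m, sigma, tau, ws)
                ) / (2 * eps)
                assert fd == pytest.approx(g[i], rel=1e-5, abs=1e-5)


def _make_state(omega, m, sigma=0.5, tau=1.0, w_star=0.2):
    return MCMCState(
        omega=np.asarray(omega, dtype=float),
        w_star=w_star,
        alpha=5.0,
        sigma=sigma,
        tau=tau,
        nbar=np.empty(0, dtype=np.int64),
        m=np.asarray(m, dtype=np.int64),
    )


class TestHMC:
    def test_zero_step_size_is_identity(self, rng):
        state = _make_state([0.1, -0.2], [2, 1])
        new, accepted, prob = hmc_update(state, 0.0, 5, rng)
        assert prob == 1.0 and accepted
        assert np.array_equal(new.omega, state.omega)

    def test_energy_error_decreases_with_step_size(self):
        state = _make_state([0.1, -0.2, 0.4], [2, 1, 3])
        errors = []
        for eps in [0.4, 0.2, 0.1, 0.05]:
            # average |Delta H| over momenta with a fixed seed per step size
            rng = np.random.default_rng(0)
            rejections = 0
            probs = []
            for _ in range(200):
                _, _, p = hmc_update(state, eps, 10, rng)
                probs.append(p)
            errors.append(1 - np.mean(probs))
        assert errors[0] > errors[-1]
        assert errors[-1] < 0.05

    def test_long_run_matches_reference_sampler(self, rng):
        """3-node conditional: HMC vs an independent random-walk Metropolis."""
        m = np.array([3, 1, 2])
        sigma, tau, ws = 0.3, 1.0, 0.1
        # reference: random-walk Metropolis on omega
        om = np.zeros(3)
        lp = log_conditional_weights(om, m, sigma, tau, ws)
        ref = []
        for _ in range(60_000):
            prop = om + 0.6 * rng.normal(size=3)
            lp_prop = log_conditional_weights(prop, m, sigma, tau, ws)
            if math.log(rng.random() + 1e-300) < lp_prop - lp:
                om, lp = prop, lp_prop
            ref.append(np.exp(om))
        ref = np.asarray(ref[10_000:])
        # HMC chain
        state = _make_state(np.zeros(3), m, sigma, tau, ws)
        hmc = []
        for _ in range(30_000):
            state, _, _ = hmc_update(state, 0.25, 5, rng)
            hmc.append(np.exp(state.omega))
        hmc = np.asarray(hmc[5_000:])
        for i in range(3):
            # batch-means standard errors to absorb autocorrelation
            se_ref = ref[:, i].reshape(50, -1).mean(axis=1).std() / math.sqrt(50)
            se_hmc = hmc[:, i].reshape(50, -1).mean(axis=1).std() / math.sqrt(50)
            tol = 4 * math.hypot(se_ref, se_hmc)
            assert hmc[:, i].mean() == pytest.approx(ref[:, i].mean(), abs=tol)


class TestLatentCounts:
    def test_ztp_mean_at_one(self, rng):
        d = sample_ztpoisson(np.full(100_000, 1.0), rng)
        se = d.std() / math.sqrt(d.size)
        assert d.mean() == pytest.approx(1.0 / (-math.expm1(-1.0)), abs=4 * se)

    def test_ztp_small_rate_is_one(self, rng):
        d = sample_ztpoisson(np.full(50_000, 1e-5), rng)
        assert d.min() >= 1
        assert d.mean() == pytest.approx(1.0, abs=1e-3)

    def test_ztp_large_rate(self, rng):
        d = sample_ztpoisson(np.full(50_000, 20.0), rng)
        se = d.std() / math.sqrt(d.size)
        assert d.min() >= 1
        assert d.mean() == pytest.approx(20.0, abs=4 * se)

    def test_absent_edges_stay_zero(self, rng):
        """Degrees accumulate only over the observed edge list."""
        w = np.array([0.5, 0.5, 0.5])
        edges = np.array([[0, 1]])  # node 2 has no edges
        nbar, m = sample_latent_counts(w, edges, rng)
        assert m[2] == 0
        assert m[0] == m[1] == nbar[0]

    def test_self_loop_counts_twice(self, rng):
        w = np.array([1.0])
        edges = np.array([[0, 0]])
        nbar, m = sample_latent_counts(w, edges, rng)
        assert m[0] == 2 * nbar[0]


class TestHyperBlock:
    def test_identity_proposal_ratio_zero(self):
        cur = (5.0, 0.3, 1.0, 0.4)
        assert hyper_log_accept_ratio(cur, cur, 2.0, -1.0, 7) == pytest.approx(0.0)

    def test_ratio_matches_gamma_closed_form(self, rng):
        """sigma=0: total-mass law is gamma, so the full joint ratio (target
        times proposal correction) is available in closed form."""

        def brute(cur, prop, s_total, sum_om, n):
            def logpi(a, s, t, w):
                lp = n * math.log(a) - s * sum_om - t * s_total
                lp -= n * math.lgamma(1 - s)
                lp += -w * w - 2 * s_total * w
                lp += st.gamma.logpdf(w, a, scale=1 / t)
                return lp

            def logq(a, s, t, w, w_from):
                # tilted-by-(2S + 2 w_from) gamma total-mass proposal
                return st.gamma.logpdf(
                    w, a, scale=1 / (t + 2 * s_total + 2 * w_from)
                )

            fwd = logq(*prop, w_from=cur[3])
            rev = logq(*cur, w_from=prop[3])
            return (logpi(*prop) - logpi(*cur)) + (rev - fwd)

        for _ in range(20):
            n = int(rng.integers(2, 30))
            s_total = float(rng.uniform(0.5, 5))
            sum_om = float(rng.normal() * n)
            cur = (rng.uniform(1, 20), 0.0, rng.uniform(0.5, 3), rng.uniform(0.01, 2))
            prop = (rng.uniform(1, 20), 0.0, rng.uniform(0.5, 3), rng.uniform(0.01, 2))
            mine = hyper_log_accept_ratio(cur, prop, s_total, sum_om, n)
            assert mine == pytest.approx(brute(cur, prop, s_total, sum_om, n), abs=1e-8)

    def test_wstar_block_invariant_vs_quadrature(self, rng):
        """With rw_sd=0 the block is a pure w* move whose equilibrium at
        sigma=0 is exp(-w^2-2Sw) gamma(w; alpha, tau), checked by quadrature."""
        m = np.array([2, 1, 1])
        omega = np.log(np.array([0.4, 0.2, 0.3]))
        state = MCMCState(omega, 0.5, 4.0, 0.0, 1.0, np.empty(0, np.int64), m)
        cfg = MCMCConfig(n_iter=10, rw_sd=0.0)
        s_total = float(np.exp(omega).sum())
        draws = []
        for _ in range(20_000):
            state, _ = mh_update_hyper(state, cfg, rng)
            draws.append(state.w_star)
        draws = np.asarray(draws[2_000:])

        dens = lambda w: math.exp(
            -w * w - 2 * s_total * w + st.gamma.logpdf(w, 4.0, scale=1.0)
        )
        z0, _ = integrate.quad(dens, 0, 50)
        mean_ref, _ = integrate.quad(lambda w: w * dens(w) / z0, 0, 50)
        se = draws.reshape(50, -1).mean(axis=1).std() / math.sqrt(50)
        assert draws.mean() == pytest.approx(mean_ref, abs=4 * se)

    def test_invalid_region_auto_rejects(self, rng):
        # force sigma' < 0 with tau' -> 0 impossible through log walks, so
        # instead check the stable-boundary guard: sigma>=0, tau=0 proposals
        # can only arise from tau=0 states, which require_finite_mean rejects
        state = _make_state([0.0], [1], sigma=0.5, tau=1.0)
        cfg = MCMCConfig(n_iter=10, rw_sd=0.05)
        out, _ = mh_update_hyper(state, cfg, rng)
        assert out.tau > 0 and out.sigma < 1


class TestRunChains:
    def test_smoke_small_graph(self, rng):
        g, _ = simulate_ggp_graph(GGPParams(8.0, 0.0, 1.0), seed=rng)
        data = GraphData.from_graph(g)
        cfg = MCMCConfig(n_iter=1000, n_burnin=200, store_weights=True)
        import time

        t0 = time.time()
        post = run_chains(data, cfg, n_chains=2, seed=3)
        assert time.time() - t0 < 60
        for name in ["alpha", "sigma", "tau", "w_star", "logcond"]:
            assert np.all(np.isfinite(getattr(post, name)))
        assert post.weights.shape == (2, 800, data.n_nodes)
        assert np.all(post.weights > 0)
        assert set(post.psrf) == {"omega", "w_star", "alpha", "sigma", "tau"}

    def test_reproducible(self):
        g, _ = simulate_ggp_graph(GGPParams(6.0, 0.0, 1.0), seed=11)
        data = GraphData.from_graph(g)
        cfg = MCMCConfig(n_iter=200, n_burnin=50)
        a = run_chains(data, cfg, n_chains=1, seed=5)
        b = run_chains(data, cfg, n_chains=1, seed=5)
        assert np.array_equal(a.sigma, b.sigma)

    def test_single_self_loop_graph_accepted(self):
        data = GraphData.from_edges(np.array([[0, 0]]), n_nodes=1)
        cfg = MCMCConfig(n_iter=300, n_burnin=50)
        post = run_chains(data, cfg, n_chains=1, seed=2)
        assert np.all(np.isfinite(post.sigma))

    def test_empty_graph_rejected(self):
        from scipy import sparse

        with pytest.raises(ValueError):
            GraphData(sparse.csr_matrix((4, 4), dtype=np.int8))


class TestInitialization:
    def test_alpha_matches_expected_nodes(self):
        g, s = simulate_ggp_graph(GGPParams(30.0, 0.5, 1.0), seed=4)
        data = GraphData.from_graph(g)
        state = initialize_state(data, np.random.default_rng(0))
        from crmgraph import GGPModel, expected_counts

        e_nodes = expected_counts(
            GGPModel(GGPParams(state.alpha, state.sigma, state.tau))
        )[2]
        assert e_nodes == pytest.approx(data.n_nodes, rel=1e-3)

    def test_weight_scale(self):
        data = GraphData.from_edges(np.array([[0, 1], [1, 2]]))
        state = initialize_state(data, np.random.default_rng(0))
        m = np.array([1, 2, 1])
        expect = np.sqrt(m) / math.sqrt(2 * m.sum())
        assert np.allclose(state.weights, expect)
        assert state.w_star == pytest.approx(expect.mean())
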