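"""Posterior inference for GGP graphs: HMC-within-Gibbs with latent counts.

Given an observed undirected graph ``z`` over the N_alpha nodes of degree
at least one, the posterior over node sociabilities ``w_1..w_N``, the
remainder mass ``w*`` (total sociability of unobserved nodes) and the
hyperparameters ``phi = (alpha, sigma, tau)`` is explored by a
three-block Gibbs sampler:

1. **weights** — Hamiltonian Monte Carlo on ``omega_i = log w_i`` whose
   target is the multigraph conditional
   ``prod_i w_i^{m_i} rho(w_i) * exp(-(sum_i w_i + w*)^2)``,
   with ``m_i`` the multigraph degrees implied by the latent counts;
2. **hyperparameters and w*** — a joint Metropolis–Hastings move: Gaussian
   random walks on ``(log alpha, log(1-sigma), log tau)`` and an exact
   proposal for ``w*`` from the exponentially tilted total-mass law (tilt
   ``2S + 2 w*`` with ``S = sum_i w_i``, i.e. the GGP total-mass law with
   ``tau`` shifted by that amount).  The tilt makes the intractable
   total-mass density cancel from the acceptance ratio, and its
   ``2 w*`` component matches the target's ``exp(-w*^2)`` factor to first
   order so the move is rarely rejected on account of ``w*``;
3. **latent counts** — for every observed edge, a zero-truncated Poisson
   draw ``nbar_ij ~ tPoisson(2 w_i w_j)`` (``tPoisson(w_i^2)`` on the
   diagonal); absent edges are pinned at zero.

Improper priors ``p(alpha) ∝ 1/alpha``, ``p(sigma) ∝ 1/(1-sigma)``,
``p(tau) ∝ 1/tau`` are used; on the random-walk scales they cancel exactly
with the change-of-variable Jacobians, so the prior contributes nothing to
the acceptance ratio.  Posterior propriety is assumed, not checked.

Degrees convention: a diagonal latent count contributes twice to its node's
degree, ``m_i = sum_{j != i} nbar_ij + 2 nbar_ii``, which makes the weight
exponent in the conditional match the Poisson-process likelihood.

The per-iteration cost is O(L N_alpha + N_alpha^(e)) for L leapfrog steps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .levy import GGPModel, GGPParams, _is_zero_sigma
from .samplers import as_rng, sample_total_mass

logger = logging.getLogger("crmgraph")

__all__ = [
    "GraphData",
    "MCMCConfig",
    "MCMCState",
    "PosteriorSamples",
    "log_conditional_weights",
    "grad_log_conditional_weights",
    "hmc_update",
    "sample_ztpoisson",
    "sample_latent_counts",
    "hyper_log_accept_ratio",
    "mh_update_hyper",
    "initialize_state",
    "run_chains",
]


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------


@dataclass
class GraphData:
    """Observed undirected graph restricted to nodes of degree >= 1."""

    adjacency: sparse.csr_matrix
    edges: np.ndarray = None  # (E, 2) unordered pairs i <= j, incl. diagonal
    node_index: np.ndarray = None  # mapping back to the input labelling

    def __post_init__(self) -> None:
        adj = sparse.csr_matrix(self.adjacency)
        adj.data = np.minimum(adj.data, 1).astype(np.int8)
        adj.eliminate_zeros()
        if (adj != adj.T).nnz:
            raise ValueError("adjacency must be symmetric")
        deg = np.asarray(adj.sum(axis=1)).ravel()
        keep = np.nonzero(deg > 0)[0]
        if keep.size == 0:
            raise ValueError(
                "empty graph: posterior inference requires at least one edge"
            )
        if self.node_index is None:
            self.node_index = np.arange(adj.shape[0])
        if keep.size < adj.shape[0]:
            adj = adj[keep][:, keep]
            self.node_index = np.asarray(self.node_index)[keep]
        self.adjacency = adj
        coo = sparse.triu(adj).tocoo()
        order = np.lexsort((coo.col, coo.row))
        self.edges = np.column_stack([coo.row[order], coo.col[order]]).astype(
            np.int64
        )

    @classmethod
    def from_graph(cls, graph) -> "GraphData":
        return cls(graph.adjacency)

    @classmethod
    def from_edges(cls, edges, n_nodes: int | None = None) -> "GraphData":
        edges = np.asarray(edges, dtype=np.int64)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise ValueError("edges must be an (E, 2) integer array")
        if n_nodes is None:
            n_nodes = int(edges.max()) + 1 if edges.size else 0
        i, j = edges[:, 0], edges[:, 1]
        adj = sparse.coo_matrix(
            (np.ones(2 * len(edges), dtype=np.int8), (np.r_[i, j], np.r_[j, i])),
            shape=(n_nodes, n_nodes),
        ).tocsr()
        return cls(adj)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``rw_sd`` is the common standard deviation of the Gaussian random walks
    on (log alpha, log(1-sigma), log tau); the leapfrog step size is adapted
    toward ``hmc_target_accept`` during the first ``adapt_frac`` of the run
    and frozen afterwards (preserving detailed balance for the kept draws).
    """

    n_iter: int = 10000
    n_burnin: int | None = None  # default: n_iter // 4
    leapfrog_steps: int = 10
    hmc_target_accept: float = 0.6
    rw_sd: float = 0.02
    adapt_frac: float = 0.25
    thinning: int = 1
    initial_step_size: float = 0.01
    hyper_mh_steps: int = 6  # MH refreshes of the (phi, w*) block per sweep
    store_weights: bool = False
    log_every: int = 0  # 0 disables periodic acceptance logging

    def __post_init__(self) -> None:
        if self.n_burnin is None:
            self.n_burnin = self.n_iter // 4
        if not (self.n_iter > 0 and 0 <= self.n_burnin < self.n_iter):
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.thinning < 1 or self.leapfrog_steps < 1:
            raise ValueError("thinning and leapfrog_steps must be >= 1")
        if not 0 < self.hmc_target_accept < 1:
            raise ValueError("hmc_target_accept must lie in (0, 1)")

    @property
    def n_adapt(self) -> int:
        return int(self.adapt_frac * self.n_iter)


@dataclass
class MCMCState:
    """Current sampler state for one chain."""

    omega: np.ndarray  # log weights, length N
    w_star: float
    alpha: float
    sigma: float
    tau: float
    nbar: np.ndarray  # latent counts per observed edge (aligned with data.edges)
    m: np.ndarray  # multigraph degrees implied by nbar

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.omega)

    @property
    def params(self) -> GGPParams:
        return GGPParams(self.alpha, self.sigma, self.tau)


@dataclass
class PosteriorSamples:
    """Stacked post-burn-in draws from one or more chains."""

    alpha: np.ndarray  # (chains, kept)
    sigma: np.ndarray
    tau: np.ndarray
    w_star: np.ndarray
    logcond: np.ndarray  # weight-conditional log density per kept draw
    hmc_accept_rate: np.ndarray  # per chain, post-adaptation
    hyper_accept_rate: np.ndarray  # per chain
    step_size: np.ndarray  # per chain, frozen value
    psrf: dict = field(default_factory=dict)  # per-parameter split-PSRF
    weights: np.ndarray | None = None  # (chains, kept, N) if stored

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_kept(self) -> int:
        return self.alpha.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        return getattr(self, name).ravel()

    @property
    def psrf_max(self) -> float:
        return max(self.psrf.values()) if self.psrf else math.nan


# --------------------------------------------------------------------------
# weight conditional (Theorem-6 form, GGP Lévy density substituted)
# --------------------------------------------------------------------------


def log_conditional_weights(
    omega: np.ndarray, m: np.ndarray, sigma: float, tau: float, w_star: float
) -> float:
    """Unnormalized log density of log-weights given degrees and the rest.

    sum_i [(m_i - sigma) omega_i - tau e^{omega_i}] - (sum_i e^{omega_i} + w*)^2

    (log-scale Jacobian included; phi-dependent constants dropped).
    """
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("non-finite log-weights")
    w = np.exp(omega)
    s = w.sum()
    return float(((m - sigma) * omega - tau * w).sum() - (s + w_star) ** 2)


def grad_log_conditional_weights(
    omega: np.ndarray, m: np.ndarray, sigma: float, tau: float, w_star: float
) -> np.ndarray:
    """Gradient in omega: m_i - sigma - w_i (tau + 2 sum_j w_j + 2 w*)."""
    w = np.exp(np.asarray(omega, dtype=float))
    total = w.sum()
    return m - sigma - w * (tau + 2.0 * total + 2.0 * w_star)


def hmc_update(
    state: MCMCState, step_size: float, n_leapfrog: int, rng, inv_mass=None
) -> tuple[MCMCState, bool, float]:
    """One HMC move on the log-weights; returns (state, accepted, accept_prob).

    ``inv_mass`` is an optional per-coordinate inverse mass (posterior
    variance scale); identity by default.
    """
    rng = as_rng(rng)
    omega0 = state.omega
    m, sigma, tau, w_star = state.m, state.sigma, state.tau, state.w_star
    if inv_mass is None:
        inv_mass = np.ones(omega0.size)
    sqrt_mass = 1.0 / np.sqrt(inv_mass)
    p0 = sqrt_mass * rng.normal(size=omega0.size)
    logp0 = log_conditional_weights(omega0, m, sigma, tau, w_star)
    h0 = -logp0 + 0.5 * float(p0 @ (inv_mass * p0))

    omega = omega0.copy()
    p = p0.copy()
    with np.errstate(over="ignore", invalid="ignore"):
        p = p + 0.5 * step_size * grad_log_conditional_weights(
            omega, m, sigma, tau, w_star
        )
        for step in range(n_leapfrog):
            omega = omega + step_size * (inv_mass * p)
            g = grad_log_conditional_weights(omega, m, sigma, tau, w_star)
            if not np.all(np.isfinite(g)):
                return state, False, 0.0
            p = p + (step_size if step < n_leapfrog - 1 else 0.5 * step_size) * g
    if not np.all(np.isfinite(omega)):
        return state, False, 0.0
    logp1 = log_conditional_weights(omega, m, sigma, tau, w_star)
    h1 = -logp1 + 0.5 * float(p @ (inv_mass * p))
    if not math.isfinite(h1):
        return state, False, 0.0
    accept_prob = min(1.0, math.exp(min(0.0, h0 - h1)))
    if rng.random() < accept_prob:
        new = MCMCState(
            omega, state.w_star, state.alpha, state.sigma, state.tau, state.nbar, state.m
        )
        return new, True, accept_prob
    return state, False, accept_prob


# --------------------------------------------------------------------------
# latent counts
# --------------------------------------------------------------------------


def sample_ztpoisson(lam, rng) -> np.ndarray:
    """Vectorized zero-truncated Poisson draws, exact for any rate > 0.

    Small rates use sequential inversion of the truncated CDF; large rates
    (lam > 12) use plain Poisson draws with zero-rejection (the zero
    probability is below e^-12).
    """
    rng = as_rng(rng)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("zero-truncated Poisson requires a positive rate")
    out = np.ones(lam.shape, dtype=np.int64)
    big = lam > 12.0
    if np.any(big):
        lb = lam[big]
        draws = rng.poisson(lb)
        while True:
            zero = draws == 0
            if not np.any(zero):
                break
            draws[zero] = rng.poisson(lb[zero])
        out[big] = draws
    small = ~big
    if np.any(small):
        ls = lam[small]
        # u uniform on (P(K=0), 1); invert the untruncated CDF from k=1
        u = np.exp(-ls) + rng.random(ls.shape) * (-np.expm1(-ls))
        k = np.ones(ls.shape, dtype=np.int64)
        term = np.exp(-ls) * ls  # P(K=1)
        cdf = np.exp(-ls) + term
        active = u > cdf
        while np.any(active):
            k[active] += 1
            term = term * ls / k
            cdf = cdf + term * active
            active = u > cdf
        out[small] = k
    return out


def sample_latent_counts(
    weights: np.ndarray, edges: np.ndarray, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Draw nbar for every observed edge and recompute degrees m.

    nbar_ij ~ tPoisson(2 w_i w_j) for i < j, nbar_ii ~ tPoisson(w_i^2);
    m_i = sum_{j != i} nbar_ij + 2 nbar_ii.
    """
    rng = as_rng(rng)
    i, j = edges[:, 0], edges[:, 1]
    lam = np.where(i == j, weights[i] ** 2, 2.0 * weights[i] * weights[j])
    nbar = sample_ztpoisson(lam, rng)
    m = np.zeros(weights.size, dtype=np.int64)
    np.add.at(m, i, nbar)
    np.add.at(m, j, nbar)  # i == j adds twice: the diagonal convention
    return nbar, m


# --------------------------------------------------------------------------
# hyperparameter / remainder-mass block
# --------------------------------------------------------------------------


def hyper_log_accept_ratio(
    cur: tuple[float, float, float, float],
    prop: tuple[float, float, float, float],
    s_total: float,
    sum_omega: float,
    n_nodes: int,
) -> float:
    """Log MH ratio for the joint (alpha, sigma, tau, w*) move.

    ``cur``/``prop`` are (alpha, sigma, tau, w_star); ``s_total`` is
    S = sum_i w_i and ``sum_omega`` = sum_i log w_i.  The proposal draws
    w*' from the total-mass law under the proposed hyperparameters,
    exponentially tilted by ``2S + 2 w*_cur`` — the tilt makes the
    intractable total-mass density cancel, and the extra ``2 w*_cur``
    linearizes the target's exp(-w*^2) factor around the current value so
    the w*-part of the move accepts with high probability:

    log r = N log(alpha'/alpha)
          + (sigma - sigma') sum_omega - (tau' - tau) S
          + N [lgamma(1-sigma) - lgamma(1-sigma')]
          + (w*^2 - w*'^2)
          + alpha  psi_{sigma,tau}  (2S + 2 w*')
          - alpha' psi_{sigma',tau'}(2S + 2 w*)

    (the psi terms are the log normalizers of the forward and reverse tilted
    proposals).  Priors p(alpha) ∝ 1/alpha, p(sigma) ∝ 1/(1-sigma),
    p(tau) ∝ 1/tau cancel exactly with the log-scale random-walk Jacobians.
    """
    a0, s0, t0, w0 = cur
    a1, s1, t1, w1 = prop
    psi0 = GGPModel(GGPParams(1.0, s0, t0)).laplace_exponent(
        2.0 * s_total + 2.0 * w1
    )
    psi1 = GGPModel(GGPParams(1.0, s1, t1)).laplace_exponent(
        2.0 * s_total + 2.0 * w0
    )
    return (
        n_nodes * (math.log(a1) - math.log(a0))
        + (s0 - s1) * sum_omega
        - (t1 - t0) * s_total
        + n_nodes * (math.lgamma(1.0 - s0) - math.lgamma(1.0 - s1))
        + (w0 * w0 - w1 * w1)
        + a0 * psi0
        - a1 * psi1
    )


def mh_update_hyper(
    state: MCMCState, config: MCMCConfig, rng
) -> tuple[MCMCState, bool]:
    """Joint Metropolis–Hastings update of (alpha, sigma, tau, w*)."""
    rng = as_rng(rng)
    sd = config.rw_sd
    alpha1 = state.alpha * math.exp(sd * rng.normal())
    sigma1 = 1.0 - (1.0 - state.sigma) * math.exp(sd * rng.normal())
    tau1 = state.tau * math.exp(sd * rng.normal())
    if _is_zero_sigma(sigma1):
        sigma1 = 0.0
    try:
        prop_params = GGPParams(alpha1, sigma1, tau1)
        prop_params.require_finite_mean()
    except ValueError:
        return state, False  # outside the admissible region: auto-reject
    w = state.weights
    s_total = float(w.sum())
    sum_omega = float(state.omega.sum())
    # exact draw from the (2S + 2 w*)-tilted total-mass law under the
    # proposed hyperparameters (see hyper_log_accept_ratio)
    tilted = GGPParams(
        alpha1, sigma1, tau1 + 2.0 * s_total + 2.0 * state.w_star
    )
    w_star1 = sample_total_mass(tilted, rng)
    logr = hyper_log_accept_ratio(
        (state.alpha, state.sigma, state.tau, state.w_star),
        (alpha1, sigma1, tau1, w_star1),
        s_total,
        sum_omega,
        state.omega.size,
    )
    if math.log(rng.random() + 1e-300) < logr:
        return (
            MCMCState(state.omega, w_star1, alpha1, sigma1, tau1, state.nbar, state.m),
            True,
        )
    return state, False


# --------------------------------------------------------------------------
# initialization and the full sampler
# --------------------------------------------------------------------------


def initialize_state(
    data: GraphData,
    rng,
    sigma0: float | None = None,
    tau0: float = 1.0,
    jitter: float = 0.0,
) -> MCMCState:
    """Order-of-magnitude starting point.

    sigma0 defaults to 0.2; alpha0 solves the expected-node-count identity
    E[N_alpha] = N_obs under (sigma0, tau0); initial weights are
    w_i = sqrt(m_i) / sqrt(2 sum_j m_j) with m from nbar = z, and
    w* starts at their mean.  ``jitter`` adds chain-dispersing noise on the
    log/logit scales.
    """
    rng = as_rng(rng)
    if sigma0 is None:
        sigma0 = 0.2
    if jitter > 0:
        sigma0 = 1.0 - (1.0 - sigma0) * math.exp(jitter * rng.normal())
        sigma0 = float(np.clip(sigma0, -0.8, 0.8))
        tau0 = tau0 * math.exp(jitter * rng.normal())
    alpha0 = _solve_alpha_for_nodes(data.n_nodes, sigma0, tau0)
    if jitter > 0:
        alpha0 *= math.exp(jitter * rng.normal())
    nbar = np.ones(data.n_edges, dtype=np.int64)
    i, j = data.edges[:, 0], data.edges[:, 1]
    m = np.zeros(data.n_nodes, dtype=np.int64)
    np.add.at(m, i, nbar)
    np.add.at(m, j, nbar)
    w0 = np.sqrt(m) / math.sqrt(2.0 * m.sum())
    state = MCMCState(
        omega=np.log(w0),
        w_star=float(w0.mean()),
        alpha=alpha0,
        sigma=sigma0,
        tau=tau0,
        nbar=nbar,
        m=m,
    )
    return state


def _solve_alpha_for_nodes(n_obs: int, sigma: float, tau: float) -> float:
    """alpha such that the expected observed-node count matches n_obs."""
    from scipy import optimize

    def f(log_alpha: float) -> float:
        model = GGPModel(GGPParams(math.exp(log_alpha), sigma, tau))
        return model.expected_counts()[2] - n_obs

    lo, hi = math.log(1e-3), math.log(1e8)
    try:
        return math.exp(optimize.brentq(f, lo, hi, rtol=1e-6))
    except ValueError:
        return float(n_obs)  # fall back to a linear guess


class _SplitAccumulator:
    """Streaming mean/variance of each half of the kept draws, per parameter.

    Avoids storing full weight trajectories: the split-chain PSRF only needs
    per-half counts, sums and sums of squares.
    """

    def __init__(self, n_params: int, n_kept: int):
        self.half = max(n_kept // 2, 1)
        self.count = np.zeros(2)
        self.s1 = np.zeros((2, n_params))
        self.s2 = np.zeros((2, n_params))
        self._idx = 0

    def add(self, values: np.ndarray) -> None:
        h = 0 if self._idx < self.half else 1
        self.count[h] += 1
        self.s1[h] += values
        self.s2[h] += values * values
        self._idx += 1

    def halves(self) -> tuple[np.ndarray, np.ndarray]:
        """(means, variances), each (2, n_params)."""
        n = np.maximum(self.count, 1)[:, None]
        mean = self.s1 / n
        var = self.s2 / n - mean**2
        # unbiased within-sequence variance
        var = var * (n / np.maximum(n - 1, 1))
        return mean, var


def psrf_from_halves(means: np.ndarray, variances: np.ndarray, n: float) -> np.ndarray:
    """Split-chain potential scale reduction from per-half moments.

    ``means``/``variances`` have shape (n_sequences, n_params); ``n`` is the
    per-sequence length.  Returns R-hat per parameter (1.0 when the
    between- and within-variance both vanish).
    """
    m = means.shape[0]
    w = variances.mean(axis=0)
    b_over_n = means.var(axis=0, ddof=1)
    var_plus = (n - 1.0) / n * w + b_over_n
    out = np.ones_like(w)
    pos = w > 0
    out[pos] = np.sqrt(var_plus[pos] / w[pos])
    # degenerate sequences with zero within-variance but separated means
    bad = (~pos) & (b_over_n > 0)
    out[bad] = np.inf
    return out


def run_chains(
    data: GraphData,
    config: MCMCConfig,
    n_chains: int = 3,
    seed=None,
    init_jitter: float = 0.3,
    sigma0: float | None = None,
) -> PosteriorSamples:
    """Run the full HMC-within-Gibbs sampler for several chains.

    Chains are initialized from dispersed starting points (``init_jitter``
    on the log scales).  Split-PSRF is accumulated for every log-weight,
    log w*, log alpha, log(1-sigma) and log tau, and stored in
    ``PosteriorSamples.psrf`` (max over weights reported as ``"omega"``).
    """
    rng_master = as_rng(seed)
    chain_seeds = rng_master.integers(0, 2**31 - 1, size=n_chains)
    n_kept = (config.n_iter - config.n_burnin) // config.thinning
    n = data.n_nodes

    alpha = np.empty((n_chains, n_kept))
    sigma = np.empty((n_chains, n_kept))
    tau = np.empty((n_chains, n_kept))
    w_star = np.empty((n_chains, n_kept))
    logcond = np.empty((n_chains, n_kept))
    hmc_rate = np.empty(n_chains)
    hyper_rate = np.empty(n_chains)
    step_sizes = np.empty(n_chains)
    weights_store = (
        np.empty((n_chains, n_kept, n)) if config.store_weights else None
    )
    # split accumulators: weights + (log w*, log alpha, log(1-sigma), log tau)
    accs = [_SplitAccumulator(n + 4, n_kept) for _ in range(n_chains)]

    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        state = initialize_state(data, rng, sigma0=sigma0, jitter=init_jitter)
        nbar, m = sample_latent_counts(state.weights, data.edges, rng)
        state = MCMCState(
            state.omega, state.w_star, state.alpha, state.sigma, state.tau, nbar, m
        )
        log_eps = math.log(config.initial_step_size)
        post_adapt_acc = []
        hyper_acc = []
        kept = 0
        # windowed adaptation: the first half of the adaptation phase tunes
        # the step size under identity mass while collecting per-coordinate
        # variances of omega; the second half re-tunes the step size under
        # the estimated diagonal mass; both freeze at n_adapt
        n_adapt = config.n_adapt
        mass_switch = n_adapt // 2
        collect_from = n_adapt // 4
        inv_mass = None
        om_s1 = np.zeros(n)
        om_s2 = np.zeros(n)
        om_n = 0
        for it in range(config.n_iter):
            # step 1: weights
            state, accepted, aprob = hmc_update(
                state, math.exp(log_eps), config.leapfrog_steps, rng, inv_mass
            )
            if it < n_adapt:
                t_adapt = it if it < mass_switch else it - mass_switch
                gamma = 0.5 / (1.0 + t_adapt) ** 0.6
                log_eps += gamma * (aprob - config.hmc_target_accept)
                if collect_from <= it < mass_switch and mass_switch > 0:
                    om_s1 += state.omega
                    om_s2 += state.omega**2
                    om_n += 1
                if it + 1 == mass_switch and om_n > 10:
                    var = om_s2 / om_n - (om_s1 / om_n) ** 2
                    inv_mass = np.clip(var, 1e-4, 1e4)
            else:
                post_adapt_acc.append(aprob)
            # step 2: hyperparameters and remainder mass.  The block is much
            # cheaper than the HMC step, so it is refreshed several times per
            # sweep to offset the small random-walk scale (each refresh is an
            # exact MH update of the same conditional).
            for _ in range(config.hyper_mh_steps):
                state, h_acc = mh_update_hyper(state, config, rng)
                hyper_acc.append(h_acc)
            # step 3: latent counts
            nbar, m = sample_latent_counts(state.weights, data.edges, rng)
            state = MCMCState(
                state.omega, state.w_star, state.alpha, state.sigma, state.tau, nbar, m
            )
            if config.log_every and (it + 1) % config.log_every == 0:
                logger.info(
                    "chain %d iter %d: hmc %.2f hyper %.2f step %.3g "
                    "alpha %.3g sigma %.3f tau %.3g",
                    c,
                    it + 1,
                    float(np.mean(post_adapt_acc[-config.log_every:] or [aprob])),
                    float(np.mean(hyper_acc[-config.log_every:])),
                    math.exp(log_eps),
                    state.alpha,
                    state.sigma,
                    state.tau,
                )
            if it >= config.n_burnin and (it - config.n_burnin) % config.thinning == 0:
                if kept < n_kept:
                    alpha[c, kept] = state.alpha
                    sigma[c, kept] = state.sigma
                    tau[c, kept] = state.tau
                    w_star[c, kept] = state.w_star
                    logcond[c, kept] = log_conditional_weights(
                        state.omega, state.m, state.sigma, state.tau, state.w_star
                    )
                    if weights_store is not None:
                        weights_store[c, kept] = state.weights
                    accs[c].add(
                        np.concatenate(
                            [
                                state.omega,
                                [
                                    math.log(max(state.w_star, 1e-300)),
                                    math.log(state.alpha),
                                    math.log(1.0 - state.sigma),
                                    math.log(state.tau),
                                ],
                            ]
                        )
                    )
                    kept += 1
        hmc_rate[c] = float(np.mean(post_adapt_acc)) if post_adapt_acc else math.nan
        hyper_rate[c] = float(np.mean(hyper_acc))
        step_sizes[c] = math.exp(log_eps)

    # split-PSRF from accumulated halves
    means = np.concatenate([a.halves()[0] for a in accs], axis=0)
    variances = np.concatenate([a.halves()[1] for a in accs], axis=0)
    half_len = accs[0].half
    r = psrf_from_halves(means, variances, half_len)
    psrf = {
        "omega": float(np.max(r[:n])) if n else 1.0,
        "w_star": float(r[n]),
        "alpha": float(r[n + 1]),
        "sigma": float(r[n + 2]),
        "tau": float(r[n + 3]),
    }
    return PosteriorSamples(
        alpha=alpha,
        sigma=sigma,
        tau=tau,
        w_star=w_star,
        logcond=logcond,
        hmc_accept_rate=hmc_rate,
        hyper_accept_rate=hyper_rate,
        step_size=step_sizes,
        psrf=psrf,
        weights=weights_store,
    )
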