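"""Random generation of CRM restrictions for graph simulation and inference.

Four sampling primitives back everything else in the package:

* the *total mass* ``W*_alpha`` of a GGP on ``[0, alpha]``, whose Laplace
  transform is ``exp(-alpha psi(t))`` — a gamma variable at sigma=0, a
  compound Poisson sum at sigma<0 and an exponentially tilted stable
  variable at sigma in (0,1);
* exact *finite-activity* draws (sigma<0): a Poisson number of
  gamma-distributed atoms;
* *truncated* infinite-activity draws: atoms above a threshold eps sampled
  by inverting the tail Lévy intensity, so the atom count is
  Poisson(alpha rho_bar(eps)) and each weight is an exact draw from the
  restriction of rho to (eps, inf);
* the *urn* predictive for the normalized CRM (exact Chinese-restaurant
  form at sigma=0; EPPF ratios with the positive stable density at
  sigma in (0,1), exact but slow and flag-gated).

The tilted-stable total mass is sampled exactly by divide and conquer:
``W*`` is infinitely divisible, so it is split into ``m`` i.i.d. pieces with
``m`` chosen so each piece's rejection step (Zolotarev/Kanter stable draw,
thinned with probability ``exp(-tau s)``) accepts with probability at least
``e^-1``.  Every routine takes an explicit seed or ``numpy`` Generator and
is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

from .levy import GGPModel, GGPParams, LevyModel, _is_zero_sigma

__all__ = [
    "WeightedNodeSet",
    "UrnState",
    "as_rng",
    "sample_total_mass",
    "sample_finite_activity",
    "sample_truncated",
    "default_truncation",
    "truncated_mean_mass",
    "urn_next",
    "eppf_ggp",
    "stable_density",
]

#: default bound on the discarded expected mass of a truncated draw,
#: relative to the total expected mass alpha*m1.
DEFAULT_MASS_FRACTION = 1e-4


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class WeightedNodeSet:
    """Atoms (w_i, theta_i) of a CRM restricted to [0, alpha].

    ``remainder_mass`` estimates the total mass of atoms below the
    truncation threshold (zero for exact finite-activity draws);
    ``truncation`` records the threshold itself.
    """

    weights: np.ndarray
    locations: np.ndarray
    remainder_mass: float = 0.0
    truncation: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.locations = np.asarray(self.locations, dtype=float)
        if self.weights.shape != self.locations.shape:
            raise ValueError("weights and locations must have equal length")
        if np.any(self.weights <= self.truncation):
            raise ValueError("all weights must exceed the truncation threshold")
        if self.remainder_mass < 0:
            raise ValueError("remainder_mass must be nonnegative")

    @property
    def n_atoms(self) -> int:
        return self.weights.size

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum() + self.remainder_mass)


@dataclass
class UrnState:
    """Partition state of the normalized-CRM urn: cluster sizes after n draws."""

    draw_count: int = 0
    cluster_sizes: list = field(default_factory=list)
    total_mass: float = 1.0

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.draw_count:
            raise ValueError("cluster sizes must sum to the draw count")
        if len(self.cluster_sizes) > self.draw_count:
            raise ValueError("cannot have more clusters than draws")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


# --------------------------------------------------------------------------
# Zolotarev / Kanter machinery for the positive stable law
# --------------------------------------------------------------------------


def _log_zolotarev_a(u: np.ndarray, sigma: float) -> np.ndarray:
    """log A(u) with A(u) = [sin(su)^s sin((1-s)u)^(1-s) / sin(u)]^(1/(1-s))."""
    s = sigma
    return (
        s * np.log(np.sin(s * u))
        + (1.0 - s) * np.log(np.sin((1.0 - s) * u))
        - np.log(np.sin(u))
    ) / (1.0 - s)


def _sample_standard_stable(sigma: float, size: int, rng: np.random.Generator):
    """Kanter's exact sampler for the positive stable law with LT e^{-t^sigma}."""
    u = rng.uniform(0.0, np.pi, size)
    e = rng.exponential(size=size)
    log_s = ((1.0 - sigma) / sigma) * (_log_zolotarev_a(u, sigma) - np.log(e))
    with np.errstate(over="ignore"):
        return np.exp(log_s)


def stable_density(x, sigma: float, n_nodes: int = 256):
    """Density g_sigma of the positive stable law (LT e^{-t^sigma}).

    Zolotarev's integral representation,

        g(x) = s/(1-s) * x^(-1/(1-s)) * (1/pi)
               * int_0^pi A(u) exp(-A(u) x^(-s/(1-s))) du,

    evaluated by fixed-order Gauss-Legendre quadrature (the integrand is
    smooth on (0, pi)).
    """
    out = np.exp(log_stable_density(x, sigma, n_nodes=n_nodes))
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def log_stable_density(x, sigma: float, n_nodes: int = 256):
    """log g_sigma(x), computed by log-sum-exp over the Zolotarev nodes so it
    stays finite deep into the x -> 0 boundary layer."""
    if not 0 < sigma < 1:
        raise ValueError("stable_density requires sigma in (0, 1)")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x1 = np.atleast_1d(x).astype(float)
    nodes, wts = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * np.pi * (nodes + 1.0)
    du = 0.5 * np.pi * wts
    log_a = _log_zolotarev_a(u, sigma)
    b = sigma / (1.0 - sigma)
    out = np.full_like(x1, -np.inf)
    pos = x1 > 0
    with np.errstate(over="ignore", under="ignore"):
        xb = np.exp(-b * np.log(x1[pos]))
        expo = (
            log_a[None, :]
            - np.exp(log_a)[None, :] * xb[:, None]
            + np.log(du)[None, :]
        )
        mx = expo.max(axis=1)
        log_integ = mx + np.log(np.exp(expo - mx[:, None]).sum(axis=1))
    out[pos] = (
        math.log(b / math.pi) - np.log(x1[pos]) / (1.0 - sigma) + log_integ
    )
    return float(out[0]) if scalar else out


# --------------------------------------------------------------------------
# total mass
# --------------------------------------------------------------------------


def sample_total_mass(params: GGPParams, seed=None, size: int | None = None):
    """Draw the GGP total mass W*_alpha, with E[e^{-t W*}] = exp(-alpha psi(t)).

    sigma = 0      : gamma(alpha, rate tau)
    sigma < 0      : compound Poisson — Poisson(-(alpha/sigma) tau^sigma)
                     count of gamma(-sigma, rate tau) jumps
    sigma in (0,1) : exponentially tilted stable, exact divide-and-conquer
                     rejection (see module docstring); requires tau > 0 or
                     sigma > 0
    """
    rng = as_rng(seed)
    alpha, sigma, tau = params.alpha, params.sigma, params.tau
    n = 1 if size is None else int(size)
    if alpha == 0:
        out = np.zeros(n)
    elif _is_zero_sigma(sigma):
        if tau <= 0:
            raise ValueError("sigma = 0 requires tau > 0 for a finite total mass")
        out = rng.gamma(shape=alpha, scale=1.0 / tau, size=n)
    elif sigma < 0:
        rate = -(alpha / sigma) * tau**sigma
        counts = rng.poisson(rate, size=n)
        out = np.array(
            [rng.gamma(-sigma, 1.0 / tau, size=k).sum() for k in counts]
        )
    else:
        out = np.array(
            [_tilted_stable_mass(alpha, sigma, tau, rng) for _ in range(n)]
        )
    return float(out[0]) if size is None else out


def _tilted_stable_mass(alpha: float, sigma: float, tau: float, rng) -> float:
    """Exact draw with LT exp(-alpha ((tau+t)^sigma - tau^sigma)/sigma)."""
    lam_alpha = alpha * tau**sigma / sigma if tau > 0 else 0.0
    m = max(1, math.ceil(lam_alpha))
    # each piece: c * S1 with S1 standard stable, thinned by exp(-tau c S1);
    # pieces are i.i.d., so candidates are drawn in oversized batches and any
    # accepted candidate fills any remaining piece
    c = (alpha / (m * sigma)) ** (1.0 / sigma)
    p_acc = math.exp(-lam_alpha / m) if tau > 0 else 1.0
    total = 0.0
    need = m
    while need > 0:
        k = int(need / p_acc + 4.0 * math.sqrt(need / p_acc)) + 16
        s = c * _sample_standard_stable(sigma, k, rng)
        if tau > 0:
            with np.errstate(over="ignore", under="ignore"):
                s = s[rng.random(k) < np.exp(-tau * s)]
        if s.size > need:
            s = s[:need]
        total += s.sum()
        need -= s.size
    return total


# --------------------------------------------------------------------------
# atom-set samplers
# --------------------------------------------------------------------------


def sample_finite_activity(params: GGPParams, seed=None) -> WeightedNodeSet:
    """Exact GGP draw in the finite-activity regime sigma < 0.

    The number of atoms is Poisson(-(alpha/sigma) tau^sigma) and weights are
    i.i.d. gamma(-sigma, rate tau); locations are uniform on [0, alpha].
    """
    if params.sigma >= 0:
        raise ValueError(
            "sample_finite_activity requires sigma < 0 (finite activity); "
            "use sample_truncated for sigma >= 0"
        )
    rng = as_rng(seed)
    alpha, sigma, tau = params.alpha, params.sigma, params.tau
    if alpha == 0:
        return WeightedNodeSet(np.empty(0), np.empty(0))
    rate = -(alpha / sigma) * tau**sigma
    k = rng.poisson(rate)
    weights = rng.gamma(-sigma, 1.0 / tau, size=k)
    locations = rng.uniform(0.0, alpha, size=k)
    return WeightedNodeSet(weights, locations)


def truncated_mean_mass(model: LevyModel, eps: float) -> float:
    """alpha * integral_0^eps w rho(dw): expected mass lost to truncation."""
    from .levy import PointMassModel

    params = model.params
    if isinstance(model, PointMassModel):
        return params.alpha * model.w0 if model.w0 <= eps else 0.0
    if isinstance(model, GGPModel):
        sigma, tau = params.sigma, params.tau
        if tau > 0:
            frac = special.gammainc(1.0 - sigma, tau * eps)
            return params.alpha * frac * tau ** (sigma - 1.0)
        return (
            params.alpha
            * eps ** (1.0 - sigma)
            / ((1.0 - sigma) * special.gamma(1.0 - sigma))
        )
    val, _ = integrate.quad(lambda w: w * model.density(w), 0.0, eps, limit=200)
    return params.alpha * val


def default_truncation(
    params: GGPParams, mass_fraction: float = DEFAULT_MASS_FRACTION
) -> float:
    """Threshold eps such that the discarded expected mass is a small
    fraction of the total expected mass alpha * m1.

    Requires a finite mean measure (tau > 0 for sigma >= 0); the pure stable
    case must be given an explicit eps.
    """
    sigma, tau = params.sigma, params.tau
    if tau <= 0:
        raise ValueError(
            "default_truncation requires tau > 0; pass eps explicitly for "
            "the stable case"
        )
    return float(special.gammaincinv(1.0 - sigma, mass_fraction) / tau)


def sample_truncated(
    params_or_model,
    eps: float | None = None,
    seed=None,
    mass_fraction: float = DEFAULT_MASS_FRACTION,
) -> WeightedNodeSet:
    """Draw the atoms with weight above eps by the inverse-Lévy method.

    The atom count is Poisson(alpha rho_bar(eps)); each weight is
    rho_bar^{-1}(v) with v uniform on (0, rho_bar(eps)) — an exact draw from
    the normalized restriction of rho to (eps, inf).  The expected mass below
    eps is stored as ``remainder_mass`` for diagnostics.

    When ``eps`` is omitted it defaults to the threshold at which the
    discarded expected mass is ``mass_fraction`` of the total.
    """
    if isinstance(params_or_model, GGPParams):
        model: LevyModel = GGPModel(params_or_model)
    else:
        model = params_or_model
    params = model.params
    if eps is None:
        if not isinstance(model, GGPModel):
            raise ValueError("eps is required for non-GGP models")
        eps = default_truncation(params, mass_fraction)
    if eps <= 0:
        raise ValueError("truncation eps must be positive")
    rng = as_rng(seed)
    alpha = params.alpha
    if alpha == 0:
        return WeightedNodeSet(np.empty(0), np.empty(0), truncation=eps)
    tail_eps = model.tail(eps)
    k = rng.poisson(alpha * tail_eps) if tail_eps > 0 else 0
    if k == 0:
        weights = np.empty(0)
    else:
        v = rng.uniform(0.0, tail_eps, size=k)
        weights = model.inverse_tail(v)
        # guard roundoff at the boundary
        weights = np.maximum(weights, np.nextafter(eps, np.inf))
    locations = rng.uniform(0.0, alpha, size=k)
    remainder = truncated_mean_mass(model, eps)
    return WeightedNodeSet(weights, locations, remainder_mass=remainder, truncation=eps)


# --------------------------------------------------------------------------
# urn / EPPF route
# --------------------------------------------------------------------------


def eppf_ggp(cluster_sizes, n: int, k: int, total_mass: float, sigma: float) -> float:
    """EPPF of the normalized GGP given total mass t, for sigma in (0, 1).

    Pi_k^n(m_1..m_k | t) = sigma^k t^{-n} / (Gamma(n - k sigma) g_sigma(t))
                           * int_0^t s^{n - k sigma - 1} g_sigma(t - s) ds
                           * prod_i Gamma(m_i - sigma)/Gamma(1 - sigma)

    Exact but slow (nested quadrature of the stable density); intended for
    small n and for validating the urn predictive.
    """
    if not 0 < sigma < 1:
        raise ValueError("eppf_ggp requires sigma in (0, 1)")
    sizes = list(cluster_sizes)
    if sum(sizes) != n or len(sizes) != k:
        raise ValueError("cluster sizes must sum to n with k clusters")
    if total_mass <= 0:
        raise ValueError("total mass must be positive")
    t = total_mass
    a = n - k * sigma

    # I = integral_0^t s^(a-1) g_sigma(t-s) ds, split at s = t/2.
    # Left piece (s near 0): y = s^a regularizes the endpoint; g is smooth.
    # Right piece (x = t-s near 0, where all of g's mass sits for small
    # sigma): substitute z = x^(-b) with b = sigma/(1-sigma); Zolotarev's
    # representation gives g(x) dx = (1/pi) int A(u) e^{-A(u) z} du dz, an
    # O(1)-scale smooth exponential in z for every sigma.
    nodes, wts = np.polynomial.legendre.leggauss(400)

    def panel(lo, hi):
        return 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo), 0.5 * (hi - lo) * wts

    y, wy = panel(0.0, (t / 2.0) ** a)
    s = y ** (1.0 / a)
    left = float(np.exp(log_stable_density(t - s, sigma)) @ wy) / a

    b = sigma / (1.0 - sigma)
    u_nodes, u_wts = np.polynomial.legendre.leggauss(256)
    u = 0.5 * np.pi * (u_nodes + 1.0)
    du = 0.5 * np.pi * u_wts
    a_vals = np.exp(_log_zolotarev_a(u, sigma))
    z0 = (t / 2.0) ** (-b)
    z1 = z0 + 60.0 / a_vals.min()
    z, wz = panel(z0, z1)
    x = z ** (-1.0 / b)
    with np.errstate(under="ignore"):
        inner = (a_vals[None, :] * np.exp(-a_vals[None, :] * z[:, None])) @ du
    right = float((((t - x) ** (a - 1.0)) * inner / math.pi) @ wz)

    val = left + right
    gt = stable_density(t, sigma)
    if not np.isfinite(val) or gt <= 0 or not np.isfinite(gt):
        raise ArithmeticError(
            f"EPPF quadrature failed (integral={val}, g_sigma(t)={gt})"
        )
    log_prod = sum(
        math.lgamma(m - sigma) - math.lgamma(1.0 - sigma) for m in sizes
    )
    log_val = (
        k * math.log(sigma)
        - n * math.log(t)
        - math.lgamma(a)
        - math.log(gt)
        + math.log(val)
        + log_prod
    )
    return math.exp(log_val)


def urn_predictive_probs(state: UrnState, params: GGPParams, use_eppf: bool = False):
    """Probabilities (new cluster, existing cluster 1..k) for the next draw.

    sigma = 0 gives the Blackwell–MacQueen / Chinese-restaurant form:
    a new cluster with probability alpha/(alpha+n), cluster j with
    probability m_j/(alpha+n) (independent of the total mass).  For
    sigma in (0, 1) the probabilities are ratios of EPPF values and require
    ``use_eppf=True``.
    """
    sigma, alpha = params.sigma, params.alpha
    n, k = state.draw_count, state.n_clusters
    sizes = state.cluster_sizes
    if n == 0:
        return np.array([1.0])
    if _is_zero_sigma(sigma):
        probs = np.empty(k + 1)
        probs[0] = alpha / (alpha + n)
        probs[1:] = np.asarray(sizes, dtype=float) / (alpha + n)
        return probs
    if sigma < 0:
        raise ValueError(
            "no closed-form urn for sigma < 0; sample the finite-activity "
            "atoms directly (sample_finite_activity)"
        )
    if not use_eppf:
        raise ValueError(
            "sigma in (0,1) urn requires use_eppf=True (exact but slow)"
        )
    t = state.total_mass
    base = eppf_ggp(sizes, n, k, t, sigma)
    probs = np.empty(k + 1)
    probs[0] = eppf_ggp(sizes + [1], n + 1, k + 1, t, sigma) / base
    for j in range(k):
        grown = list(sizes)
        grown[j] += 1
        probs[j + 1] = eppf_ggp(grown, n + 1, k, t, sigma) / base
    total = probs.sum()
    if not math.isfinite(total) or abs(total - 1.0) > 1e-3:
        raise ArithmeticError(
            f"urn predictive probabilities sum to {total}; quadrature failure"
        )
    return probs / total


def urn_next(
    state: UrnState, params: GGPParams, seed=None, use_eppf: bool = False
) -> tuple[UrnState, int]:
    """Advance the urn by one draw; returns (new state, cluster index).

    The cluster index is 0-based into the updated ``cluster_sizes``; a brand
    new cluster is appended at the end.
    """
    rng = as_rng(seed)
    probs = urn_predictive_probs(state, params, use_eppf=use_eppf)
    choice = int(rng.choice(probs.size, p=probs))
    sizes = list(state.cluster_sizes)
    if choice == 0:
        sizes.append(1)
        idx = len(sizes) - 1
    else:
        sizes[choice - 1] += 1
        idx = choice - 1
    return (
        UrnState(state.draw_count + 1, sizes, total_mass=state.total_mass),
        idx,
    )
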