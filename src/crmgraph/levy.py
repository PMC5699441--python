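"""Lévy-measure machinery for random-measure graph models.

A homogeneous completely random measure (CRM) on the real line is
characterized by a Lévy measure ``rho(dw)`` on the positive weights.  The
graph models in this package place a CRM ``W = sum_i w_i delta_{theta_i}``
on a window ``[0, alpha]`` and connect nodes i and j with probability
``1 - exp(-2 w_i w_j)``; every analytic property of the resulting graph
(expected node/edge counts, sparsity regime, total-mass law) is a
functional of ``rho``.

The workhorse here is the generalized gamma process (GGP),

    rho(dw) = w^(-1-sigma) exp(-tau w) / Gamma(1-sigma) dw,

with ``sigma < 1`` controlling activity/sparsity and ``tau >= 0`` an
exponential tilt.  ``sigma < 0`` gives a finite-activity CRM (dense
graphs); ``sigma in [0, 1)`` gives infinite activity (sparse graphs).
Closed forms are used wherever they exist; adaptive quadrature covers the
rest, with the integral split at w=1 and a log substitution on (0, 1] to
tame the w^(-1-sigma) singularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "GGPParams",
    "LevyModel",
    "GGPModel",
    "PointMassModel",
    "CompoundPoissonModel",
    "ggp_density",
    "tail_intensity",
    "inverse_tail_intensity",
    "laplace_exponent",
    "moments",
    "expected_counts",
    "asymptotic_nodes",
]

#: sigma values closer to zero than this are routed to the sigma=0 closed
#: forms, avoiding catastrophic cancellation in ((tau+t)^sigma - tau^sigma)/sigma.
SIGMA_ZERO_TOL = 1e-12

#: relative tolerance for the adaptive quadratures backing Theorem-style
#: expectation formulas.
QUAD_RTOL = 1e-8

#: relative tolerance for monotone root solves (inverse tail intensity).
INV_RTOL = 1e-10


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GGPParams:
    """Hyperparameters (alpha, sigma, tau) of a GGP restricted to [0, alpha].

    Parameters
    ----------
    alpha : float
        Size of the observation window; scales the expected number of
        nodes and interactions.  Must be positive (zero is tolerated for
        degenerate/empty-window computations).
    sigma : float
        Sparsity/discount parameter, ``sigma < 1``.  Negative values give
        finite-activity (dense-graph) processes, ``[0, 1)`` infinite
        activity (sparse graphs).
    tau : float
        Exponential tilt, controls the decay of large weights.  The valid
        region is ``(sigma < 0, tau > 0)`` or ``(0 <= sigma < 1, tau >= 0)``.
    """

    alpha: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.alpha >= 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be a nonnegative real, got {self.alpha}")
        ok_neg = self.sigma < 0 and self.tau > 0
        ok_pos = 0 <= self.sigma < 1 and self.tau >= 0
        if not (ok_neg or ok_pos):
            raise ValueError(
                "(sigma, tau) must lie in (-inf,0)x(0,inf) or [0,1)x[0,inf); "
                f"got sigma={self.sigma}, tau={self.tau}"
            )

    @property
    def is_finite_activity(self) -> bool:
        return self.sigma < 0

    def require_finite_mean(self) -> None:
        """Reject parameter choices with infinite mean weight measure.

        Posterior inference requires ``integral w rho(dw) < inf``, which for
        the GGP excludes the pure stable case ``sigma >= 0, tau = 0``; that
        case remains available for simulation demos.
        """
        if self.sigma >= 0 and self.tau == 0:
            raise ValueError(
                "sigma >= 0 with tau = 0 (stable process) has infinite mean "
                "weight measure and is not supported for inference"
            )


def _is_zero_sigma(sigma: float) -> bool:
    return abs(sigma) < SIGMA_ZERO_TOL


# --------------------------------------------------------------------------
# upper incomplete gamma for real (possibly nonpositive) first argument
# --------------------------------------------------------------------------


def _gamma_upper(a: float, x):
    """Upper incomplete gamma Gamma(a, x) for real a, vectorized in x > 0.

    scipy only exposes the regularized version for a > 0; for a <= 0 the
    recurrence Gamma(a, x) = (Gamma(a+1, x) - x^a e^-x) / a is used, switching
    to the divergent asymptotic series x^(a-1) e^-x sum_k (a-1)...(a-k)/x^k
    for large x where the recurrence cancels catastrophically.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Gamma(a, x) requires x >= 0 here")
    if a > 0:
        return special.gammaincc(a, x) * special.gamma(a)
    if a == 0:
        return special.exp1(x)
    if a <= -1:
        # peel off one unit at a time (only small |a| is ever needed)
        return (_gamma_upper(a + 1.0, x) - np.power(x, a) * np.exp(-x)) / a

    out = np.empty_like(x)
    small = x <= 30.0
    if np.any(small):
        xs = x[small]
        out[small] = (_gamma_upper(a + 1.0, xs) - np.power(xs, a) * np.exp(-xs)) / a
    if np.any(~small):
        xl = x[~small]
        # asymptotic series; |a-1..a-k|/x^k terms shrink rapidly for x > 30
        term = np.ones_like(xl)
        acc = np.ones_like(xl)
        for k in range(1, 16):
            term = term * (a - k) / xl
            acc = acc + term
        out[~small] = np.power(xl, a - 1.0) * np.exp(-xl) * acc
    return out


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------


class LevyModel:
    """A Lévy measure with density, tail, Laplace exponent and moments.

    Subclasses override with closed forms where available; the base class
    supplies adaptive-quadrature fallbacks.  ``alpha`` (the window size) is
    carried on ``params`` so expectation formulas are total functions of the
    model.
    """

    params: GGPParams

    # -- density -----------------------------------------------------------
    def density(self, w):
        raise NotImplementedError

    # -- tail intensity ----------------------------------------------------
    def tail(self, x):
        """rho_bar(x) = integral_x^inf rho(dw); quadrature fallback."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("tail intensity requires x > 0")
        scalar = x.ndim == 0

        def one(xi: float) -> float:
            val, _ = integrate.quad(
                self.density, xi, np.inf, epsrel=QUAD_RTOL, limit=200
            )
            return val

        out = np.array([one(xi) for xi in np.atleast_1d(x)])
        return float(out[0]) if scalar else out

    def total_intensity(self) -> float:
        """rho_bar(0+); +inf for infinite-activity measures."""
        return float(self.tail(1e-300))

    # -- inverse tail ------------------------------------------------------
    def inverse_tail(self, v):
        """Solve rho_bar(x) = v for x > 0 (monotone root solve)."""
        v = np.asarray(v, dtype=float)
        if np.any(v <= 0):
            raise ValueError("inverse tail intensity requires v > 0")
        total = self.total_intensity()
        if np.any(v > total):
            raise ValueError(
                f"v={np.max(v)} outside the range of the tail intensity "
                f"(rho_bar(0+)={total})"
            )
        scalar = v.ndim == 0

        def one(vi: float) -> float:
            lo, hi = 1e-12, 1.0
            while self.tail(lo) < vi:
                lo /= 1e3
                if lo < 1e-290:
                    break
            while self.tail(hi) > vi:
                hi *= 1e3
                if hi > 1e290:
                    break
            return optimize.brentq(
                lambda t: self.tail(math.exp(t)) - vi,
                math.log(lo),
                math.log(hi),
                rtol=INV_RTOL,
            )

        out = np.exp([one(vi) for vi in np.atleast_1d(v)])
        return float(out[0]) if scalar else out

    # -- Laplace exponent --------------------------------------------------
    def laplace_exponent(self, t):
        """psi(t) = integral (1 - e^{-wt}) rho(dw); quadrature fallback."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("Laplace exponent requires t >= 0")
        scalar = t.ndim == 0

        def one(ti: float) -> float:
            if ti == 0:
                return 0.0
            return _split_levy_integral(self.density, lambda w: -np.expm1(-w * ti))

        out = np.array([one(ti) for ti in np.atleast_1d(t)])
        return float(out[0]) if scalar else out

    # -- moments -----------------------------------------------------------
    def moments(self) -> tuple[float, float]:
        """(m1, m2) = (integral w rho(dw), integral w^2 rho(dw)).

        Divergent moments are returned as ``inf`` (a flagged value, never an
        exception) so sparsity classification can branch on them.
        """
        m1 = _split_levy_integral(self.density, lambda w: w)
        m2 = _split_levy_integral(self.density, lambda w: w * w)
        return m1, m2

    # -- expectation formulas ---------------------------------------------
    def expected_counts(self) -> tuple[float, float, float]:
        """Expected (D*_alpha, N^(e)_alpha, N_alpha) on the window [0, alpha].

        D*_alpha is the directed multigraph edge total, N^(e)_alpha the
        undirected edge count (self-loops counted once) and N_alpha the
        number of nodes of degree >= 1:

            E[D*]  = alpha^2 m1^2 + alpha m2
            E[Ne]  = alpha^2/2 * int psi(2w) rho(dw)
                     + alpha * int (1 - e^{-w^2}) rho(dw)
            E[N]   = alpha * int [1 - exp(-w^2 - alpha psi(2w))] rho(dw)
        """
        alpha = self.params.alpha
        if alpha == 0:
            return 0.0, 0.0, 0.0
        m1, m2 = self.moments()
        if not (math.isfinite(m1) and math.isfinite(m2)):
            return math.inf, math.inf, math.inf
        e_dstar = alpha**2 * m1**2 + alpha * m2
        e_edges = 0.5 * alpha**2 * _split_levy_integral(
            self.density, lambda w: self.laplace_exponent(2.0 * w)
        ) + alpha * _split_levy_integral(self.density, lambda w: -np.expm1(-w * w))
        e_nodes = alpha * _split_levy_integral(
            self.density,
            lambda w: -np.expm1(-w * w - alpha * self.laplace_exponent(2.0 * w)),
        )
        return e_dstar, e_edges, e_nodes


def _split_levy_integral(density: Callable, f: Callable) -> float:
    """integral_0^inf f(w) rho(w) dw, split at w=1, log-substituted on (0,1].

    After u = log(w) the inner integrand is smooth and decays exponentially
    as u -> -inf for every integrable f; the outer piece decays at least
    exponentially for the GGP-type densities used here.  Divergence shows up
    as quadrature blow-up and is reported as inf.
    """

    def inner(u):
        w = math.exp(u)
        return f(w) * density(w) * w

    def outer(w):
        return f(w) * density(w)

    # The lower cutoff w = e^-138 ~ 1e-60 keeps density(w) representable;
    # every integrand used here vanishes at least linearly at 0, so the
    # discarded piece is below ~1e-30 absolute.
    import warnings

    with np.errstate(over="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        try:
            lo, _ = integrate.quad(inner, -138.0, 0.0, epsrel=QUAD_RTOL, limit=400)
            hi, _ = integrate.quad(outer, 1.0, np.inf, epsrel=QUAD_RTOL, limit=400)
        except (OverflowError, FloatingPointError):
            return math.inf
    total = lo + hi
    if not math.isfinite(total) or total > 1e300:
        return math.inf
    return total


class GGPModel(LevyModel):
    """Generalized gamma process, with closed forms throughout."""

    kind = "ggp"

    def __init__(self, params: GGPParams):
        self.params = params

    # density --------------------------------------------------------------
    def density(self, w):
        w = np.asarray(w, dtype=float)
        if np.any(w <= 0):
            raise ValueError("GGP density requires w > 0")
        sigma, tau = self.params.sigma, self.params.tau
        out = np.power(w, -1.0 - sigma) * np.exp(-tau * w) / special.gamma(1.0 - sigma)
        return float(out) if out.ndim == 0 else out

    # tail ------------------------------------------------------------------
    def tail(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("tail intensity requires x > 0")
        sigma, tau = self.params.sigma, self.params.tau
        if tau == 0.0:
            if not 0 < sigma < 1:
                raise ValueError("tau = 0 requires sigma in (0, 1)")
            out = np.power(x, -sigma) / (special.gamma(1.0 - sigma) * sigma)
        else:
            out = (
                tau**sigma
                * _gamma_upper(-sigma, tau * x)
                / special.gamma(1.0 - sigma)
            )
        out = np.asarray(out)
        return float(out) if out.ndim == 0 else out

    def total_intensity(self) -> float:
        sigma, tau = self.params.sigma, self.params.tau
        if sigma >= 0:
            return math.inf
        # finite activity: rho_bar(0+) = -tau^sigma / sigma
        return -(tau**sigma) / sigma

    def log_tail(self, x):
        """log rho_bar(x), computed without underflow for large tau*x."""
        x = np.asarray(x, dtype=float)
        sigma, tau = self.params.sigma, self.params.tau
        if tau == 0.0:
            out = -sigma * np.log(x) - math.log(special.gamma(1.0 - sigma) * sigma)
            out = np.asarray(out)
            return float(out) if out.ndim == 0 else out
        z = tau * np.atleast_1d(x).astype(float)
        out = np.empty_like(z)
        small = z <= 30.0
        if np.any(small):
            out[small] = np.log(_gamma_upper(-sigma, z[small]))
        if np.any(~small):
            zl = z[~small]
            a = -sigma
            term = np.ones_like(zl)
            acc = np.ones_like(zl)
            for k in range(1, 16):
                term = term * (a - k) / zl
                acc = acc + term
            out[~small] = (a - 1.0) * np.log(zl) - zl + np.log(acc)
        out = out + sigma * math.log(tau) - math.lgamma(1.0 - sigma)
        if np.asarray(x).ndim == 0:
            return float(out[0])
        return out

    # inverse tail ----------------------------------------------------------
    def inverse_tail(self, v):
        v = np.asarray(v, dtype=float)
        if np.any(v <= 0):
            raise ValueError("inverse tail intensity requires v > 0")
        sigma, tau = self.params.sigma, self.params.tau
        total = self.total_intensity()
        if np.any(v > total * (1 + 1e-12)):
            raise ValueError(
                "v exceeds rho_bar(0+) for a finite-activity model "
                f"(rho_bar(0+)={total})"
            )
        scalar = v.ndim == 0
        v1 = np.atleast_1d(v).astype(float)
        if tau == 0.0:
            out = np.power(sigma * special.gamma(1.0 - sigma) * v1, -1.0 / sigma)
        else:
            if self.log_tail(1e-280) < math.log(np.max(v1)):
                raise ValueError(
                    "requested tail-intensity level exceeds the double-"
                    "precision weight range (weights would underflow)"
                )
            out = self._inverse_tail_newton(v1)
        return float(out[0]) if scalar else out

    def _newton_init(self, v: np.ndarray) -> np.ndarray:
        """Cheap monotone starting points for log-x Newton, by regime."""
        sigma, tau = self.params.sigma, self.params.tau
        euler = 0.5772156649015329
        if sigma > 0:
            x0 = np.power(sigma * special.gamma(1.0 - sigma) * v, -1.0 / sigma)
            return np.minimum(x0, 500.0 / tau)
        if _is_zero_sigma(sigma):
            # rho_bar(x) = E1(tau x): -log(tau x)-euler for small x,
            # e^{-tau x}/(tau x) for large x
            with np.errstate(invalid="ignore", divide="ignore"):
                lv = np.log(v)
                big_x = -lv + np.log(np.maximum(-lv, 1e-1))
            x0 = np.where(v > 1.0, np.exp(-v - euler), np.maximum(big_x, 1e-2))
            return x0 / tau
        # finite activity: weights are O(1/tau)
        return np.full_like(v, 1.0 / tau)

    def _inverse_tail_newton(self, v: np.ndarray) -> np.ndarray:
        """Vectorized damped Newton on log rho_bar in log-x coordinates."""
        logv = np.log(v)
        if v.size >= 10_000:
            t = self._interp_init(logv)
        else:
            t = np.log(np.clip(self._newton_init(v), 1e-290, 1e290))
        active = np.arange(t.size)
        for _ in range(100):
            ta = t[active]
            x = np.exp(ta)
            lt = self.log_tail(x)
            g = lt - logv[active]
            done = np.abs(g) < 1e-12
            if np.any(done):
                keep = ~done
                active = active[keep]
                if active.size == 0:
                    break
                ta, x, lt, g = ta[keep], x[keep], lt[keep], g[keep]
            # d/dt log rho_bar(e^t) = -x rho(x) / rho_bar(x)
            with np.errstate(over="ignore", under="ignore"):
                deriv = -np.exp(np.log(x) + self._log_density(x) - lt)
            step = np.where(np.isfinite(deriv) & (deriv < 0), g / deriv, np.sign(g))
            step = np.clip(step, -2.0, 2.0)  # damping keeps iterates sane
            t[active] = ta - step
        x = np.exp(t)
        resid = np.abs(self.log_tail(x) - logv)
        bad = ~(resid < 1e-9)
        if np.any(bad):
            for i in np.nonzero(bad)[0]:
                x[i] = math.exp(
                    optimize.brentq(
                        lambda u: self.log_tail(math.exp(u)) - logv[i],
                        math.log(1e-280),
                        math.log(1e280),
                        rtol=INV_RTOL,
                    )
                )
        return x

    def _interp_init(self, logv: np.ndarray) -> np.ndarray:
        """Tabulated inverse of log_tail as a cheap Newton starting point.

        Brackets the needed x-range with two scalar solves, tabulates
        log_tail on a dense log-grid, and linearly interpolates; Newton
        then polishes in 2-4 iterations.
        """
        vmin, vmax = float(np.min(logv)), float(np.max(logv))
        if self.log_tail(1e-280) < vmax:
            raise ValueError(
                "requested tail-intensity level exceeds the double-precision "
                "weight range (weights would underflow)"
            )
        x_hi = math.exp(
            optimize.brentq(
                lambda u: self.log_tail(math.exp(u)) - vmin,
                math.log(1e-280),
                math.log(1e280),
                rtol=1e-6,
            )
        )
        x_lo = math.exp(
            optimize.brentq(
                lambda u: self.log_tail(math.exp(u)) - vmax,
                math.log(1e-280),
                math.log(1e280),
                rtol=1e-6,
            )
        )
        grid_t = np.linspace(math.log(x_lo) - 0.1, math.log(x_hi) + 0.1, 4000)
        grid_f = self.log_tail(np.exp(grid_t))
        # log_tail decreases in t; np.interp needs increasing abscissae
        return np.interp(logv, grid_f[::-1], grid_t[::-1])

    def _log_density(self, w):
        sigma, tau = self.params.sigma, self.params.tau
        return (
            (-1.0 - sigma) * np.log(w) - tau * w - math.lgamma(1.0 - sigma)
        )

    # Laplace exponent -------------------------------------------------------
    def laplace_exponent(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("Laplace exponent requires t >= 0")
        sigma, tau = self.params.sigma, self.params.tau
        if _is_zero_sigma(sigma):
            out = np.log1p(t / tau)
        else:
            out = ((tau + t) ** sigma - tau**sigma) / sigma
        out = np.asarray(out)
        return float(out) if out.ndim == 0 else out

    # moments ----------------------------------------------------------------
    def moments(self) -> tuple[float, float]:
        sigma, tau = self.params.sigma, self.params.tau
        if tau == 0.0:
            return math.inf, math.inf
        m1 = tau ** (sigma - 1.0)
        m2 = (1.0 - sigma) * tau ** (sigma - 2.0)
        return m1, m2

    # asymptotics ------------------------------------------------------------
    def asymptotic_nodes(self) -> float:
        """Leading-order E[N_alpha] as alpha grows, by sigma regime.

        sigma < 0 :  -(alpha/sigma) tau^sigma      (finite-activity node rate)
        sigma = 0 :  alpha log(alpha)
        sigma > 0 :  alpha^(1+sigma) 2^sigma tau^(sigma(sigma-1)) / sigma

        The sigma > 0 constant follows from E[N] ~ alpha psi(2 alpha m1) with
        psi(t) ~ t^sigma/sigma.  No error bound is attached; this is an
        asymptotic, useful as an order-of-magnitude check on Eq-27-style
        quadrature.
        """
        alpha, sigma, tau = self.params.alpha, self.params.sigma, self.params.tau
        if _is_zero_sigma(sigma):
            return alpha * math.log(alpha)
        if sigma < 0:
            return -(alpha / sigma) * tau**sigma
        return alpha ** (1.0 + sigma) * 2.0**sigma * tau ** (sigma * (sigma - 1.0)) / sigma


class PointMassModel(LevyModel):
    """rho(dw) = delta_{w0}(dw): finite activity, Erdos-Renyi equivalent."""

    kind = "poisson_point_mass"

    def __init__(self, params: GGPParams, w0: float):
        if w0 <= 0:
            raise ValueError("w0 must be positive")
        self.params = params
        self.w0 = float(w0)

    def density(self, w):  # pragma: no cover - degenerate density
        raise NotImplementedError("point-mass Lévy measure has no density")

    def tail(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("tail intensity requires x > 0")
        out = np.where(x < self.w0, 1.0, 0.0)
        return float(out) if out.ndim == 0 else out

    def total_intensity(self) -> float:
        return 1.0

    def inverse_tail(self, v):
        v = np.asarray(v, dtype=float)
        if np.any(v <= 0):
            raise ValueError("inverse tail intensity requires v > 0")
        if np.any(v > 1.0):
            raise ValueError("v exceeds rho_bar(0+) = 1 for a point-mass model")
        out = np.full_like(v, self.w0)
        return float(out) if out.ndim == 0 else out

    def laplace_exponent(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("Laplace exponent requires t >= 0")
        out = -np.expm1(-self.w0 * t)
        return float(out) if out.ndim == 0 else out

    def moments(self) -> tuple[float, float]:
        return self.w0, self.w0**2

    def expected_counts(self) -> tuple[float, float, float]:
        alpha, w0 = self.params.alpha, self.w0
        if alpha == 0:
            return 0.0, 0.0, 0.0
        psi2w = -math.expm1(-2.0 * w0 * w0)
        e_dstar = alpha**2 * w0**2 + alpha * w0**2
        e_edges = 0.5 * alpha**2 * psi2w + alpha * (-math.expm1(-(w0**2)))
        e_nodes = alpha * (-math.expm1(-(w0**2) - alpha * psi2w))
        return e_dstar, e_edges, e_nodes


class CompoundPoissonModel(LevyModel):
    """rho(dw) = h(w) dw with a probability density h: finite activity."""

    kind = "compound_poisson"

    def __init__(
        self,
        params: GGPParams,
        jump_density: Callable,
        jump_cdf: Callable | None = None,
    ):
        self.params = params
        self.jump_density = jump_density
        self.jump_cdf = jump_cdf
        norm = _split_levy_integral(jump_density, lambda w: 1.0)
        if not math.isfinite(norm) or abs(norm - 1.0) > 1e-6:
            raise ValueError(
                f"compound-Poisson jump density must integrate to 1, got {norm}"
            )

    def density(self, w):
        return self.jump_density(w)

    def tail(self, x):
        if self.jump_cdf is not None:
            x = np.asarray(x, dtype=float)
            if np.any(x <= 0):
                raise ValueError("tail intensity requires x > 0")
            out = 1.0 - np.asarray(self.jump_cdf(x), dtype=float)
            return float(out) if out.ndim == 0 else out
        return super().tail(x)

    def total_intensity(self) -> float:
        return 1.0


# --------------------------------------------------------------------------
# operation-style wrappers
# --------------------------------------------------------------------------


def ggp_density(params: GGPParams, w):
    """GGP Lévy density w^(-1-sigma) exp(-tau w) / Gamma(1-sigma), w > 0."""
    return GGPModel(params).density(w)


def tail_intensity(model: LevyModel, x):
    """Tail Lévy intensity rho_bar(x) = integral_x^inf rho(dw)."""
    return model.tail(x)


def inverse_tail_intensity(model: LevyModel, v):
    """Inverse of the (monotone nonincreasing) tail intensity."""
    return model.inverse_tail(v)


def laplace_exponent(model: LevyModel, t):
    """psi(t) = integral (1 - e^{-wt}) rho(dw)."""
    return model.laplace_exponent(t)


def moments(model: LevyModel) -> tuple[float, float]:
    """First two moments of the Lévy measure; inf flags divergence."""
    return model.moments()


def expected_counts(model: LevyModel) -> tuple[float, float, float]:
    """Expected (multigraph edge total, undirected edges, observed nodes)."""
    return model.expected_counts()


def asymptotic_nodes(model: GGPModel) -> float:
    """Leading-order approximation of E[N_alpha] for large alpha (GGP)."""
    if not isinstance(model, GGPModel):
        raise TypeError("asymptotic_nodes is defined for GGP models")
    return model.asymptotic_nodes()
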