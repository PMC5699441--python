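"""Convergence and model-assessment tooling.

Covers the multi-chain potential scale reduction factor (PSRF, split-chain
Gelman–Rubin), the posterior probability of the sparse regime
``Pr(sigma >= 0 | z)``, the dense-regime reparameterization
``(varsigma_1, varsigma_2, varsigma_3)`` and posterior-predictive degree
distributions.

The reparameterization maps (alpha, sigma, tau) to quantities that remain
identifiable when the data are dense (sigma < 0): varsigma_1 =
-(alpha/sigma) tau^sigma is the expected number of (potential) nodes,
varsigma_2 = -sigma/tau the mean sociability and varsigma_3 = -sigma/tau^2
the sociability variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .levy import GGPParams
from .samplers import as_rng
from .simulate import simulate_ggp_graph

__all__ = [
    "ReparamSummary",
    "psrf",
    "prob_sigma_nonneg",
    "reparameterize",
    "reparameterize_samples",
    "posterior_predictive_degrees",
    "degree_ccdf",
    "plot_degree_bands",
    "plot_traces",
]


@dataclass(frozen=True)
class ReparamSummary:
    """(varsigma_1, varsigma_2, varsigma_3) for sigma != 0, tau > 0."""

    varsigma1: float
    varsigma2: float
    varsigma3: float


def psrf(chains) -> float:
    """Split-chain potential scale reduction factor for one scalar series.

    ``chains`` is a sequence of >= 2 equal-length (>= 10) 1-d arrays, on
    whatever scale the sampler used.  Each chain is split in half; R-hat is
    sqrt(((n-1)/n W + B/n) / W) over the resulting sequences.  Identical
    constant chains return exactly 1.0.
    """
    arrs = [np.asarray(c, dtype=float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("psrf requires at least two chains")
    lengths = {a.shape[0] for a in arrs}
    if len(lengths) != 1:
        raise ValueError("chains must have equal lengths")
    n_full = lengths.pop()
    if n_full < 10:
        raise ValueError("chains must have length >= 10")
    half = n_full // 2
    seqs = []
    for a in arrs:
        seqs.append(a[:half])
        seqs.append(a[half : 2 * half])
    seqs = np.asarray(seqs)
    w = seqs.var(axis=1, ddof=1).mean()
    b_over_n = seqs.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else math.inf
    var_plus = (half - 1) / half * w + b_over_n
    return float(math.sqrt(var_plus / w))


def prob_sigma_nonneg(samples) -> float:
    """Posterior Pr(sigma >= 0 | z): fraction of retained draws, pooled."""
    sig = np.asarray(samples.sigma, dtype=float).ravel()
    if sig.size == 0:
        raise ValueError("no posterior draws")
    return float(np.mean(sig >= 0.0))


def reparameterize(alpha: float, sigma: float, tau: float) -> ReparamSummary:
    """varsigma_1 = -(alpha/sigma) tau^sigma, varsigma_2 = -sigma/tau,
    varsigma_3 = -sigma/tau^2 (undefined at sigma = 0)."""
    if sigma == 0:
        raise ValueError("reparameterization is undefined at sigma = 0")
    if tau <= 0:
        raise ValueError("reparameterization requires tau > 0")
    return ReparamSummary(
        varsigma1=-(alpha / sigma) * tau**sigma,
        varsigma2=-sigma / tau,
        varsigma3=-sigma / tau**2,
    )


def reparameterize_samples(samples):
    """Vectorized (varsigma_1, varsigma_2, varsigma_3) over retained draws."""
    a = np.asarray(samples.alpha, float).ravel()
    s = np.asarray(samples.sigma, float).ravel()
    t = np.asarray(samples.tau, float).ravel()
    if np.any(s == 0):
        raise ValueError("reparameterization is undefined at sigma = 0")
    return (-(a / s) * t**s, -s / t, -s / t**2)


def degree_ccdf(degrees: np.ndarray, max_degree: int | None = None) -> np.ndarray:
    """Empirical P(degree >= d) for d = 1..max_degree."""
    degrees = np.asarray(degrees)
    if max_degree is None:
        max_degree = int(degrees.max()) if degrees.size else 1
    counts = np.bincount(degrees, minlength=max_degree + 1)[: max_degree + 1]
    tail = counts[::-1].cumsum()[::-1]
    total = max(degrees.size, 1)
    return tail[1:] / total


def posterior_predictive_degrees(
    samples,
    n_draws: int = 200,
    seed=None,
    max_degree: int = 1000,
    quantiles=(0.025, 0.5, 0.975),
    mass_fraction: float = 1e-3,
):
    """Posterior-predictive degree-distribution bands.

    For ``n_draws`` retained hyperparameter draws (evenly spaced through the
    pooled chains), simulates a graph and tabulates the degree CCDF
    P(deg >= d); returns ``(d_grid, bands)`` where bands has one row per
    requested quantile.  Degrees count a self-loop as 2, matching the
    multigraph-degree convention.
    """
    rng = as_rng(seed)
    a = np.asarray(samples.alpha, float).ravel()
    s = np.asarray(samples.sigma, float).ravel()
    t = np.asarray(samples.tau, float).ravel()
    if a.size == 0:
        raise ValueError("no posterior draws to predict from")
    idx = np.linspace(0, a.size - 1, min(n_draws, a.size)).astype(int)
    ccdfs = np.zeros((idx.size, max_degree))
    for row, k in enumerate(idx):
        params = GGPParams(a[k], s[k], max(t[k], 1e-10))
        _, summ = simulate_ggp_graph(
            params, method="auto", seed=rng, mass_fraction=mass_fraction
        )
        if summ.degrees.size:
            cc = degree_ccdf(summ.degrees, max_degree)
            ccdfs[row, : cc.size] = cc
    bands = np.quantile(ccdfs, quantiles, axis=0)
    return np.arange(1, max_degree + 1), bands


# --------------------------------------------------------------------------
# plots (thin matplotlib wrappers; files only, no interactive backend)
# --------------------------------------------------------------------------


def plot_degree_bands(
    observed_degrees, d_grid, bands, path, title="posterior-predictive degrees"
):
    """Log-log degree CCDF: observed curve inside predictive quantile bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    obs = degree_ccdf(np.asarray(observed_degrees), int(d_grid[-1]))
    ax.loglog(d_grid[: obs.size], np.maximum(obs, 1e-12), "r-", label="observed")
    ax.fill_between(
        d_grid,
        np.maximum(bands[0], 1e-12),
        np.maximum(bands[-1], 1e-12),
        alpha=0.3,
        label="predictive band",
    )
    if bands.shape[0] > 2:
        ax.loglog(d_grid, np.maximum(bands[1], 1e-12), "b--", lw=1, label="median")
    ax.set_xlabel("degree d")
    ax.set_ylabel("P(degree >= d)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_traces(samples, path):
    """Trace plots of alpha, sigma, tau and w* for each chain."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = ["alpha", "sigma", "tau", "w_star"]
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for ax, name in zip(axes.ravel(), names):
        series = getattr(samples, name)
        for c in range(series.shape[0]):
            ax.plot(series[c], lw=0.6)
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
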