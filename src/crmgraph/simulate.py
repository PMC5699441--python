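"""Graph generation from CRM draws.

The generative model, conditional on an atom set ``W = sum_i w_i
delta_{theta_i}`` on ``[0, alpha]``:

1. a directed multigraph is a Poisson process with mean measure W x W —
   equivalently, a total of ``D* ~ Poisson((sum_i w_i)^2)`` directed edges,
   each picking its two endpoints independently with probability
   ``w_i / sum_j w_j`` (a normalized-CRM draw);
2. the undirected graph sets ``z_ij = z_ji = 1`` iff ``n_ij + n_ji > 0``
   (self-loops allowed), which conditionally on the weights is the same as
   independent links with probability ``1 - exp(-2 w_i w_j)`` off the
   diagonal and ``1 - exp(-w_i^2)`` on it.

Only nodes hit by at least one edge end are retained ("observed nodes").
Atom locations theta never enter edge probabilities; they are carried for
reproducibility only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .levy import GGPModel, GGPParams, _is_zero_sigma
from .samplers import (
    UrnState,
    WeightedNodeSet,
    as_rng,
    sample_finite_activity,
    sample_total_mass,
    sample_truncated,
    urn_predictive_probs,
    DEFAULT_MASS_FRACTION,
)

__all__ = [
    "Multigraph",
    "UndirectedGraph",
    "BipartiteGraph",
    "GraphSummary",
    "link_probability",
    "simulate_multigraph",
    "to_undirected",
    "simulate_ggp_graph",
    "simulate_er_equivalent",
    "simulate_bipartite",
    "simulate_graphex",
    "growth_curves",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class Multigraph:
    """Directed multigraph over observed nodes: sparse integer counts n_ij.

    ``node_weights`` holds the atoms restricted to nodes hit by at least one
    edge end; ``atom_index`` maps each observed node back to its index in
    the originating atom set.
    """

    node_weights: WeightedNodeSet
    counts: sparse.csr_matrix
    atom_index: np.ndarray = None

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("edge counts must be nonnegative")
        if self.atom_index is None:
            self.atom_index = np.arange(self.counts.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]

    @property
    def d_star(self) -> int:
        """Total number of directed edges D*_alpha."""
        return int(self.counts.sum())

    def degrees(self) -> np.ndarray:
        """Multigraph degrees m_i = sum_j (n_ij + n_ji); self-loops count twice."""
        out = np.asarray(self.counts.sum(axis=0)).ravel() + np.asarray(
            self.counts.sum(axis=1)
        ).ravel()
        return out.astype(np.int64)


@dataclass
class UndirectedGraph:
    """Simple undirected graph: sparse symmetric 0/1 adjacency, self-loops allowed.

    Isolated nodes are dropped at construction; ``atom_index`` keeps the
    mapping back to the originating atoms (identity when unknown).
    """

    adjacency: sparse.csr_matrix
    atom_index: np.ndarray = None
    node_weights: WeightedNodeSet | None = None

    def __post_init__(self) -> None:
        adj = sparse.csr_matrix(self.adjacency)
        adj.data = np.minimum(adj.data, 1).astype(np.int8)
        adj.eliminate_zeros()
        if (adj != adj.T).nnz:
            raise ValueError("adjacency must be symmetric")
        deg = np.asarray(adj.sum(axis=1)).ravel()
        keep = np.nonzero(deg > 0)[0]
        if keep.size < adj.shape[0]:
            adj = adj[keep][:, keep]
            if self.atom_index is not None:
                self.atom_index = np.asarray(self.atom_index)[keep]
            if self.node_weights is not None:
                self.node_weights = WeightedNodeSet(
                    self.node_weights.weights[keep],
                    self.node_weights.locations[keep],
                    remainder_mass=self.node_weights.remainder_mass,
                    truncation=self.node_weights.truncation,
                )
        self.adjacency = adj
        if self.atom_index is None:
            self.atom_index = np.arange(adj.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of unordered connected pairs, self-loops counted once."""
        adj = self.adjacency
        n_diag = int(adj.diagonal().sum())
        return (adj.nnz - n_diag) // 2 + n_diag

    def degrees(self, self_loop_weight: int = 2) -> np.ndarray:
        """Node degrees; a self-loop contributes ``self_loop_weight`` (default 2)."""
        adj = self.adjacency
        deg = np.asarray(adj.sum(axis=1)).ravel().astype(np.int64)
        if self_loop_weight != 1:
            deg += (self_loop_weight - 1) * adj.diagonal().astype(np.int64)
        return deg

    def edge_list(self) -> np.ndarray:
        """(n_edges, 2) array of unordered pairs i <= j."""
        coo = sparse.triu(self.adjacency).tocoo()
        return np.column_stack([coo.row, coo.col])


@dataclass
class BipartiteGraph:
    """Binary bipartite graph between two independent CRM draws."""

    adjacency: sparse.csr_matrix  # rows: side A, cols: side B
    row_weights: WeightedNodeSet | None = None
    col_weights: WeightedNodeSet | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.adjacency.shape

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)


@dataclass
class GraphSummary:
    """Observed-graph statistics: N_alpha, N^(e)_alpha, D*_alpha, degrees."""

    n_nodes: int
    n_edges: int
    d_star: int
    degrees: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        if self.n_edges > self.d_star:
            raise ValueError("undirected edge count cannot exceed D*")
        if self.n_nodes > 2 * self.d_star:
            raise ValueError("cannot observe more than 2 D* nodes")


def summarize(graph: UndirectedGraph, d_star: int) -> GraphSummary:
    return GraphSummary(
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        d_star=int(d_star),
        degrees=graph.degrees(),
    )


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------


def link_probability(w_i, w_j, same_node: bool = False):
    """P(z_ij = 1 | w) = 1 - exp(-2 w_i w_j) for i != j, 1 - exp(-w_i^2) for i = j."""
    w_i = np.asarray(w_i, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    if np.any(w_i < 0) or np.any(w_j < 0):
        raise ValueError("weights must be nonnegative")
    if same_node:
        out = -np.expm1(-w_i * w_i)
    else:
        out = -np.expm1(-2.0 * w_i * w_j)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def simulate_multigraph(atoms: WeightedNodeSet, seed=None) -> Multigraph:
    """Cox-process draw of the directed multigraph given an atom set.

    ``D* ~ Poisson(T^2)`` with ``T = sum_i w_i``; each directed edge picks
    two endpoints i.i.d. proportional to the weights.  Conditionally on the
    atoms this matches independent per-pair Poisson(w_i w_j) counts.
    """
    rng = as_rng(seed)
    w = atoms.weights
    total = float(w.sum())
    if total <= 0:
        return _empty_multigraph(atoms)
    d_star = rng.poisson(total * total)
    if d_star == 0:
        return _empty_multigraph(atoms)
    if d_star > 200_000_000:
        raise RuntimeError(
            f"D* = {d_star} directed edges requested (total mass {total:.3g}); "
            "heavy-tailed weight draws (e.g. the stable case tau=0, whose "
            "multigraph edge total has infinite mean) can exceed memory — "
            "reduce alpha or use a tilted (tau > 0) model"
        )
    # vectorized categorical draw over atoms
    cum = np.cumsum(w)
    ends = np.searchsorted(cum, rng.random(2 * d_star) * total, side="right")
    ends = np.minimum(ends, w.size - 1)
    src, dst = ends[:d_star], ends[d_star:]
    observed = np.unique(ends)
    relabel = np.searchsorted(observed, ends)
    rs, rd = relabel[:d_star], relabel[d_star:]
    n = observed.size
    counts = sparse.coo_matrix(
        (np.ones(d_star, dtype=np.int64), (rs, rd)), shape=(n, n)
    ).tocsr()
    node_weights = WeightedNodeSet(
        atoms.weights[observed],
        atoms.locations[observed],
        remainder_mass=atoms.remainder_mass,
        truncation=atoms.truncation,
    )
    return Multigraph(node_weights, counts, atom_index=observed)


def _empty_multigraph(atoms: WeightedNodeSet) -> Multigraph:
    empty = WeightedNodeSet(
        np.empty(0),
        np.empty(0),
        remainder_mass=atoms.remainder_mass,
        truncation=atoms.truncation,
    )
    return Multigraph(
        empty,
        sparse.csr_matrix((0, 0), dtype=np.int64),
        atom_index=np.empty(0, dtype=np.int64),
    )


def to_undirected(mg: Multigraph) -> UndirectedGraph:
    """z_ij = min(n_ij + n_ji, 1) off-diagonal, z_ii = min(n_ii, 1)."""
    sym = mg.counts + mg.counts.T
    # the diagonal of counts + counts.T double-counts self-loops; harmless
    # since everything is clipped to {0, 1}
    return UndirectedGraph(
        sym, atom_index=np.asarray(mg.atom_index).copy(), node_weights=mg.node_weights
    )


# --------------------------------------------------------------------------
# full generators
# --------------------------------------------------------------------------


def simulate_ggp_graph(
    params: GGPParams,
    method: str = "auto",
    seed=None,
    eps: float | None = None,
    mass_fraction: float = DEFAULT_MASS_FRACTION,
    use_eppf: bool = False,
) -> tuple[UndirectedGraph, GraphSummary]:
    """Simulate an undirected GGP graph on the window [0, alpha].

    Methods
    -------
    ``finite``    : exact, sigma < 0 only (compound-Poisson atoms).
    ``truncated`` : inverse-Lévy truncation at eps (default: eps chosen so
                    the discarded expected mass is ``mass_fraction`` of the
                    total); any regime with tau > 0, or explicit eps.
    ``urn``       : marginalized urn route — exact for sigma = 0; for
                    sigma in (0, 1) requires ``use_eppf=True`` (slow).
    ``auto``      : finite for sigma < 0, truncated otherwise.
    """
    rng = as_rng(seed)
    sigma = params.sigma
    if method == "auto":
        method = "finite" if sigma < 0 else "truncated"
    if method == "finite":
        if sigma >= 0:
            raise ValueError("method='finite' requires sigma < 0")
        atoms = sample_finite_activity(params, rng)
    elif method == "truncated":
        atoms = sample_truncated(params, eps=eps, seed=rng, mass_fraction=mass_fraction)
    elif method == "urn":
        if not (_is_zero_sigma(sigma) or (0 < sigma < 1 and use_eppf)):
            raise ValueError(
                "method='urn' is exact for sigma = 0; sigma in (0,1) needs "
                "use_eppf=True, and sigma < 0 should use method='finite'"
            )
        return _simulate_urn_graph(params, rng, use_eppf=use_eppf)
    else:
        raise ValueError(f"unknown method {method!r}")
    mg = simulate_multigraph(atoms, rng)
    graph = to_undirected(mg)
    return graph, summarize(graph, mg.d_star)


def _simulate_urn_graph(
    params: GGPParams, rng, use_eppf: bool = False
) -> tuple[UndirectedGraph, GraphSummary]:
    """Exact marginalized route: total mass, Poisson edge total, urn endpoints."""
    if params.alpha == 0:
        g = UndirectedGraph(sparse.csr_matrix((0, 0), dtype=np.int8))
        return g, summarize(g, 0)
    w_star = sample_total_mass(params, rng)
    d_star = rng.poisson(w_star * w_star)
    state = UrnState(total_mass=w_star)
    labels = np.empty(2 * d_star, dtype=np.int64)
    for i in range(2 * d_star):
        probs = urn_predictive_probs(state, params, use_eppf=use_eppf)
        choice = int(rng.choice(probs.size, p=probs))
        sizes = list(state.cluster_sizes)
        if choice == 0:
            sizes.append(1)
            labels[i] = len(sizes) - 1
        else:
            sizes[choice - 1] += 1
            labels[i] = choice - 1
        state = UrnState(state.draw_count + 1, sizes, total_mass=w_star)
    n = state.n_clusters
    src, dst = labels[:d_star], labels[d_star:]
    counts = sparse.coo_matrix(
        (np.ones(d_star, dtype=np.int64), (src, dst)), shape=(n, n)
    ).tocsr()
    # weights are marginalized out on the urn route; carry NaN placeholders
    atoms = WeightedNodeSet(
        np.full(n, np.nan), rng.uniform(0.0, params.alpha, size=n)
    )
    mg = Multigraph(atoms, counts)
    graph = to_undirected(mg)
    return graph, summarize(graph, d_star)


def simulate_er_equivalent(
    alpha: float, w0: float, seed=None, n: int | None = None
) -> UndirectedGraph:
    """Point-mass CRM graph == Erdős–Rényi G(n, p), n ~ Poisson(alpha).

    ``p = 1 - exp(-2 w0^2)``; self-edges are ignored as in the classical
    model.  Pass ``n`` to fix the node count (G(n, p) fixture variant).
    """
    if w0 <= 0:
        raise ValueError("w0 must be positive")
    rng = as_rng(seed)
    if n is None:
        n = int(rng.poisson(alpha))
    p = -math.expm1(-2.0 * w0 * w0)
    n_pairs = n * (n - 1) // 2
    k = rng.binomial(n_pairs, p) if n_pairs > 0 else 0
    if k > 0:
        flat = rng.choice(n_pairs, size=k, replace=False)
        # linear index -> (i, j), i < j, row-major over the strict upper triangle
        i = (
            n
            - 2
            - np.floor(
                np.sqrt(-8.0 * flat + 4.0 * n * (n - 1) - 7.0) / 2.0 - 0.5
            ).astype(np.int64)
        )
        j = flat + i + 1 - (n * (n - 1) // 2) + ((n - i) * (n - i - 1)) // 2
        adj = sparse.coo_matrix(
            (np.ones(2 * k, dtype=np.int8), (np.r_[i, j], np.r_[j, i])),
            shape=(n, n),
        ).tocsr()
    else:
        adj = sparse.csr_matrix((n, n), dtype=np.int8)
    return UndirectedGraph(adj)


def simulate_bipartite(
    params_a: GGPParams,
    params_b: GGPParams,
    seed=None,
    eps: float | None = None,
    mass_fraction: float = DEFAULT_MASS_FRACTION,
) -> BipartiteGraph:
    """Bipartite binary graph from two independent CRM draws.

    Directed counts are Poisson with mean measure W x W': total
    ``D* ~ Poisson(W*_A W*_B)``, endpoints drawn independently from each
    normalized measure; ``z_ij = min(n_ij, 1)``.
    """
    rng = as_rng(seed)
    atoms_a = _any_regime_atoms(params_a, rng, eps, mass_fraction)
    atoms_b = _any_regime_atoms(params_b, rng, eps, mass_fraction)
    ta, tb = float(atoms_a.weights.sum()), float(atoms_b.weights.sum())
    if ta <= 0 or tb <= 0:
        return BipartiteGraph(
            sparse.csr_matrix((0, 0), dtype=np.int8), atoms_a, atoms_b
        )
    d_star = rng.poisson(ta * tb)
    rows = np.searchsorted(np.cumsum(atoms_a.weights), rng.random(d_star) * ta)
    cols = np.searchsorted(np.cumsum(atoms_b.weights), rng.random(d_star) * tb)
    rows = np.minimum(rows, atoms_a.n_atoms - 1)
    cols = np.minimum(cols, atoms_b.n_atoms - 1)
    adj = sparse.coo_matrix(
        (np.ones(d_star, dtype=np.int64), (rows, cols)),
        shape=(atoms_a.n_atoms, atoms_b.n_atoms),
    ).tocsr()
    adj.data = np.minimum(adj.data, 1).astype(np.int8)
    return BipartiteGraph(adj, atoms_a, atoms_b)


def _any_regime_atoms(params, rng, eps, mass_fraction) -> WeightedNodeSet:
    if params.sigma < 0:
        return sample_finite_activity(params, rng)
    return sample_truncated(params, eps=eps, seed=rng, mass_fraction=mass_fraction)


def simulate_graphex(
    params: GGPParams,
    vartheta_cap: float,
    seed=None,
) -> tuple[UndirectedGraph, GraphSummary]:
    """Kallenberg/graphex construction of the same undirected graph law.

    Draws a unit-rate Poisson process (theta_i, vartheta_i) on
    [0, alpha] x [0, vartheta_cap], maps vartheta to a weight through the
    inverse tail intensity (w_i = rho_bar^{-1}(vartheta_i)) and connects
    pairs with probability M(vartheta_i, vartheta_j) =
    1 - exp(-2 w_i w_j) (diagonal 1 - exp(-w_i^2)).

    ``vartheta_cap`` truncates the vertical axis and plays exactly the role
    of a weight truncation: vartheta > rho_bar(eps) iff w < eps.  Pairwise
    O(K^2) — intended for modest windows.
    """
    if vartheta_cap <= 0:
        raise ValueError("vartheta_cap must be positive")
    rng = as_rng(seed)
    alpha = params.alpha
    model = GGPModel(params)
    k = rng.poisson(alpha * vartheta_cap)
    if k == 0:
        g = UndirectedGraph(sparse.csr_matrix((0, 0), dtype=np.int8))
        return g, summarize(g, 0)
    if k > 20000:
        raise ValueError(
            f"graphex construction is O(K^2); K={k} points is too large"
        )
    theta = rng.uniform(0.0, alpha, size=k)
    vartheta = rng.uniform(0.0, vartheta_cap, size=k)
    w = model.inverse_tail(vartheta)
    # D | W ~ PP(W x W): per ordered pair Poisson(w_i w_j) counts, so the
    # undirected link probability is 1 - exp(-2 w_i w_j) (1 - exp(-w_i^2)
    # on the diagonal)
    prob = -np.expm1(-2.0 * np.outer(w, w))
    np.fill_diagonal(prob, -np.expm1(-(w**2)))
    u = rng.random((k, k))
    upper = np.triu(u < prob)
    adj_dense = upper | upper.T
    adj = sparse.csr_matrix(adj_dense.astype(np.int8))
    graph = UndirectedGraph(
        adj, node_weights=WeightedNodeSet(w, theta)
    )
    n_diag = int(adj.diagonal().sum())
    n_edges = (adj.nnz - n_diag) // 2 + n_diag
    return graph, GraphSummary(
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        d_star=max(n_edges, 1) if n_edges else 0,  # D* unobserved on this route
        degrees=graph.degrees(),
    )


def simulate_ggp_summaries(
    params: GGPParams,
    n_reps: int,
    seed=None,
    eps: float | None = None,
    mass_fraction: float = DEFAULT_MASS_FRACTION,
    batch_atoms: int = 20_000_000,
) -> list[GraphSummary]:
    """Monte-Carlo replicates of (N, N^(e), D*) for one parameter setting.

    Equivalent in distribution to repeated ``simulate_ggp_graph`` calls on
    the truncated route, but the weight inversions of many replicates are
    batched into single vectorized calls, which is much faster for large
    windows.
    """
    from .levy import GGPModel
    from .samplers import default_truncation, truncated_mean_mass

    rng = as_rng(seed)
    model = GGPModel(params)
    if eps is None:
        eps = default_truncation(params, mass_fraction)
    tail_eps = model.tail(eps)
    counts = rng.poisson(params.alpha * tail_eps, size=n_reps)
    out: list[GraphSummary] = []
    start = 0
    while start < n_reps:
        stop = start
        tot = 0
        while stop < n_reps and (tot == 0 or tot + counts[stop] <= batch_atoms):
            tot += counts[stop]
            stop += 1
        v = rng.uniform(0.0, tail_eps, size=int(counts[start:stop].sum()))
        weights = model.inverse_tail(v) if v.size else np.empty(0)
        offsets = np.concatenate([[0], np.cumsum(counts[start:stop])])
        for r in range(stop - start):
            w = weights[offsets[r] : offsets[r + 1]]
            atoms = WeightedNodeSet(
                np.maximum(w, np.nextafter(eps, np.inf)),
                rng.uniform(0.0, params.alpha, size=w.size),
                remainder_mass=truncated_mean_mass(model, eps),
                truncation=eps,
            )
            mg = simulate_multigraph(atoms, rng)
            graph = to_undirected(mg)
            out.append(summarize(graph, mg.d_star))
        start = stop
    return out


# --------------------------------------------------------------------------
# growth curves
# --------------------------------------------------------------------------


def growth_curves(
    params: GGPParams,
    alpha_grid,
    replicates: int = 5,
    seed=None,
    mass_fraction: float = DEFAULT_MASS_FRACTION,
):
    """Edge vs node growth along an increasing window grid.

    Simulates ``replicates`` graphs per alpha, collects (alpha, N, N^(e)),
    and fits the ordinary least-squares slope of log N^(e) on log N — the
    empirical sparsity exponent (2 for dense graphs, <= 2/(1+sigma) for
    GGP sigma in (0,1)).

    Returns ``(table, slope)`` where table is a pandas DataFrame.
    """
    import pandas as pd

    alpha_grid = list(alpha_grid)
    if len(alpha_grid) < 2 or any(
        b <= a for a, b in zip(alpha_grid, alpha_grid[1:])
    ):
        raise ValueError("alpha_grid must be increasing with at least 2 points")
    rng = as_rng(seed)
    rows = []
    for alpha in alpha_grid:
        pa = GGPParams(alpha, params.sigma, params.tau)
        for rep in range(replicates):
            _, s = simulate_ggp_graph(
                pa, method="auto", seed=rng, mass_fraction=mass_fraction
            )
            rows.append(
                {
                    "alpha": alpha,
                    "rep": rep,
                    "n_nodes": s.n_nodes,
                    "n_edges": s.n_edges,
                    "d_star": s.d_star,
                }
            )
    table = pd.DataFrame(rows)
    ok = (table.n_nodes > 1) & (table.n_edges > 0)
    if ok.sum() < 2:
        raise ValueError("degenerate growth table: all simulated graphs empty")
    x = np.log(table.n_nodes[ok].to_numpy(dtype=float))
    y = np.log(table.n_edges[ok].to_numpy(dtype=float))
    slope = float(np.polyfit(x, y, 1)[0])
    return table, slope
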