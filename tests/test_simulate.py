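"""Graph-construction checks: Cox-process route, transformations, equivalences."""

import math

import numpy as np
import pytest
import scipy.stats as st
from scipy import sparse

from crmgraph import (
    GGPModel,
    GGPParams,
    GraphSummary,
    Multigraph,
    WeightedNodeSet,
    growth_curves,
    link_probability,
    simulate_bipartite,
    simulate_er_equivalent,
    simulate_ggp_graph,
    simulate_ggp_summaries,
    simulate_graphex,
    simulate_multigraph,
    to_undirected,
)


class TestLinkProbability:
    def test_zero_weight_never_links(self):
        assert link_probability(0.0, 1.0) == 0.0

    def test_value(self):
        assert link_probability(0.5, 0.5) == pytest.approx(
            -math.expm1(-0.5), rel=1e-12
        )

    def test_self_loop_form(self):
        assert link_probability(0.7, 0.7, same_node=True) == pytest.approx(
            -math.expm1(-0.49), rel=1e-12
        )

    def test_monotone_in_each_weight(self):
        w = np.linspace(0, 3, 50)
        p = link_probability(w, np.full_like(w, 0.8))
        assert np.all(np.diff(p) >= 0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            link_probability(-1.0, 1.0)


class TestMultigraph:
    def test_single_atom_self_loops(self, rng):
        atoms = WeightedNodeSet(np.array([2.0]), np.array([0.0]))
        ds = np.array(
            [simulate_multigraph(atoms, rng).d_star for _ in range(3000)]
        )
        se = ds.std() / math.sqrt(ds.size)
        assert ds.mean() == pytest.approx(4.0, abs=4 * se)  # Poisson(w^2)

    def test_zero_mass_empty(self, rng):
        atoms = WeightedNodeSet(np.empty(0), np.empty(0))
        mg = simulate_multigraph(atoms, rng)
        assert mg.n_nodes == 0 and mg.d_star == 0

    def test_pair_count_mean(self, rng):
        """n_12 + n_21 has mean 2 w1 w2 (per-pair Poisson route)."""
        atoms = WeightedNodeSet(np.array([1.0, 1.0]), np.array([0.0, 0.5]))
        tot = 0
        n_rep = 3000
        for _ in range(n_rep):
            mg = simulate_multigraph(atoms, rng)
            c = mg.counts.toarray()
            full = np.zeros((2, 2))
            for r, a in enumerate(mg.atom_index):
                for s, b in enumerate(mg.atom_index):
                    full[a, b] = c[r, s]
            tot += full[0, 1] + full[1, 0]
        assert tot / n_rep == pytest.approx(2.0, abs=0.15)

    def test_undirected_link_frequencies_match_closed_form(self, rng):
        """Eq-of-link-probability vs multigraph-transformation equivalence."""
        w = np.array([0.3, 0.8, 1.5])
        atoms = WeightedNodeSet(w, np.zeros(3))
        n_rep = 8000
        hits = np.zeros((3, 3))
        for _ in range(n_rep):
            g = to_undirected(simulate_multigraph(atoms, rng))
            adj = np.zeros((3, 3))
            sub = g.adjacency.toarray()
            for r, a in enumerate(g.atom_index):
                for s, b in enumerate(g.atom_index):
                    adj[a, b] = sub[r, s]
            hits += adj
        freq = hits / n_rep
        for i in range(3):
            for j in range(3):
                p = link_probability(w[i], w[j], same_node=(i == j))
                se = math.sqrt(p * (1 - p) / n_rep)
                assert freq[i, j] == pytest.approx(p, abs=4 * se + 1e-9)


class TestToUndirected:
    def test_direct_rule(self):
        atoms = WeightedNodeSet(np.array([1.0, 1.0]), np.zeros(2))
        mg = Multigraph(atoms, sparse.csr_matrix(np.array([[2, 0], [1, 0]])))
        z = to_undirected(mg).adjacency.toarray()
        assert z.tolist() == [[1, 1], [1, 0]]

    def test_empty(self):
        atoms = WeightedNodeSet(np.empty(0), np.empty(0))
        mg = Multigraph(atoms, sparse.csr_matrix((0, 0), dtype=np.int64))
        g = to_undirected(mg)
        assert g.n_nodes == 0

    def test_symmetric_binary(self, rng):
        atoms = WeightedNodeSet(rng.uniform(0.1, 1.0, 5), np.zeros(5))
        g = to_undirected(simulate_multigraph(atoms, rng))
        adj = g.adjacency.toarray()
        assert np.array_equal(adj, adj.T)
        assert set(np.unique(adj)).issubset({0, 1})


class TestGGPGraph:
    def test_summary_invariants_across_regimes(self, rng):
        for sigma, tau in [(0.5, 1.0), (0.0, 1.0), (-0.5, 1.0)]:
            for _ in range(5):
                _, s = simulate_ggp_graph(GGPParams(20.0, sigma, tau), seed=rng)
                assert s.n_edges <= s.d_star
                assert s.n_nodes <= 2 * s.d_star
                assert s.n_edges <= s.n_nodes**2

    def test_empty_window(self):
        _, s = simulate_ggp_graph(GGPParams(0.0, 0.5, 1.0), seed=0)
        assert (s.n_nodes, s.n_edges, s.d_star) == (0, 0, 0)

    def test_incompatible_method(self):
        with pytest.raises(ValueError):
            simulate_ggp_graph(GGPParams(1.0, 0.5, 1.0), method="finite", seed=0)
        with pytest.raises(ValueError):
            simulate_ggp_graph(GGPParams(1.0, 0.5, 1.0), method="urn", seed=0)

    def test_urn_vs_truncated_agree_gamma_case(self, rng):
        """Two exact-vs-truncated routes give the same N_alpha law at sigma=0."""
        params = GGPParams(5.0, 0.0, 1.0)
        n_urn = [
            simulate_ggp_graph(params, method="urn", seed=rng)[1].n_nodes
            for _ in range(800)
        ]
        n_tr = [
            simulate_ggp_graph(params, method="truncated", seed=rng)[1].n_nodes
            for _ in range(800)
        ]
        assert st.mannwhitneyu(n_urn, n_tr).pvalue > 1e-3

    def test_batched_replicates_match_direct_route(self, rng):
        params = GGPParams(10.0, 0.5, 1.0)
        batched = simulate_ggp_summaries(params, 400, seed=rng, mass_fraction=1e-3)
        direct = [
            simulate_ggp_graph(params, seed=rng, mass_fraction=1e-3)[1]
            for _ in range(400)
        ]
        nb = [s.n_nodes for s in batched]
        nd = [s.n_nodes for s in direct]
        assert st.mannwhitneyu(nb, nd).pvalue > 1e-3


class TestER:
    def test_half_probability_weight(self):
        w0 = math.sqrt(math.log(2) / 2)
        assert link_probability(w0, w0) == pytest.approx(0.5, rel=1e-12)

    def test_edge_frequency(self, rng):
        """Pairwise link frequency at w0=1 is 1 - e^-2."""
        n = 500
        g = simulate_er_equivalent(0.0, 1.0, seed=rng, n=n)
        pairs = n * (n - 1) / 2
        p = 1 - math.exp(-2.0)
        freq = (g.adjacency.nnz / 2) / pairs
        se = math.sqrt(p * (1 - p) / pairs)
        assert freq == pytest.approx(p, abs=4 * se)

    def test_poisson_node_count(self, rng):
        counts = []
        for _ in range(300):
            g = simulate_er_equivalent(50.0, 2.0, seed=rng)
            # w0 large: nearly complete graph, all nodes observed
            counts.append(g.n_nodes)
        se = np.std(counts) / math.sqrt(len(counts))
        assert np.mean(counts) == pytest.approx(50.0, abs=4 * se)

    def test_tiny_weight_empty(self, rng):
        g = simulate_er_equivalent(20.0, 1e-9, seed=rng)
        assert g.n_edges == 0


class TestBipartite:
    def test_single_atom_sides_poisson(self, rng):
        # both sides dense single-ish atoms via sigma<0 with tiny alpha is
        # awkward; instead check the empty-side contract and the D* mean on a
        # fixed-weight stub through the internal sampler contract
        from crmgraph.simulate import BipartiteGraph

        g = simulate_bipartite(
            GGPParams(0.0, 0.5, 1.0), GGPParams(5.0, 0.5, 1.0), seed=rng
        )
        assert isinstance(g, BipartiteGraph)
        assert g.n_edges == 0

    def test_edge_mean_scales_with_masses(self, rng):
        params = GGPParams(2.0, -0.5, 1.0)
        totals = []
        for _ in range(500):
            g = simulate_bipartite(params, params, seed=rng)
            totals.append(g.n_edges)
        # E[D*] = E[Wa*] E[Wb*] = (alpha tau^(sigma-1))^2 = 4; binary count <= D*
        assert 1.0 < np.mean(totals) <= 4.5

    def test_exchangeable_marginals(self, rng):
        """Row/column structure symmetric under relabeling by construction."""
        params = GGPParams(3.0, -0.5, 1.0)
        g = simulate_bipartite(params, params, seed=rng)
        assert g.adjacency.shape[0] == g.row_weights.n_atoms


class TestGraphex:
    def test_symmetry_and_decay(self):
        model = GGPModel(GGPParams(1.0, 0.5, 0.0))
        w_small = model.inverse_tail(np.array([50.0, 100.0]))
        assert np.all(np.diff(w_small) < 0)  # rho_bar^-1 decreasing => M -> 0

    def test_matches_truncated_route(self, rng):
        """Graphex with cap rho_bar(eps) == truncated route, in distribution.

        Run at tau=1 (numeric inverse tail): the stable case tau=0 has an
        infinite-mean multigraph edge total, so the Cox-total route is not a
        usable reference there.
        """
        params = GGPParams(5.0, 0.5, 1.0)
        model = GGPModel(params)
        eps = 1e-3
        cap = model.tail(eps)
        n_gx = [
            simulate_graphex(params, vartheta_cap=cap, seed=rng)[1].n_nodes
            for _ in range(400)
        ]
        n_tr = [
            simulate_ggp_graph(params, method="truncated", eps=eps, seed=rng)[1].n_nodes
            for _ in range(400)
        ]
        assert st.mannwhitneyu(n_gx, n_tr).pvalue > 1e-3

    def test_bad_cap(self):
        with pytest.raises(ValueError):
            simulate_graphex(GGPParams(1.0, 0.5, 0.0), vartheta_cap=0.0, seed=0)


class TestGrowthCurves:
    def test_dense_slope_two(self, rng):
        _, slope = growth_curves(
            GGPParams(1.0, -0.5, 1.0), [50, 100, 200, 400, 800], replicates=3, seed=rng
        )
        assert slope == pytest.approx(2.0, abs=0.15)

    def test_sparse_slope_bounded(self, rng):
        _, slope = growth_curves(
            GGPParams(1.0, 0.5, 1.0),
            [50, 100, 200, 400],
            replicates=3,
            seed=rng,
            mass_fraction=1e-3,
        )
        assert slope <= 2.0 / 1.5 + 0.1

    def test_table_contents(self, rng):
        table, _ = growth_curves(
            GGPParams(1.0, -0.5, 1.0), [20, 40], replicates=2, seed=rng
        )
        assert set(table.columns) == {"alpha", "rep", "n_nodes", "n_edges", "d_star"}
        assert len(table) == 4
        assert np.all(table.n_edges <= table.n_nodes**2)

    def test_bad_grid(self, rng):
        with pytest.raises(ValueError):
            growth_curves(GGPParams(1.0, 0.5, 1.0), [100, 50], seed=rng)


class TestSummaryInvariants:
    def test_rejects_impossible_counts(self):
        with pytest.raises(ValueError):
            GraphSummary(n_nodes=1, n_edges=5, d_star=4)
        with pytest.raises(ValueError):
            GraphSummary(n_nodes=10, n_edges=1, d_star=1)
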