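"""Network statistics, DP-ERGM release, randomized-response baseline.

Graph summaries are validated against independent brute-force oracles
(triple scans, exhaustive shortest-path enumeration) on every graph
with up to 5 nodes and on random sparser graphs up to 8 nodes.
"""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from pandemicdp import (
    Graph,
    dp_ergm_release,
    espd_tvd,
    fit_ergm_edge,
    graph_stats,
    rr_debias_edge_count,
    rr_flip,
    sample_graph_fixed_edges,
    simulate_ctn,
)
from pandemicdp.ctn import BoundaryMLEError


def make_graph(n, edges):
    return Graph(n_nodes=n, edges=frozenset(edges))


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation path)
# ---------------------------------------------------------------------------


def brute_triangles(n, edges):
    es = {tuple(sorted(e)) for e in edges}
    return sum(
        1
        for a, b, c in itertools.combinations(range(n), 3)
        if (a, b) in es and (a, c) in es and (b, c) in es
    )


def brute_adj(n, edges):
    adj = {u: set() for u in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def brute_espd(n, edges):
    adj = brute_adj(n, edges)
    counts = np.zeros(max(n - 1, 1))
    for u, v in edges:
        counts[len(adj[u] & adj[v])] += 1
    return counts / len(edges) if edges else counts


def brute_all_shortest_paths(n, edges, s, t):
    """All shortest s-t paths by exhaustive simple-path enumeration."""
    adj = brute_adj(n, edges)
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for w in adj[u]:
            if w not in path:
                extend(path + [w])

    extend([s])
    if not paths:
        return []
    shortest = min(len(p) for p in paths)
    return [p for p in paths if len(p) == shortest]


def brute_betweenness(n, edges):
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = brute_all_shortest_paths(n, edges, s, t)
        if not paths:
            continue
        for i in range(n):
            if i in (s, t):
                continue
            bc[i] += sum(i in p for p in paths) / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return bc / norm if norm > 0 else bc


def brute_closeness(n, edges):
    adj = brute_adj(n, edges)
    out = np.zeros(n)
    for i in range(n):
        dist = {i: 0}
        frontier = [i]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = d
                        nxt.append(w)
            frontier = nxt
        a = len(dist) - 1
        if a > 0:
            out[i] = (a / (n - 1)) ** 2 / sum(dist.values())
    return out


def all_graphs(n):
    dyads = list(itertools.combinations(range(n), 2))
    for mask in range(2 ** len(dyads)):
        yield [d for j, d in enumerate(dyads) if mask >> j & 1]


# ---------------------------------------------------------------------------


class TestGraphStats:
    def test_complete_graph_k4(self):
        g = make_graph(4, itertools.combinations(range(4), 2))
        s = graph_stats(g)
        assert s.edge_count == 6
        assert s.triangle_count == 4
        # every edge's endpoints share the other 2 nodes
        assert s.espd[2] == pytest.approx(1.0)
        assert s.degree_dist[3] == 4

    def test_isolated_node_closeness_zero(self):
        g = make_graph(3, [(0, 1)])
        s = graph_stats(g)
        assert s.closeness[2] == 0.0
        assert s.degree_dist[0] == 1

    def test_path_graph_center_betweenness(self):
        """P5 center: 4 of the 6 non-center pair paths pass through it."""
        g = make_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        s = graph_stats(g)
        assert s.betweenness[2] == pytest.approx(4.0 / 6.0)
        np.testing.assert_allclose(s.betweenness, brute_betweenness(5, g.edges))

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_exhaustive_small_graphs(self, n):
        for edges in all_graphs(n):
            g = make_graph(n, edges)
            s = graph_stats(g)
            assert s.triangle_count == brute_triangles(n, edges)
            np.testing.assert_allclose(s.betweenness, brute_betweenness(n, edges), atol=1e-12)
            np.testing.assert_allclose(s.closeness, brute_closeness(n, edges), atol=1e-12)
            if edges:
                np.testing.assert_allclose(s.espd, brute_espd(n, edges))
            assert s.degree_dist.sum() == n

    def test_exhaustive_five_node_graphs(self):
        for edges in all_graphs(5):
            g = make_graph(5, edges)
            s = graph_stats(g)
            assert s.triangle_count == brute_triangles(5, edges)
            np.testing.assert_allclose(s.closeness, brute_closeness(5, edges), atol=1e-12)
            if edges:
                np.testing.assert_allclose(s.espd, brute_espd(5, edges))

    def test_random_graphs_up_to_eight_nodes(self, rng):
        for n in (6, 7, 8):
            for _ in range(12):
                mask = rng.random(n * (n - 1) // 2) < 0.25
                dyads = list(itertools.combinations(range(n), 2))
                edges = [d for d, keep in zip(dyads, mask) if keep]
                g = make_graph(n, edges)
                s = graph_stats(g)
                assert s.triangle_count == brute_triangles(n, edges)
                np.testing.assert_allclose(
                    s.betweenness, brute_betweenness(n, edges), atol=1e-12
                )
                np.testing.assert_allclose(
                    s.closeness, brute_closeness(n, edges), atol=1e-12
                )

    def test_graph_invariants_enforced(self):
        with pytest.raises(ValueError, match="self-loop"):
            make_graph(3, [(1, 1)])
        with pytest.raises(ValueError):
            make_graph(2, [(0, 5)])


class TestEspdTvd:
    def test_identical_graphs_distance_zero(self):
        g = make_graph(4, [(0, 1), (1, 2), (0, 2)])
        assert espd_tvd(graph_stats(g), graph_stats(g)) == 0.0

    def test_triangle_vs_path_disjoint_support(self):
        """Triangle edges share 1 partner, path edges 0: TVD = 1."""
        tri = graph_stats(make_graph(3, [(0, 1), (1, 2), (0, 2)]))
        path = graph_stats(make_graph(3, [(0, 1), (1, 2)]))
        assert espd_tvd(tri, path) == pytest.approx(1.0)

    def test_zero_edge_graph_rejected(self):
        empty = graph_stats(make_graph(3, []))
        tri = graph_stats(make_graph(3, [(0, 1), (1, 2), (0, 2)]))
        with pytest.raises(ValueError):
            espd_tvd(empty, tri)


class TestErgmFit:
    def test_closed_form_at_published_edge_count(self, rng):
        """n=100, E=39: theta = log(39/4911) ~= -4.8358."""
        g = sample_graph_fixed_edges(100, 39, rng)
        theta, se = fit_ergm_edge(g)
        assert theta == pytest.approx(np.log(39 / 4911))
        assert theta == pytest.approx(-4.8357, abs=1e-4)

    def test_half_full_graph_theta_zero(self, rng):
        g = sample_graph_fixed_edges(5, 5, rng)  # N = 10, E = N/2
        theta, _ = fit_ergm_edge(g)
        assert theta == pytest.approx(0.0)

    def test_agrees_with_logistic_regression_oracle(self, rng):
        """Intercept-only logistic fit on the dyad indicators to 1e-8."""
        g = sample_graph_fixed_edges(100, 39, rng)
        y = np.zeros(g.n_dyads)
        y[: g.edge_count] = 1.0
        res = sm.GLM(y, np.ones((g.n_dyads, 1)), family=sm.families.Binomial()).fit()
        theta, se = fit_ergm_edge(g)
        assert theta == pytest.approx(res.params[0], abs=1e-8)
        assert se == pytest.approx(np.sqrt(res.cov_params()[0, 0]), abs=1e-8)

    def test_boundary_edge_counts_rejected(self, rng):
        with pytest.raises(BoundaryMLEError):
            fit_ergm_edge(make_graph(4, []))
        with pytest.raises(BoundaryMLEError):
            fit_ergm_edge(make_graph(3, [(0, 1), (1, 2), (0, 2)]))

    def test_parameter_recovery_coverage(self, rng_factory):
        """Wald CIs cover theta at 95% +- 2% over 2000 replicates."""
        theta0 = np.log(39 / 4911)
        z = stats.norm.ppf(0.975)
        hits = total = 0
        for i in range(2000):
            g = simulate_ctn(100, 39, rng_factory(0, i))
            try:
                theta, se = fit_ergm_edge(g)
            except BoundaryMLEError:
                continue
            hits += abs(theta - theta0) < z * se
            total += 1
        assert total > 1900
        assert abs(hits / total - 0.95) < 0.02


class TestFixedEdgeSampler:
    def test_boundary_cases(self, rng):
        assert sample_graph_fixed_edges(4, 0, rng).edge_count == 0
        assert sample_graph_fixed_edges(4, 6, rng).edge_count == 6

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_graph_fixed_edges(4, 7, rng)

    def test_uniform_over_two_edge_graphs_on_four_nodes(self, rng):
        """Each of the C(6,2)=15 graphs appears with frequency 1/15."""
        counts = {}
        draws = 100_000
        for _ in range(draws):
            g = sample_graph_fixed_edges(4, 2, rng)
            key = tuple(sorted(g.edges))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 15
        p = 1 / 15
        bound = 3 * np.sqrt(p * (1 - p) / draws)
        for c in counts.values():
            assert abs(c / draws - p) < bound


class TestRandomizedResponse:
    def test_huge_epsilon_leaves_graph_unchanged(self, rng):
        g = simulate_ctn(20, 30, rng)
        assert rr_flip(g, 1e3, rng).edges == g.edges

    def test_expected_edge_count_from_empty_graph(self, rng_factory):
        """Empty n=50 graph at eps=1: E[count] = 1225/(1+e) ~= 329.6."""
        counts = [
            rr_flip(make_graph(50, []), 1.0, rng_factory(1, i)).edge_count
            for i in range(1000)
        ]
        expect = 1225 / (1 + np.e)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_debias_identity_at_large_epsilon(self):
        assert rr_debias_edge_count(42, 50, 1e3) == pytest.approx(42.0)

    def test_debias_algebraic_zero(self):
        q = 1 / (1 + np.e)
        n_dyads = 190
        assert rr_debias_edge_count(n_dyads * q, 20, 1.0) == pytest.approx(0.0)

    def test_debias_unbiasedness(self, rng_factory):
        g = simulate_ctn(20, 40, rng_factory(9))
        true_e = g.edge_count
        ests = [
            rr_debias_edge_count(
                rr_flip(g, 1.0, rng_factory(2, i)).edge_count, 20, 1.0
            )
            for i in range(10_000)
        ]
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - true_e) < 3 * se

    def test_zero_epsilon_rejected(self):
        with pytest.raises(ValueError):
            rr_debias_edge_count(10, 20, 0.0)


class TestDpErgmRelease:
    def test_vanishing_noise_reproduces_edge_count(self, rng):
        g = sample_graph_fixed_edges(100, 39, rng)
        rel = dp_ergm_release(g, 1e9, rng, m=1).releases[0]
        assert rel.sanitized_edge_count == 39
        assert rel.surrogate.edge_count == 39

    def test_surrogate_constraint_and_ledger(self, rng):
        g = sample_graph_fixed_edges(50, 80, rng)
        out = dp_ergm_release(g, 2.0, rng, m=3)
        assert out.m == 3
        for rel in out.releases:
            assert rel.surrogate.edge_count == rel.sanitized_edge_count
            assert 0 <= rel.sanitized_edge_count <= g.n_dyads
        assert out.ledger.spent == pytest.approx(2.0)
        assert len(out.ledger.entries) == 6  # two stages per release

    def test_dispersion_decreases_with_epsilon(self, rng_factory):
        g = sample_graph_fixed_edges(100, 39, rng_factory(5))
        sds = []
        for eps in (0.5, 1.0, 2.0, 5.0):
            counts = [
                dp_ergm_release(g, eps, rng_factory(6, i), m=1)
                .releases[0].sanitized_edge_count
                for i in range(200)
            ]
            sds.append(np.std(counts, ddof=1))
        assert all(a > b for a, b in zip(sds, sds[1:]))

    def test_invalid_epsilon(self, rng):
        with pytest.raises(ValueError):
            dp_ergm_release(make_graph(4, [(0, 1)]), 0.0, rng)


class TestSimulateCtn:
    def test_mean_edge_count(self, rng_factory):
        counts = [
            simulate_ctn(100, 39, rng_factory(7, i)).edge_count
            for i in range(1000)
        ]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 39) < 3 * se

    def test_bernoulli_triangle_expectation(self, rng_factory):
        """Expected triangles C(n,3) p^3 for the unclustered generator."""
        import math

        n, e = 30, 60
        p = e / (n * (n - 1) / 2)
        expect = math.comb(n, 3) * p**3
        tris = [
            graph_stats(simulate_ctn(n, e, rng_factory(8, i))).triangle_count
            for i in range(400)
        ]
        se = np.std(tris, ddof=1) / np.sqrt(len(tris))
        assert abs(np.mean(tris) - expect) < 3.5 * se

    def test_clustering_knob_preserves_edges_adds_triangles(self, rng_factory):
        base_tris, clus_tris = [], []
        for i in range(50):
            g0 = simulate_ctn(40, 80, rng_factory(10, i))
            g1 = simulate_ctn(40, 80, rng_factory(10, i), clustering=1.0)
            assert g1.edge_count == g0.edge_count
            base_tris.append(graph_stats(g0).triangle_count)
            clus_tris.append(graph_stats(g1).triangle_count)
        assert np.mean(clus_tris) > np.mean(base_tris)

    def test_two_node_graph(self, rng):
        g = simulate_ctn(2, 0.5, rng)
        assert g.edge_count <= 1
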