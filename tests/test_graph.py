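"""Graph-metric unit and property tests.

Betweenness is checked against an independent exhaustive oracle that
enumerates every simple path between every node pair and credits
shortest paths fractionally.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronnect.graph import (
    CommunityPartition,
    edge_betweenness,
    louvain_partition,
    maslov_sneppen_rewire,
    nodal_betweenness,
    participation_coefficient,
    small_worldness,
    soft_threshold,
)


# ---------------------------------------------------------------- oracle ---


def brute_force_betweenness(w: np.ndarray):
    """Exhaustive shortest-path enumeration on a small weighted graph.

    Lengths are 1/w; returns (nodal, edge) betweenness with unordered
    pairs, endpoints excluded for nodal and included for edge, and
    fractional credit across co-shortest paths.
    """
    n = w.shape[0]
    nodal = np.zeros(n)
    edge = np.zeros((n, n))

    def all_paths(s, t):
        paths = []

        def walk(v, visited, length, path):
            if v == t:
                paths.append((length, tuple(path)))
                return
            for u in range(n):
                if u not in visited and w[v, u] > 0:
                    walk(u, visited | {u}, length + 1.0 / w[v, u], path + [u])

        walk(s, {s}, 0.0, [s])
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            paths = all_paths(s, t)
            if not paths:
                continue
            dmin = min(length for length, _ in paths)
            shortest = [p for length, p in paths if length <= dmin * (1 + 1e-12)]
            credit = 1.0 / len(shortest)
            for p in shortest:
                for v in p[1:-1]:
                    nodal[v] += credit
                for a, b in zip(p[:-1], p[1:]):
                    edge[a, b] += credit
                    edge[b, a] += credit
    return nodal, edge


def random_weighted_graph(rng, n, p_edge=0.5):
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.05, 1.0)
    return w


# ---------------------------------------------------------- soft threshold ---


class TestSoftThreshold:
    def test_fixed_points_and_midpoint(self):
        r = np.array([[1.0, 1.0, -1.0, 0.0],
                      [1.0, 1.0, 0.5, 0.0],
                      [-1.0, 0.5, 1.0, 0.0],
                      [0.0, 0.0, 0.0, 1.0]])
        g = soft_threshold(r, beta=12)
        assert g.weights[0, 1] == 1.0
        assert g.weights[0, 2] == 0.0
        assert g.weights[0, 3] == pytest.approx(2.0**-12)
        assert g.weights[0, 3] == pytest.approx(2.44140625e-4)
        assert np.all(np.diag(g.weights) == 0)

    def test_strict_monotonicity_on_grid(self):
        grid = np.linspace(-1, 1, 201)
        w = ((grid + 1) / 2) ** 12
        assert np.all(np.diff(w) > 0)

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(deadline=None, max_examples=50)
    def test_monotone_property(self, r1, r2):
        if r1 == r2:
            return
        lo, hi = sorted([r1, r2])
        f = lambda r: ((r + 1) / 2) ** 12
        assert f(lo) <= f(hi)

    def test_rejects_out_of_range(self):
        z = np.array([[0.0, 1.4], [1.4, 0.0]])
        with pytest.raises(ValueError, match="tanh"):
            soft_threshold(z)


# ------------------------------------------------------------------ louvain ---


class TestLouvain:
    def test_two_disconnected_cliques(self):
        w = np.zeros((10, 10))
        w[:5, :5] = 0.9
        w[5:, 5:] = 0.9
        np.fill_diagonal(w, 0)
        g = soft_threshold(np.zeros((10, 10)))
        g.weights = w
        part = louvain_partition(g, seed=0)
        assert part.n_communities == 2
        assert len(set(part.assignment[:5])) == 1
        assert len(set(part.assignment[5:])) == 1
        assert set(part.assignment[:5]) != set(part.assignment[5:])

    def test_planted_partition_recovery(self, rng):
        from itertools import combinations

        def nmi(a, b):
            # mutual information between two labelings, normalized
            from math import log
            n = len(a)
            pa = {x: np.mean(a == x) for x in set(a)}
            pb = {y: np.mean(b == y) for y in set(b)}
            mi = 0.0
            for x in pa:
                for y in pb:
                    pxy = np.mean((a == x) & (b == y))
                    if pxy > 0:
                        mi += pxy * log(pxy / (pa[x] * pb[y]))
            ha = -sum(p * log(p) for p in pa.values())
            hb = -sum(p * log(p) for p in pb.values())
            return mi / np.sqrt(ha * hb)

        planted = np.repeat(np.arange(4), 6)
        scores = []
        for s in range(10):
            local = np.random.default_rng(s)
            w = np.zeros((24, 24))
            for i, j in combinations(range(24), 2):
                base = 0.8 if planted[i] == planted[j] else 0.05
                w[i, j] = w[j, i] = base * local.uniform(0.8, 1.2)
            g = soft_threshold(np.zeros((24, 24)))
            g.weights = np.clip(w, 0, 1)
            part = louvain_partition(g, n_runs=10, seed=s)
            scores.append(nmi(planted, part.assignment))
        assert np.mean(scores) >= 0.9

    def test_determinism(self, rng):
        r = np.clip(rng.uniform(-0.5, 0.9, (12, 12)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1)
        g = soft_threshold(r)
        p1 = louvain_partition(g, n_runs=5, seed=3)
        p2 = louvain_partition(g, n_runs=5, seed=3)
        assert np.array_equal(p1.assignment, p2.assignment)
        assert p1.modularity_q == p2.modularity_q

    def test_beats_random_partition(self, rng):
        import networkx as nx
        r = np.clip(rng.uniform(-0.5, 0.9, (16, 16)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1)
        g = soft_threshold(r)
        part = louvain_partition(g, n_runs=5, seed=0)
        gx = nx.from_numpy_array(g.weights)
        rand = [set(range(0, 8)), set(range(8, 16))]
        q_rand = nx.community.modularity(gx, rand, weight="weight")
        assert part.modularity_q >= q_rand


# ---------------------------------------------------------- participation ---


class TestParticipation:
    def _graph(self, w):
        g = soft_threshold(np.zeros_like(w))
        g.weights = w
        return g

    def test_single_community_node(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.5
        part = CommunityPartition(np.array([1, 1, 1, 2]), 2, 0.0)
        pc = participation_coefficient(self._graph(w), part)
        assert pc[0] == 0.0

    def test_even_split_two_and_four(self):
        w = np.zeros((5, 5))
        for j in range(1, 5):
            w[0, j] = w[j, 0] = 0.25
        part2 = CommunityPartition(np.array([1, 1, 1, 2, 2]), 2, 0.0)
        pc2 = participation_coefficient(self._graph(w), part2)
        assert pc2[0] == pytest.approx(0.5)
        part4 = CommunityPartition(np.array([5, 1, 2, 3, 4]), 5, 0.0)
        pc4 = participation_coefficient(self._graph(w), part4)
        assert pc4[0] == pytest.approx(0.75)

    @given(st.integers(2, 5), st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_bounded_by_community_count(self, m, seed):
        local = np.random.default_rng(seed)
        n = 3 * m
        w = np.abs(local.normal(size=(n, n)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        part = CommunityPartition(local.integers(1, m + 1, n), m, 0.0)
        pc = participation_coefficient(self._graph(w), part)
        assert np.all(pc >= 0)
        assert np.all(pc <= 1 - 1 / m + 1e-12)

    def test_isolated_node_gets_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        part = CommunityPartition(np.array([1, 2, 1]), 2, 0.0)
        pc = participation_coefficient(self._graph(w), part)
        assert pc[2] == 0.0


# ------------------------------------------------------------- betweenness ---


def _graph_from_w(w):
    g = soft_threshold(np.zeros_like(w))
    g.weights = w
    return g


class TestBetweenness:
    def test_path_graph(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        nb = nodal_betweenness(_graph_from_w(w))
        assert nb[1] == pytest.approx(1.0)
        assert nb[0] == nb[2] == 0.0
        eb = edge_betweenness(_graph_from_w(w))
        assert eb[0, 1] == pytest.approx(2.0)  # pairs {a,b} and {a,c}
        assert eb[1, 2] == pytest.approx(2.0)

    def test_star_graph(self):
        w = np.zeros((5, 5))
        for leaf in range(1, 5):
            w[0, leaf] = w[leaf, 0] = 0.7
        nb = nodal_betweenness(_graph_from_w(w))
        assert nb[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert np.all(nb[1:] == 0)

    def test_complete_graph_equal_weights(self):
        w = np.full((4, 4), 0.6)
        np.fill_diagonal(w, 0)
        nb = nodal_betweenness(_graph_from_w(w))
        assert np.all(nb == 0)
        eb = edge_betweenness(_graph_from_w(w))
        off = ~np.eye(4, dtype=bool)
        assert np.all(eb[off] == pytest.approx(1.0))

    def test_absent_edge_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        eb = edge_betweenness(_graph_from_w(w))
        assert eb[0, 2] == 0.0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_oracle(self, seed):
        local = np.random.default_rng(seed)
        n = int(local.integers(4, 9))
        w = random_weighted_graph(local, n)
        g = _graph_from_w(w)
        nb = nodal_betweenness(g)
        eb = edge_betweenness(g)
        nb_o, eb_o = brute_force_betweenness(w)
        np.testing.assert_allclose(nb, nb_o, atol=1e-9)
        np.testing.assert_allclose(eb, eb_o, atol=1e-9)


# --------------------------------------------------------- small-worldness ---


class TestSmallWorldness:
    def test_self_null_identity(self):
        import networkx as nx
        g = nx.ring_of_cliques(4, 4)
        a = nx.to_numpy_array(g)
        stats = small_worldness(a, nulls=[g] * 20)
        assert stats.gamma == pytest.approx(1.0)
        assert stats.lam == pytest.approx(1.0)
        assert stats.sigma == pytest.approx(1.0)

    def test_ring_lattice_gamma_above_one(self):
        import networkx as nx
        a = nx.to_numpy_array(nx.watts_strogatz_graph(20, 4, 0.0, seed=1))
        stats = small_worldness(a, n_null=20, seed=4)
        assert stats.gamma > 1.0

    def test_tree_sigma_zero(self):
        import networkx as nx
        a = nx.to_numpy_array(nx.balanced_tree(2, 3))
        stats = small_worldness(a, n_null=20, seed=2)
        assert stats.gamma == 0.0
        assert stats.sigma == 0.0

    def test_sigma_is_exact_ratio(self):
        import networkx as nx
        a = nx.to_numpy_array(nx.erdos_renyi_graph(15, 0.4, seed=9))
        stats = small_worldness(a, n_null=25, seed=5)
        assert stats.sigma == stats.gamma / stats.lam

    def test_rewiring_preserves_degrees(self, rng):
        import networkx as nx
        g = nx.erdos_renyi_graph(12, 0.4, seed=3)
        h = maslov_sneppen_rewire(g, 10 * g.number_of_edges(), rng)
        assert sorted(d for _, d in g.degree()) == sorted(d for _, d in h.degree())
        assert h.number_of_edges() == g.number_of_edges()

    def test_guards(self):
        with pytest.raises(ValueError, match="4 nodes"):
            small_worldness(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="null"):
            small_worldness(np.eye(5), n_null=5)
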