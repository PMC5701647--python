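"""Metric correctness against hand computations and independent oracles.

The brute-force oracle enumerates all simple paths with reciprocal-weight
lengths — an implementation entirely independent of the Dijkstra route
used by the package.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import random_weighted_graph
from hemilat.build import HemiNetwork
from hemilat.metrics import (
    characteristic_path_length_w,
    clustering_coefficient_w,
    compute_global_metrics,
    global_efficiency,
    integrate_over_sparsity,
    local_efficiency,
    nodal_efficiency,
    node_degrees,
    normalize_weights_joint,
    rewire_preserving_degree,
    shortest_paths,
    small_worldness,
)


def brute_force_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by enumerating every simple path."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    nodes = range(n)
    for src, dst in itertools.permutations(nodes, 2):
        best = np.inf
        for k in range(0, n - 1):
            for middle in itertools.permutations(set(nodes) - {src, dst}, k):
                path = (src, *middle, dst)
                length = 0.0
                for a, b in zip(path, path[1:]):
                    if w[a, b] == 0:
                        length = np.inf
                        break
                    length += 1.0 / w[a, b]
                best = min(best, length)
        dist[src, dst] = best
    return dist


def path_graph_3():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 0.5
    return w


class TestShortestPaths:
    def test_single_edge(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert shortest_paths(w).lengths[0, 1] == 1.0

    def test_reciprocal_lengths_on_path(self):
        dm = shortest_paths(path_graph_3())
        assert dm.lengths[0, 1] == 1.0
        assert dm.lengths[1, 2] == 2.0
        assert dm.lengths[0, 2] == 3.0

    def test_indirect_route_beats_weak_shortcut(self):
        w = np.zeros((3, 3))
        w[0, 2] = w[2, 0] = 0.2          # direct length 5
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0          # two-hop length 2
        assert shortest_paths(w).lengths[0, 2] == 2.0

    def test_disconnection_is_represented_not_raised(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        dm = shortest_paths(w)
        assert np.isinf(dm.lengths[0, 2])
        assert dm.n_unreachable_pairs == 4


class TestClustering:
    def test_unit_triangle(self):
        w = np.ones((3, 3)); np.fill_diagonal(w, 0)
        assert clustering_coefficient_w(w) == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert clustering_coefficient_w(w) == 0.0

    def test_weighted_triangle_geometric_mean(self):
        w = np.array([[0, 1, 1], [1, 0, 0.125], [1, 0.125, 0]], dtype=float)
        # every node's term is (1*1*0.125)^(1/3) = 0.5
        assert clustering_coefficient_w(w) == pytest.approx(0.5)

    def test_matches_networkx_onnela(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = random_weighted_graph(12, 0.4, rng)
            if w.max() == 0:
                continue
            wn = w / w.max()
            g = nx.from_numpy_array(wn)
            expected = np.mean(list(nx.clustering(g, weight="weight").values()))
            assert clustering_coefficient_w(wn) == pytest.approx(expected, abs=1e-12)


class TestPathBasedMetrics:
    def test_complete_unit_graph(self):
        w = np.ones((6, 6)); np.fill_diagonal(w, 0)
        dm = shortest_paths(w)
        assert characteristic_path_length_w(dm) == pytest.approx(1.0)
        assert global_efficiency(dm) == pytest.approx(1.0)
        assert np.allclose(nodal_efficiency(dm), 1.0)
        assert local_efficiency(w) == pytest.approx(1.0)

    def test_three_node_path_values(self):
        dm = shortest_paths(path_graph_3())
        assert characteristic_path_length_w(dm) == pytest.approx(2.0)
        assert global_efficiency(dm) == pytest.approx((1 + 0.5 + 1 / 3) / 3)
        assert nodal_efficiency(dm)[1] == pytest.approx(0.75)

    def test_star_and_triangle_local_efficiency(self):
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1.0
        assert local_efficiency(star) == 0.0
        tri = np.ones((3, 3)); np.fill_diagonal(tri, 0)
        assert local_efficiency(tri) == pytest.approx(1.0)

    def test_isolated_node_has_zero_nodal_efficiency(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 2.0
        assert nodal_efficiency(shortest_paths(w))[2] == 0.0

    def test_empty_network_rejected_for_path_length(self):
        with pytest.raises(ValueError, match="empty network"):
            characteristic_path_length_w(shortest_paths(np.zeros((4, 4))))
        assert global_efficiency(shortest_paths(np.zeros((4, 4)))) == 0.0

    def test_adding_an_edge_never_increases_path_length(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            w = random_weighted_graph(8, 0.4, rng, connected=True)
            l0 = characteristic_path_length_w(shortest_paths(w))
            zeros = np.argwhere(np.triu(w == 0, k=1))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = rng.random() + 0.1
            l1 = characteristic_path_length_w(shortest_paths(w2))
            assert l1 <= l0 + 1e-12


class TestOracleEquivalence:
    def test_brute_force_simple_path_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            n = int(rng.integers(3, 7))
            w = random_weighted_graph(n, 0.6, rng, connected=True)
            dm = shortest_paths(w)
            oracle = brute_force_distances(w)
            assert np.allclose(dm.lengths, oracle, atol=1e-10)
            n_pairs = n * (n - 1)
            finite = np.isfinite(oracle) & ~np.eye(n, dtype=bool)
            assert characteristic_path_length_w(dm) == pytest.approx(
                oracle[finite].mean(), abs=1e-10
            )
            inv = np.where(finite, 1.0 / np.where(finite, oracle, 1.0), 0.0)
            assert global_efficiency(dm) == pytest.approx(
                inv.sum() / n_pairs, abs=1e-10
            )
            assert np.allclose(nodal_efficiency(dm), inv.sum(axis=1) / (n - 1), atol=1e-10)


class TestScaleHomogeneityAndBounds:
    @pytest.mark.parametrize("c", [0.5, 2.0, 7.3])
    def test_uniform_scaling(self, c):
        rng = np.random.default_rng(5)
        w = random_weighted_graph(10, 0.5, rng, connected=True)
        w = w / w.max()
        dm, dmc = shortest_paths(w), shortest_paths(c * w)
        assert clustering_coefficient_w(c * w) == pytest.approx(
            c * clustering_coefficient_w(w)
        )
        assert characteristic_path_length_w(dmc) == pytest.approx(
            characteristic_path_length_w(dm) / c
        )
        assert global_efficiency(dmc) == pytest.approx(c * global_efficiency(dm))
        assert local_efficiency(c * w) == pytest.approx(c * local_efficiency(w))
        assert np.allclose(nodal_efficiency(dmc), c * nodal_efficiency(dm))

    def test_bounds_on_normalized_weights(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            w = random_weighted_graph(12, 0.5, rng)
            if w.max() == 0:
                continue
            w = w / w.max()
            dm = shortest_paths(w)
            assert 0 <= clustering_coefficient_w(w) <= 1
            assert 0 <= global_efficiency(dm) <= 1
            assert 0 <= local_efficiency(w) <= 1
            assert np.all((nodal_efficiency(dm) >= 0) & (nodal_efficiency(dm) <= 1))


class TestJointNormalization:
    def test_divides_by_joint_max(self):
        rng = np.random.default_rng(8)
        wl = random_weighted_graph(45, 0.3, rng)
        wr = random_weighted_graph(45, 0.3, rng)
        wl[0, 1] = wl[1, 0] = 4.0  # joint max lives in the left network
        left, right = HemiNetwork(wl, "L"), HemiNetwork(wr, "R")
        nl, nr = normalize_weights_joint(left, right)
        assert np.allclose(nl.weights, wl / 4.0)
        assert np.allclose(nr.weights, wr / 4.0)
        assert nl.normalized and nr.normalized

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        left = HemiNetwork(random_weighted_graph(10, 0.5, rng), "L")
        right = HemiNetwork(random_weighted_graph(10, 0.5, rng), "R")
        nl, nr = normalize_weights_joint(left, right)
        nl2, nr2 = normalize_weights_joint(nl, nr)
        assert np.array_equal(nl.weights, nl2.weights)
        assert np.array_equal(nr.weights, nr2.weights)

    def test_empty_pair_rejected(self):
        z = np.zeros((5, 5))
        with pytest.raises(ValueError, match="empty"):
            normalize_weights_joint(HemiNetwork(z, "L"), HemiNetwork(z, "R"))

    def test_asymmetry_scores_invariant_to_joint_normalization(self, hemi_pair_scaled):
        from hemilat.asymmetry import asymmetry_score

        left, right = hemi_pair_scaled
        nl, nr = normalize_weights_joint(left, right)
        for pair in ((left, right), (nl, nr)):
            gl, gr = compute_global_metrics(pair[0]), compute_global_metrics(pair[1])
            assert asymmetry_score(gr.c_w, gl.c_w) == pytest.approx(
                asymmetry_score(
                    compute_global_metrics(nr).c_w, compute_global_metrics(nl).c_w
                )
            )


class TestRewiring:
    def test_complete_graph_unchanged(self):
        w = np.ones((6, 6)); np.fill_diagonal(w, 0)
        assert np.array_equal(rewire_preserving_degree(w, seed=1), w)

    def test_degree_sequence_and_weights_preserved(self):
        rng = np.random.default_rng(10)
        for trial in range(50):
            w = random_weighted_graph(15, 0.3, rng)
            r = rewire_preserving_degree(w, seed=trial)
            assert np.array_equal(node_degrees(w), node_degrees(r))
            assert np.allclose(np.sort(w[w > 0]), np.sort(r[r > 0]))
            assert np.array_equal(r, r.T)

    def test_connectedness_maintained_when_input_connected(self):
        from hemilat.metrics import is_connected

        rng = np.random.default_rng(11)
        for trial in range(20):
            w = random_weighted_graph(20, 0.25, rng, connected=True)
            assert is_connected(rewire_preserving_degree(w, seed=trial))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(12)
        w = random_weighted_graph(20, 0.3, rng)
        assert np.array_equal(
            rewire_preserving_degree(w, seed=5), rewire_preserving_degree(w, seed=5)
        )


class TestSmallWorldness:
    def test_complete_graph_sigma_exactly_one(self):
        w = np.ones((10, 10)); np.fill_diagonal(w, 0)
        gm = small_worldness(w, n_null=20, seed=1)
        assert gm.gamma == 1.0 and gm.lam == 1.0 and gm.sigma == 1.0

    def test_ring_lattice_is_strongly_clustered(self):
        # ring of 30 nodes, each tied to 4 neighbors: high gamma
        n = 30
        w = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                w[i, j] = w[j, i] = 1.0
        gm = small_worldness(w, n_null=20, seed=2)
        assert gm.gamma > 2.0

    def test_random_graph_sigma_near_one(self):
        rng = np.random.default_rng(13)
        sigmas = []
        for trial in range(5):
            w = random_weighted_graph(45, 0.2, rng, connected=True)
            sigmas.append(small_worldness(w, n_null=20, seed=trial).sigma)
        assert 0.8 < np.mean(sigmas) < 1.25

    def test_sigma_invariant_under_weight_scaling(self):
        rng = np.random.default_rng(14)
        w = random_weighted_graph(20, 0.3, rng, connected=True)
        a = small_worldness(w, n_null=10, seed=3)
        b = small_worldness(5.0 * w, n_null=10, seed=3)
        assert a.sigma == pytest.approx(b.sigma, rel=1e-9)


class TestSparsityIntegration:
    def test_constant_curve(self):
        assert integrate_over_sparsity(
            [2.5] * 5, np.linspace(0.1, 0.35, 5)
        ) == pytest.approx(2.5)

    def test_linear_ramp_gives_midpoint(self):
        assert integrate_over_sparsity([0.0, 1.0], [0.1, 0.35]) == pytest.approx(0.5)

    def test_invariant_to_level_order(self):
        values = [1.0, 3.0, 2.0]
        levels = [0.1, 0.2, 0.3]
        forward = integrate_over_sparsity(values, levels)
        backward = integrate_over_sparsity(values[::-1], levels[::-1])
        assert forward == pytest.approx(backward)

    def test_single_level_returns_value(self):
        assert integrate_over_sparsity([7.0], [0.2]) == 7.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            integrate_over_sparsity([1.0, 2.0], [0.1])
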