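import numpy as np
import pytest

from sdconnectome.io import Connectome
from sdconnectome.metrics import (
    DisconnectedGraphError,
    characteristic_path_length,
    clustering_coefficient,
    degree_distribution,
    distance_matrix,
    global_efficiency,
    local_efficiency,
    network_strength,
    nodal_efficiency,
    small_world_metrics,
)
from conftest import random_connectome


def floyd_warshall_oracle(w: np.ndarray) -> np.ndarray:
    """Brute-force all-pairs shortest paths on reciprocal lengths."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def onnela_clustering_oracle(w: np.ndarray) -> np.ndarray:
    """Triple-loop Onnela clustering with network-max normalization."""
    n = w.shape[0]
    wh = w / w.max() if w.max() > 0 else w
    c = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
        c[i] = s / (k * (k - 1))
    return c


class TestDistances:
    def test_single_edge_reciprocal(self):
        conn = Connectome(np.array([[0.0, 2], [2, 0]]))
        assert distance_matrix(conn)[0, 1] == pytest.approx(0.5)

    def test_indirect_path_beats_direct(self):
        w = np.zeros((3, 3))
        w[0, 1], w[0, 2], w[2, 1] = 1, 4, 4
        w += w.T
        # direct 0-1 has length 1; 0-2-1 has length 1/4 + 1/4 = 1/2
        assert distance_matrix(Connectome(w))[0, 1] == pytest.approx(0.5)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(30):
            conn = random_connectome(rng, 8, density=0.4)
            np.testing.assert_allclose(
                distance_matrix(conn), floyd_warshall_oracle(conn.weights)
            )


class TestStrength:
    def test_two_nodes(self):
        assert network_strength(Connectome(np.array([[0.0, 3], [3, 0]]))) == 3

    def test_triangle_hand_value(self, triangle_135):
        assert network_strength(triangle_135) == pytest.approx(4.0)

    def test_zero_matrix(self):
        assert network_strength(Connectome(np.zeros((4, 4)))) == 0


class TestGlobalEfficiency:
    def test_two_nodes_unit(self):
        assert global_efficiency(Connectome(np.array([[0.0, 1], [1, 0]]))) == 1

    def test_path3_hand_value(self, path3):
        # pairs: 0-1,1-2 at distance 1 and 0-2 at distance 2 -> mean inverse 5/6
        assert global_efficiency(path3) == pytest.approx(5 / 6)

    def test_disconnected_pair_contributes_zero(self):
        assert global_efficiency(Connectome(np.zeros((2, 2)))) == 0


class TestLocalEfficiency:
    def test_unit_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert local_efficiency(Connectome(w)) == pytest.approx(1.0)

    def test_star_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = 1
        w += w.T
        assert local_efficiency(Connectome(w)) == 0

    def test_matches_subgraph_oracle(self, rng):
        for _ in range(10):
            conn = random_connectome(rng, 8, density=0.5)
            w = conn.weights
            total = 0.0
            for i in range(8):
                nbrs = np.nonzero(w[i])[0]
                if nbrs.size < 2:
                    continue
                d = floyd_warshall_oracle(w[np.ix_(nbrs, nbrs)])
                inv = np.where(np.isfinite(d) & (d > 0), 1 / np.where(d > 0, d, 1), 0)
                total += inv.sum() / (nbrs.size * (nbrs.size - 1))
            assert local_efficiency(conn) == pytest.approx(total / 8)


class TestPathLength:
    def test_two_nodes(self):
        assert characteristic_path_length(Connectome(np.array([[0.0, 2], [2, 0]]))) == 0.5

    def test_path3_hand_value(self, path3):
        assert characteristic_path_length(path3) == pytest.approx(8 / 6)

    def test_disconnected_warns_and_averages_finite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1
        with pytest.warns(UserWarning, match="unreachable"):
            lp = characteristic_path_length(Connectome(w))
        assert lp == pytest.approx(1.0)
        with pytest.raises(DisconnectedGraphError):
            characteristic_path_length(Connectome(w), on_disconnected="raise")

    def test_fully_disconnected_raises(self):
        with pytest.raises(DisconnectedGraphError):
            characteristic_path_length(Connectome(np.zeros((3, 3))))


class TestClustering:
    def test_equal_triangle_maximal(self):
        w = 2 * (np.ones((3, 3)) - np.eye(3))
        cp, c = clustering_coefficient(Connectome(w))
        assert cp == pytest.approx(1.0)
        np.testing.assert_allclose(c, 1.0)

    def test_path_zero(self, path3):
        assert clustering_coefficient(path3)[0] == 0

    def test_weighted_triangle_hand_value(self):
        w = np.zeros((3, 3))
        w[0, 1], w[0, 2], w[1, 2] = 1, 2, 4
        w += w.T
        _, c = clustering_coefficient(Connectome(w))
        np.testing.assert_allclose(c, 0.5)  # (0.25 * 0.5 * 1.0) ** (1/3)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(10):
            conn = random_connectome(rng, 8, density=0.5)
            _, c = clustering_coefficient(conn)
            np.testing.assert_allclose(c, onnela_clustering_oracle(conn.weights))

    def test_matches_networkx_onnela(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(5):
            conn = random_connectome(rng, 10, density=0.4)
            g = nx.from_numpy_array(conn.weights)
            expected = np.array([nx.clustering(g, weight="weight")[i] for i in range(10)])
            np.testing.assert_allclose(clustering_coefficient(conn)[1], expected)


class TestNodalEfficiency:
    def test_path3_hand_values(self, path3):
        np.testing.assert_allclose(nodal_efficiency(path3), [0.75, 1.0, 0.75])

    def test_mean_equals_global_efficiency(self, rng):
        conn = random_connectome(rng, 9, density=0.4)
        assert nodal_efficiency(conn).mean() == pytest.approx(global_efficiency(conn))


class TestDegreeDistribution:
    def test_regular_graph_zero_skew(self):
        w = np.ones((6, 6)) - np.eye(6)
        assert degree_distribution(Connectome(w))[2] == 0

    def test_star_positive_skew(self):
        w = np.zeros((8, 8))
        w[0, 1:] = 1
        w += w.T
        assert degree_distribution(Connectome(w))[2] > 0

    def test_empty_graph(self):
        k, counts, g = degree_distribution(Connectome(np.zeros((4, 4))))
        assert np.all(k == 0) and g == 0


class TestProperties:
    def test_scale_behavior(self, rng):
        conn = random_connectome(rng, 8, density=0.6)
        scaled = Connectome(conn.weights * 3.0)
        assert characteristic_path_length(scaled) == pytest.approx(
            characteristic_path_length(conn) / 3
        )
        assert global_efficiency(scaled) == pytest.approx(3 * global_efficiency(conn))
        assert clustering_coefficient(scaled)[0] == pytest.approx(
            clustering_coefficient(conn)[0]
        )
        np.testing.assert_array_equal(
            degree_distribution(scaled)[0], degree_distribution(conn)[0]
        )

    def test_permutation_equivariance(self, rng):
        conn = random_connectome(rng, 8, density=0.6)
        perm = rng.permutation(8)
        permuted = Connectome(conn.weights[np.ix_(perm, perm)])
        np.testing.assert_allclose(
            nodal_efficiency(permuted), nodal_efficiency(conn)[perm]
        )
        assert global_efficiency(permuted) == pytest.approx(global_efficiency(conn))
        assert local_efficiency(permuted) == pytest.approx(local_efficiency(conn))

    def test_efficiency_weakly_increases_with_weight(self, rng):
        conn = random_connectome(rng, 8, density=0.6)
        before = global_efficiency(conn)
        w = conn.weights.copy()
        iu, ju = np.nonzero(np.triu(w, 1))
        w[iu[0], ju[0]] += 10
        w[ju[0], iu[0]] += 10
        assert global_efficiency(Connectome(w)) >= before


class TestSmallWorld:
    def test_self_ensemble_normalizes_to_one(self, rng):
        conn = random_connectome(rng, 8, density=0.6)
        g, l = small_world_metrics(conn, [conn, conn])
        assert g == pytest.approx(1.0)
        assert l == pytest.approx(1.0)

    def test_complete_graph_rewiring_invariant(self, rng):
        from sdconnectome.nulls import matched_ensemble

        w = np.ones((6, 6)) - np.eye(6)
        conn = Connectome(w)
        g, l = small_world_metrics(conn, matched_ensemble(conn, n=5, seed=1))
        assert g == pytest.approx(1.0)
        assert l == pytest.approx(1.0)

    def test_empty_ensemble_rejected(self, rng):
        with pytest.raises(ValueError):
            small_world_metrics(random_connectome(rng, 5), [])
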