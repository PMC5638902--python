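"""Network construction pipeline and graph metrics, against hand oracles."""

import numpy as np
import pytest

from pvcnet import (
    ConnectivityMatrix,
    IntensityMatrix,
    Partition,
    betweenness_centrality,
    clustering_coefficient,
    correlation_network,
    degree_and_density,
    global_efficiency,
    maximize_modularity,
    modularity,
    normalize_and_threshold,
    standardize_columns,
)
from pvcnet.network import _partitions_rgs, betweenness_ranking


def _intensity(values):
    values = np.asarray(values, dtype=float)
    return IntensityMatrix(
        values=values,
        region_labels=np.arange(1, len(values) + 1),
        subject_ids=[f"s{i}" for i in range(values.shape[1])],
    )


def _thr(W):
    return ConnectivityMatrix(np.asarray(W, dtype=float), "thresholded")


def _graph(n, edges):
    W = np.zeros((n, n))
    for i, j in edges:
        W[i, j] = W[j, i] = 1.0
    return _thr(W)


class TestCorrelationNetwork:
    def test_identical_rows_correlate_fully(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        net = correlation_network(_intensity([base, base * 2, base + 1]))
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.stage == "clipped"

    def test_anticorrelation_clipped_to_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        net = correlation_network(_intensity([x, -x, x + 0.5]))
        assert net.weights[0, 1] == 0.0

    def test_matches_pearson_definition(self):
        rng = np.random.default_rng(0)
        vals = rng.random((3, 4))
        net = correlation_network(_intensity(vals))
        for i in range(3):
            for j in range(3):
                xi, xj = vals[i], vals[j]
                r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (
                    np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
                )
                assert net.weights[i, j] == pytest.approx(max(r, 0.0), abs=1e-12)

    def test_zero_variance_row_named(self):
        with pytest.raises(ValueError, match="2"):
            correlation_network(_intensity([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))


class TestStandardizeColumns:
    def test_hand_computed_column(self):
        net = ConnectivityMatrix(
            np.array([[1.0, 0.0, 2.0], [2.0, 0.5, 4.0], [3.0, 1.0, 9.0]]), "clipped"
        )
        # column (1,2,3) with sample SD 1 -> (-1, 0, 1)
        z = standardize_columns(net)
        assert np.allclose(z.weights[:, 0], [-1.0, 0.0, 1.0])
        assert z.stage == "zscored"

    def test_postconditions_random(self):
        rng = np.random.default_rng(1)
        z = standardize_columns(ConnectivityMatrix(rng.random((8, 8)), "clipped"))
        assert np.abs(z.weights.mean(axis=0)).max() < 1e-12
        assert np.abs(z.weights.std(axis=0, ddof=1) - 1.0).max() < 1e-12

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        z1 = standardize_columns(ConnectivityMatrix(rng.random((6, 6)), "clipped"))
        z2 = standardize_columns(ConnectivityMatrix(z1.weights, "clipped"))
        assert np.allclose(z1.weights, z2.weights, atol=1e-12)

    def test_constant_column_rejected(self):
        W = np.ones((4, 4))
        with pytest.raises(ValueError):
            standardize_columns(ConnectivityMatrix(W, "clipped"))


class TestNormalizeAndThreshold:
    def test_bounds(self):
        rng = np.random.default_rng(3)
        net = ConnectivityMatrix(rng.random((6, 6)), "zscored")
        full = normalize_and_threshold(net, p=1.0)
        off = full.weights[np.triu_indices(6, 1)]
        assert (off != 0).sum() == 15
        empty = normalize_and_threshold(net, p=0.0)
        assert (empty.weights == 0).all()

    def test_max_surviving_entry_is_one(self):
        rng = np.random.default_rng(4)
        W = rng.random((10, 10))
        W = (W + W.T) / 2
        net = normalize_and_threshold(ConnectivityMatrix(W, "zscored"), p=0.3)
        assert net.weights.max() == pytest.approx(1.0)

    def test_90_nodes_p01_keeps_400_edges(self):
        rng = np.random.default_rng(5)
        W = rng.random((90, 90))
        W = (W + W.T) / 2
        net = normalize_and_threshold(ConnectivityMatrix(W, "zscored"), p=0.1)
        n_edges = (net.weights[np.triu_indices(90, 1)] != 0).sum()
        assert n_edges == 400  # floor(0.1 * 90*89/2)

    def test_symmetric_nonnegative_zero_diagonal(self):
        rng = np.random.default_rng(6)
        net = normalize_and_threshold(
            ConnectivityMatrix(rng.normal(size=(12, 12)), "zscored"), p=0.2
        )
        assert np.allclose(net.weights, net.weights.T)
        assert (net.weights >= 0).all()
        assert np.diag(net.weights).max() == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_threshold(ConnectivityMatrix(np.zeros((4, 4)), "zscored"))


class TestDegreeDensityEfficiency:
    def test_triangle(self):
        net = _graph(3, [(0, 1), (1, 2), (0, 2)])
        deg, d = degree_and_density(net)
        assert list(deg) == [2, 2, 2]
        assert d == 1.0
        assert global_efficiency(net) == pytest.approx(1.0)

    def test_density_arithmetic(self):
        net = _graph(4, [(0, 1), (1, 2), (2, 3)])
        _, d = degree_and_density(net)
        assert d == pytest.approx(0.5)  # 2*3 / (16-4)

    def test_empty_graph(self):
        net = _thr(np.zeros((4, 4)))
        deg, d = degree_and_density(net)
        assert d == 0.0 and deg.sum() == 0
        assert global_efficiency(net) == 0.0

    def test_three_node_path_efficiency(self):
        """Distances 1,1,2 -> mean inverse = (1+1+0.5)/3 = 5/6."""
        net = _graph(3, [(0, 1), (1, 2)])
        assert global_efficiency(net) == pytest.approx(5.0 / 6.0)

    def test_stage_guard(self):
        with pytest.raises(ValueError):
            degree_and_density(ConnectivityMatrix(np.eye(3), "clipped"))


class TestClustering:
    def test_binary_triangle(self):
        assert clustering_coefficient(
            _graph(3, [(0, 1), (1, 2), (0, 2)]), variant="binary"
        ) == pytest.approx(1.0)

    def test_star_graph(self):
        star = _graph(5, [(0, i) for i in range(1, 5)])
        assert clustering_coefficient(star) == 0.0

    def test_weighted_matches_triangle_enumeration(self):
        """4-node weighted toy vs brute-force geometric-mean triangle count."""
        W = np.array(
            [
                [0.0, 0.8, 0.4, 0.0],
                [0.8, 0.0, 1.0, 0.2],
                [0.4, 1.0, 0.0, 0.6],
                [0.0, 0.2, 0.6, 0.0],
            ]
        )
        got = clustering_coefficient(_thr(W))
        What = W / W.max()
        n = 4
        cs = []
        for i in range(n):
            ki = (W[i] > 0).sum()
            if ki < 2:
                cs.append(0.0)
                continue
            tri = 0.0
            for j in range(n):
                for k in range(n):
                    tri += (What[i, j] * What[i, k] * What[j, k]) ** (1.0 / 3.0)
            cs.append(tri / (ki * (ki - 1)))
        assert got == pytest.approx(np.mean(cs), abs=1e-12)


class TestBetweenness:
    def test_complete_graph_zero(self):
        net = _graph(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert np.allclose(betweenness_centrality(net), 0.0)

    def test_path_center(self):
        net = _graph(3, [(0, 1), (1, 2)])
        assert betweenness_centrality(net)[1] == pytest.approx(1.0)

    def test_star_center(self):
        net = _graph(5, [(0, i) for i in range(1, 5)])
        bc = betweenness_centrality(net)
        assert bc[0] == pytest.approx(1.0)
        assert np.allclose(bc[1:], 0.0)
        ranking = betweenness_ranking(net)
        assert ranking[0][0] == 1  # node label of the hub


class TestModularity:
    def test_single_module_zero(self):
        net = _graph(4, [(0, 1), (1, 2), (2, 3)])
        assert modularity(net, Partition(np.zeros(4))) == pytest.approx(0.0)

    def test_two_triangles_half(self):
        net = _graph(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        q = modularity(net, Partition([0, 0, 0, 1, 1, 1]))
        assert q == pytest.approx(0.5)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(7)
        W = (rng.random((10, 10)) > 0.6).astype(float)
        W = np.triu(W, 1)
        W = W + W.T
        if not W.any():
            W[0, 1] = W[1, 0] = 1.0
        net = _thr(W)
        for _ in range(20):
            q = modularity(net, Partition(rng.integers(0, 4, size=10)))
            assert q <= 1.0

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            modularity(_thr(np.zeros((3, 3))), Partition([0, 0, 0]))


def _brute_force_max_q(net):
    """Independent exhaustive enumeration over all set partitions."""
    W = net.weights
    n = len(W)
    B = (W != 0).astype(int)
    P = B[np.triu_indices(n, 1)].sum()
    deg = B.sum(axis=1)
    best = -np.inf
    for assign in _enumerate_partitions(n):
        q = 0.0
        for mod in set(assign):
            mem = [i for i in range(n) if assign[i] == mod]
            p_i = sum(B[i, j] for i in mem for j in mem) / 2
            d_i = sum(deg[i] for i in mem)
            q += p_i / P - (d_i / (2 * P)) ** 2
        best = max(best, q)
    return best


def _enumerate_partitions(n):
    """Recursive set-partition generator (independent of the package's)."""
    if n == 1:
        yield [0]
        return
    for smaller in _enumerate_partitions(n - 1):
        k = max(smaller) + 1
        for mod in range(k + 1):
            yield smaller + [mod]


class TestMaximizeModularity:
    def test_two_cliques_recovered(self):
        net = _graph(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part, q = maximize_modularity(net, seed=0)
        assert q == pytest.approx(0.5)
        assert part.assignment[0] == part.assignment[1] == part.assignment[2]
        assert part.assignment[3] == part.assignment[4] == part.assignment[5]
        assert part.assignment[0] != part.assignment[3]

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_matches_exhaustive_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        W = (rng.random((n, n)) > 0.5).astype(float)
        W = np.triu(W, 1)
        W = W + W.T
        if not W.any():
            W[0, 1] = W[1, 0] = 1.0
        net = _thr(W)
        _, q = maximize_modularity(net, seed=seed)
        assert abs(q - _brute_force_max_q(net)) < 1e-12

    def test_greedy_regime_near_enumeration_optimum(self):
        """Above the exact regime (n > 8) the heuristic is a valid lower
        bound and lands close to the exhaustive optimum."""
        rng = np.random.default_rng(9)
        W = (rng.random((10, 10)) > 0.65).astype(float)
        W = np.triu(W, 1)
        W = W + W.T
        net = _thr(W)
        _, q = maximize_modularity(net, seed=3)
        best = _brute_force_max_q(net)
        assert q <= best + 1e-12
        assert q >= 0.9 * best

    def test_determinism(self):
        rng = np.random.default_rng(8)
        W = (rng.random((12, 12)) > 0.6).astype(float)
        W = np.triu(W, 1) + np.triu(W, 1).T
        net = _thr(W)
        p1, q1 = maximize_modularity(net, seed=11)
        p2, q2 = maximize_modularity(net, seed=11)
        assert np.array_equal(p1.assignment, p2.assignment)
        assert q1 == q2

    def test_returned_value_consistent(self):
        rng = np.random.default_rng(10)
        W = (rng.random((9, 9)) > 0.5).astype(float)
        W = np.triu(W, 1) + np.triu(W, 1).T
        net = _thr(W)
        part, q = maximize_modularity(net, seed=0)
        assert q == pytest.approx(modularity(net, part), abs=1e-12)


def test_pipeline_stage_order_enforced():
    """Stages carry tags so misordering is detectable."""
    rng = np.random.default_rng(11)
    mat = _intensity(rng.random((6, 8)))
    net = correlation_network(mat)
    assert net.stage == "clipped"
    z = standardize_columns(net)
    assert z.stage == "zscored"
    thr = normalize_and_threshold(z, 0.2)
    assert thr.stage == "thresholded"
    with pytest.raises(ValueError):
        global_efficiency(z)  # metrics refuse non-thresholded input
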