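import itertools

import numpy as np
import pytest

from netlyze import netgraph
from netlyze.io_events import LocalizationSet
from netlyze.partition import Roi


def graph_from_edges(n, edges, d=50.0):
    ed = np.array(sorted(map(tuple, map(sorted, edges))), dtype=np.int64)
    ed = ed.reshape(-1, 2)
    return netgraph.ProximityGraph(n=n, edges=ed,
                                   dists=np.full(len(ed), d),
                                   threshold_T=80.0)


def set_partitions(elems):
    """All partitions of a list (for the brute-force modularity oracle)."""
    if not elems:
        yield []
        return
    first, rest = elems[0], elems[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1:]
        yield [[first]] + p


def brute_force_max_modularity(g):
    best = -np.inf
    for p in set_partitions(list(range(g.n))):
        a = np.zeros(g.n, dtype=int)
        for i, grp in enumerate(p):
            a[grp] = i
        best = max(best, netgraph.modularity(g, a))
    return best


class TestBuildGraph:
    def test_triangle_complete(self, triangle_points):
        g = netgraph.build_graph(triangle_points, 80.0)
        assert g.m == 3
        np.testing.assert_array_equal(
            netgraph.node_measures(g)["uw_degree"], [2, 2, 2])

    def test_no_edge_beyond_threshold(self):
        g = netgraph.build_graph(np.array([[0.0, 0, 0], [100.0, 0, 0]]), 80.0)
        assert g.m == 0

    def test_weight_is_inverse_distance(self):
        g = netgraph.build_graph(np.array([[0.0, 0, 0], [50.0, 0, 0]]), 80.0,
                                 mode="weighted")
        assert g.weights[0] == pytest.approx(0.02)

    def test_coincident_points_weight_capped(self):
        g = netgraph.build_graph(np.zeros((2, 3)), 80.0, mode="weighted")
        assert np.isfinite(g.weights).all()
        assert g.weights[0] == pytest.approx(1.0)

    def test_threshold_monotonicity(self, rng):
        pts = rng.uniform(0, 500, size=(60, 3))
        edges = {}
        for T in (40.0, 80.0, 160.0):
            g = netgraph.build_graph(pts, T)
            edges[T] = set(map(tuple, g.edges))
        assert edges[40.0] <= edges[80.0] <= edges[160.0]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            netgraph.build_graph(np.zeros((2, 3)), -5.0)
        with pytest.raises(ValueError):
            netgraph.build_graph(np.zeros((2, 3)), 10.0, mode="both")


class TestNodeMeasures:
    def test_triangle(self, triangle_points):
        g = netgraph.build_graph(triangle_points, 80.0)
        nm = netgraph.node_measures(g)
        np.testing.assert_allclose(nm["uw_ndeg"], [2, 2, 2])
        np.testing.assert_allclose(nm["uw_cc"], [1, 1, 1])
        np.testing.assert_allclose(nm["w_degree"], [0.04, 0.04, 0.04])

    def test_path_graph(self):
        pts = np.array([[0.0, 0, 0], [50.0, 0, 0], [100.0, 0, 0]])
        g = netgraph.build_graph(pts, 60.0)
        nm = netgraph.node_measures(g)
        np.testing.assert_array_equal(nm["uw_degree"], [1, 2, 1])
        assert nm["uw_cc"][1] == 0.0
        assert nm["uw_ndeg"][0] == 2.0

    def test_isolated_node_zero(self):
        pts = np.array([[0.0, 0, 0], [5000.0, 0, 0]])
        g = netgraph.build_graph(pts, 80.0)
        nm = netgraph.node_measures(g)
        assert np.all(nm["uw_ndeg"] == 0)
        assert np.all(nm["uw_cc"] == 0)

    def test_barrat_cc_equals_unweighted_for_equal_weights(
            self, triangle_points):
        g = netgraph.build_graph(triangle_points, 80.0)
        nm = netgraph.node_measures(g)
        np.testing.assert_allclose(nm["w_cc"], nm["uw_cc"])

    def test_weighted_degree_is_sum_of_inverse_distances(self, rng):
        pts = rng.uniform(0, 200, size=(20, 3))
        g = netgraph.build_graph(pts, 150.0)
        nm = netgraph.node_measures(g)
        i = 3
        expected = sum(1.0 / max(d, 1.0)
                       for (a, b), d in zip(g.edges, g.dists)
                       if i in (a, b))
        assert nm["w_degree"][i] == pytest.approx(expected)


class TestGraphMeasures:
    def test_triangle_char_path(self, triangle_points):
        g = netgraph.build_graph(triangle_points, 80.0)
        gm = netgraph.graph_measures(g)
        assert gm["char_path"] == pytest.approx(1.0)
        assert gm["n_components"] == 1.0

    def test_two_disjoint_triangles(self, triangle_points):
        pts = np.vstack([triangle_points, triangle_points + 10_000.0])
        g = netgraph.build_graph(pts, 80.0)
        gm = netgraph.graph_measures(g)
        assert gm["n_components"] == 2.0
        assert gm["char_path"] == pytest.approx(1.0)  # connected pairs only
        assert gm["largest_comp_frac"] == pytest.approx(0.5)

    def test_single_node_degenerate(self):
        g = netgraph.build_graph(np.zeros((1, 3)), 80.0)
        gm = netgraph.graph_measures(g)
        assert gm["char_path"] == 0.0
        assert gm["node_count"] == 1.0

    def test_weighted_char_path_uses_distance(self):
        pts = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        g = netgraph.build_graph(pts, 80.0)
        gm = netgraph.graph_measures(g, weighted=True)
        assert gm["char_path"] == pytest.approx(50.0)

    def test_density_complete_graph(self, triangle_points):
        g = netgraph.build_graph(triangle_points, 80.0)
        assert netgraph.graph_measures(g)["density"] == pytest.approx(1.0)


class TestNewmanPartition:
    def test_complete_graph_one_module(self):
        g = graph_from_edges(5, itertools.combinations(range(5), 2))
        part = netgraph.newman_partition(g)
        assert part.n_modules == 1
        assert part.Q == pytest.approx(0.0)

    def test_two_cliques_two_modules(self):
        edges = (list(itertools.combinations(range(4), 2))
                 + list(itertools.combinations(range(4, 8), 2)) + [(3, 4)])
        g = graph_from_edges(8, edges)
        part = netgraph.newman_partition(g)
        assert part.n_modules == 2
        assert part.Q == pytest.approx(brute_force_max_modularity(g))
        # the two cliques are the modules
        assert len(set(part.assignment[:4])) == 1
        assert len(set(part.assignment[4:])) == 1

    def test_ring_of_three_cliques(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5),
                 (6, 7), (7, 8), (6, 8), (2, 3), (5, 6), (8, 0)]
        g = graph_from_edges(9, edges)
        part = netgraph.newman_partition(g)
        assert part.n_modules == 3
        assert part.Q >= 0.9 * brute_force_max_modularity(g)

    def test_six_node_two_triangles(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        g = graph_from_edges(6, edges)
        part = netgraph.newman_partition(g)
        assert part.n_modules == 2
        assert part.Q == pytest.approx(brute_force_max_modularity(g))

    def test_near_optimal_on_random_small_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            pts = rng.uniform(0, 200, size=(n, 3))
            g = netgraph.build_graph(pts, 100.0)
            if g.m == 0:
                continue
            qmax = brute_force_max_modularity(g)
            part = netgraph.newman_partition(g)
            assert part.Q >= 0.9 * qmax - 1e-12
            assert part.Q >= -1e-12  # never worse than the trivial partition

    def test_empty_graph_errors(self):
        g = netgraph.build_graph(np.zeros((0, 3)), 80.0)
        with pytest.raises(ValueError):
            netgraph.newman_partition(g)

    def test_modularity_of_trivial_partition_zero(self, triangle_points):
        g = netgraph.build_graph(triangle_points, 80.0)
        assert netgraph.modularity(g, np.zeros(3, int)) == pytest.approx(0.0)


class TestRandomPointsLike:
    def _roi(self, rng, n=1000):
        lo = np.array([0.0, 0, 0])
        hi = np.array([3000.0, 3000, 1000])
        pts = np.column_stack([
            rng.uniform(0, 3000, n), rng.uniform(0, 3000, n),
            rng.normal(500, 120, n)])
        return Roi(bounds=np.array([lo, hi]),
                   points=LocalizationSet(points=pts))

    def test_count_and_xy_bounds(self, rng):
        roi = self._roi(rng)
        out = netgraph.random_points_like(roi, seed=3)
        assert len(out) == 1000
        assert out[:, 0].min() >= 0 and out[:, 0].max() <= 3000
        assert out[:, 1].min() >= 0 and out[:, 1].max() <= 3000

    def test_z_moments_match(self, rng):
        roi = self._roi(rng, n=10_000)
        out = netgraph.random_points_like(roi, seed=3)
        z_in = roi.points.points[:, 2]
        se = z_in.std() / np.sqrt(len(z_in))
        assert abs(out[:, 2].mean() - z_in.mean()) < 4 * se
        assert abs(out[:, 2].std() - z_in.std()) < 5 * se

    def test_seeded_reproducibility(self, rng):
        roi = self._roi(rng)
        a = netgraph.random_points_like(roi, seed=11)
        b = netgraph.random_points_like(roi, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_too_few_points_errors(self):
        roi = Roi(bounds=np.array([[0.0, 0, 0], [1.0, 1, 1]]),
                  points=LocalizationSet(points=np.zeros((1, 3))))
        with pytest.raises(ValueError):
            netgraph.random_points_like(roi, seed=0)
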