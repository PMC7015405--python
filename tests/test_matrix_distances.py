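import numpy as np
import pytest
import scipy.stats

from netdist import (
    Graph,
    deltacon,
    edit_distance,
    fbp_matrix,
    permute,
    renormalized_resistance_matrix,
    resistance_distance,
    resistance_matrix,
    rp_single_edge_closed_form,
)
from netdist.errors import (
    DisconnectedGraphError,
    GraphValidationError,
    SizeMismatchError,
)
from netdist.matrix_distances import _rp_direct, default_epsilon

from conftest import random_connected_graph, random_graph


class TestEditDistance:
    def test_one_edge_difference_counts_twice(self, k3, p3):
        assert edit_distance(k3, p3) == 2.0

    def test_identical_graphs(self, k3):
        assert edit_distance(k3, k3) == 0.0

    def test_size_mismatch_rejected(self, k3):
        with pytest.raises(SizeMismatchError, match="node correspondence"):
            edit_distance(k3, Graph(4))

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_twice_symmetric_difference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        g, h = random_graph(rng, n, 0.4), random_graph(rng, n, 0.4)
        sym_diff = len(set(g.edges) ^ set(h.edges))
        assert edit_distance(g, h) == 2 * sym_diff

    def test_weighted_graphs_sum_absolute_weight_differences(self):
        g = Graph(3, {(0, 1): 2.0, (1, 2): 1.0})
        h = Graph(3, {(0, 1): 0.5, (0, 2): 3.0})
        # ordered-pair sum: 2*(|2-0.5| + |1-0| + |0-3|)
        assert edit_distance(g, h) == pytest.approx(2 * (1.5 + 1.0 + 3.0))


class TestResistanceMatrix:
    def test_path_series_law(self, p3):
        r = resistance_matrix(p3).values
        assert r[0, 1] == pytest.approx(1)
        assert r[1, 2] == pytest.approx(1)
        assert r[0, 2] == pytest.approx(2)

    def test_triangle_parallel_law(self, k3):
        r = resistance_matrix(k3).values
        off = r[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 2 / 3)

    def test_disconnected_rejected_with_pointer(self):
        g = Graph.from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(DisconnectedGraphError, match="renormalized"):
            resistance_matrix(g)

    @pytest.mark.parametrize("seed", range(10))
    def test_tree_resistance_equals_path_length(self, seed):
        import networkx as nx

        t = nx.random_labeled_tree(12, seed=seed)
        g = Graph.from_networkx(t)
        r = resistance_matrix(g).values
        sp = dict(nx.all_pairs_shortest_path_length(t))
        for u in range(12):
            for v in range(12):
                assert r[u, v] == pytest.approx(sp[u][v], abs=1e-8)

    @pytest.mark.parametrize("seed", range(100))
    def test_resistance_is_a_vertex_metric(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 31))
        g = random_connected_graph(rng, n, 0.2)
        r = resistance_matrix(g).values
        assert np.all(r >= -1e-10)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 0)
        # triangle inequality R(u,w) <= R(u,v) + R(v,w)
        viol = r[:, None, :] - (r[:, :, None] + r[None, :, :])
        assert viol.max() <= 1e-8


class TestResistanceDistance:
    def test_path_vs_triangle(self, p3, k3):
        # |dR| entries: (0,1): 1/3, (1,2): 1/3, (0,2): 4/3; doubled -> 4
        assert resistance_distance(p3, k3) == pytest.approx(4.0)

    def test_identical_graphs(self, k3):
        assert resistance_distance(k3, k3) == pytest.approx(0, abs=1e-10)

    def test_depends_on_node_correspondence(self):
        # asymmetric 5-vertex tree: relabeling changes pairwise resistances
        g = Graph.from_edges(5, [(0, 1), (1, 2), (2, 3), (2, 4)])
        h = permute(g, [4, 3, 2, 1, 0])
        assert resistance_distance(g, h) > 0.1

    def test_renormalized_handles_disconnected(self):
        g = Graph.from_edges(4, [(0, 1), (2, 3)])
        h = Graph.from_edges(4, [(0, 1), (1, 2), (2, 3)])
        with pytest.raises(DisconnectedGraphError):
            resistance_distance(g, h)
        assert resistance_distance(g, h, renormalized=True) > 0


class TestRenormalizedResistance:
    def test_unit_resistance_maps_to_half(self):
        g = Graph.from_edges(2, [(0, 1)])
        assert renormalized_resistance_matrix(g).values[0, 1] == pytest.approx(0.5)

    def test_disconnected_pair_saturates_at_one(self):
        g = Graph.from_edges(4, [(0, 1), (2, 3)])
        rho = renormalized_resistance_matrix(g).values
        assert rho[0, 2] == 1.0
        assert rho[1, 3] == 1.0
        assert rho[0, 1] == pytest.approx(0.5)

    def test_entries_bounded_and_zero_diagonal(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, 15, 0.1)
        rho = renormalized_resistance_matrix(g).values
        assert np.all(rho >= 0) and np.all(rho <= 1)
        assert np.allclose(np.diag(rho), 0)

    def test_monotone_transform_preserves_affinity_ranking(self):
        rng = np.random.default_rng(10)
        g = random_connected_graph(rng, 12, 0.3)
        iu = np.triu_indices(12, k=1)
        r = resistance_matrix(g).values[iu]
        rho = renormalized_resistance_matrix(g).values[iu]
        # strictly monotone map: every clearly-ordered pair keeps its order
        for a in range(len(r)):
            for b in range(a + 1, len(r)):
                if abs(r[a] - r[b]) > 1e-9:
                    assert np.sign(r[a] - r[b]) == np.sign(rho[a] - rho[b])
        corr = scipy.stats.spearmanr(r, rho).statistic
        assert corr == pytest.approx(1.0, abs=1e-3)


class TestFbpAndDeltacon:
    def test_zero_epsilon_gives_identity(self, k3):
        assert np.allclose(fbp_matrix(k3, 0.0).values, np.eye(3))

    def test_single_edge_closed_form(self):
        g = Graph.from_edges(2, [(0, 1)])
        s = fbp_matrix(g, 0.1).values
        expected = np.linalg.inv(np.array([[1.01, -0.1], [-0.1, 1.01]]))
        assert np.allclose(s, expected)
        assert s[0, 0] == pytest.approx(0.99990, abs=5e-5)
        assert s[0, 1] == pytest.approx(0.09900, abs=5e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_series_expansion_error_scales_as_epsilon_cubed(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 12, 0.4)
        a = g.to_adjacency()
        d = np.diag(a.sum(axis=1))
        errs = {}
        for eps in (1e-2, 1e-3):
            s = fbp_matrix(g, eps).values
            series = np.eye(12) + eps * a + eps**2 * (a @ a - d)
            errs[eps] = np.abs(s - series).max()
        # eps drops by 10, so an O(eps^3) error must drop by ~1000
        assert errs[1e-3] <= errs[1e-2] / 100

    def test_deltacon_identity_and_symmetry(self, k3, p3):
        assert deltacon(k3, k3) == pytest.approx(0, abs=1e-10)
        rng = np.random.default_rng(1)
        for _ in range(5):
            g, h = random_graph(rng, 10, 0.4), random_graph(rng, 10, 0.4)
            eps = default_epsilon(g, h)
            assert deltacon(g, h, eps) == pytest.approx(deltacon(h, g, eps))

    def test_frobenius_variant_differs_from_matusita(self, k3, p3):
        assert deltacon(k3, p3, variant="frobenius") != pytest.approx(
            deltacon(k3, p3, variant="matusita")
        )
        with pytest.raises(GraphValidationError):
            deltacon(k3, p3, variant="chebyshev")

    def test_monotone_under_growing_perturbation(self):
        """Adding one edge moves DeltaCon off zero; adding two disjoint edges
        moves it at least as far in >= 90% of trials."""
        rng = np.random.default_rng(77)
        wins = 0
        trials = 100
        for _ in range(trials):
            g = random_graph(rng, 50, 0.1)
            absent = [
                (i, j)
                for i in range(50)
                for j in range(i + 1, 50)
                if g.weight(i, j) == 0
            ]
            rng.shuffle(absent)
            a, b = absent[0]
            c, d = next(e for e in absent[1:] if len({a, b, *e}) == 4)
            eps = default_epsilon(g)
            g1 = Graph(50, {**g.weights, (a, b): 1.0})
            g2 = Graph(50, {**g.weights, (a, b): 1.0, (c, d): 1.0})
            d1 = deltacon(g, g1, eps)
            d2 = deltacon(g, g2, eps)
            assert d1 > 0
            wins += d2 >= d1
        assert wins >= 0.9 * trials


class TestSingleEdgeClosedForm:
    def test_zero_perturbation(self, k3):
        assert rp_single_edge_closed_form(k3, 0, 1, 0.0) == 0.0

    def test_removing_triangle_edge_matches_direct(self, k3):
        got = rp_single_edge_closed_form(k3, 0, 1, -1.0)
        direct = _rp_direct(k3, 0, 1, -1.0)
        assert got == pytest.approx(direct, rel=1e-9)
        # and matches the hand computation ||R(K3) - R(P3 relabeled)||
        assert got == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_direct_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 41))
        g = random_connected_graph(rng, n, 0.15)
        i0, j0 = 0, 1
        w0 = g.weight(i0, j0)
        delta = float(rng.uniform(-w0 if w0 else 0.0, 1.0))
        if delta == 0:
            delta = 0.5
        closed = rp_single_edge_closed_form(g, i0, j0, delta)
        if closed == 0 and delta == 0:
            return
        direct = _rp_direct(g, i0, j0, delta)
        assert closed == pytest.approx(direct, rel=1e-6)

    def test_bridge_removal_warns_then_fails_as_undefined(self):
        g = Graph.from_edges(4, [(0, 1), (1, 2), (2, 3)])
        with pytest.warns(UserWarning, match="disconnects"):
            with pytest.raises(DisconnectedGraphError):
                rp_single_edge_closed_form(g, 1, 2, -1.0)

    def test_continuity_in_perturbation_size(self):
        rng = np.random.default_rng(4)
        g = random_connected_graph(rng, 15, 0.3)
        d3 = rp_single_edge_closed_form(g, 0, 1, 1e-3)
        d6 = rp_single_edge_closed_form(g, 0, 1, 1e-6)
        assert d3 < 1e-1
        assert d6 < 1e-4
        assert d6 < d3
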