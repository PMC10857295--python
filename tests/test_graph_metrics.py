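"""Weighted graph metrics against closed forms and brute-force oracles.

The brute-force oracles are written independently of the implementation:
Floyd-Warshall over 1/|w| lengths for distances, exhaustive triple
enumeration for triangles, and explicit per-module accumulation for the
participation coefficient. networkx provides a second independent
cross-check for distances and Onnela clustering.
"""

import networkx as nx
import numpy as np
import pytest

from conftest import random_weighted_graph
from nmcoupling.errors import NMCouplingError
from nmcoupling.metrics import (characteristic_path_length,
                                closeness_centrality, clustering_coefficient,
                                compute_all, global_efficiency,
                                participation_coefficient,
                                shortest_path_matrix, weighted_degree)


# ---------------------------------------------------------------- oracles --

def floyd_warshall(w):
    """Brute-force all-pairs shortest paths on 1/|w| edge lengths."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] != 0:
                d[i, j] = 1.0 / abs(w[i, j])
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_triangles(w):
    """t_i by exhaustive (j, h) enumeration on max-normalized |w|."""
    a = np.abs(w)
    mx = a.max()
    if mx == 0:
        return np.zeros(w.shape[0])
    a = a / mx
    n = a.shape[0]
    t = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for h in range(n):
                t[i] += (a[i, j] * a[i, h] * a[j, h]) ** (1.0 / 3.0)
    return t / 2.0


def brute_participation(w, labels):
    a = np.abs(w)
    n = a.shape[0]
    y = np.zeros(n)
    for i in range(n):
        k = a[i].sum()
        if k == 0:
            continue
        s = 0.0
        for m in set(labels):
            km = sum(a[i, j] for j in range(n) if labels[j] == m)
            s += (km / k) ** 2
        y[i] = 1.0 - s
    return y


def _unit_graph(edges, n):
    w = np.zeros((n, n))
    for i, j in edges:
        w[i, j] = w[j, i] = 1.0
    return w


# ----------------------------------------------------------- closed forms --

class TestClosedForms:
    def test_complete_graph_degrees(self):
        w = _unit_graph([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)
        np.testing.assert_allclose(weighted_degree(w), 3.0)

    def test_star_hub_degree_sums_leaf_weights(self):
        w = np.zeros((4, 4))
        for leaf, wt in zip([1, 2, 3], [0.5, 0.4, 0.6]):
            w[0, leaf] = w[leaf, 0] = wt
        assert weighted_degree(w)[0] == pytest.approx(1.5)

    def test_degree_uses_absolute_weights(self):
        w = np.array([[0, -0.5, 0.5], [-0.5, 0, 0], [0.5, 0, 0]])
        np.testing.assert_allclose(weighted_degree(w), [1.0, 0.5, 0.5])

    def test_participation_zero_within_own_module(self):
        # every edge of every node stays inside its community
        w = _unit_graph([(0, 1), (2, 3)], 4)
        y = participation_coefficient(w, ["m1", "m1", "m2", "m2"])
        np.testing.assert_allclose(y, 0.0)

    def test_participation_even_split_two_modules(self):
        # node 0 sends equal weight into its own module and one other
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.7   # within module a
        w[0, 2] = w[2, 0] = 0.7   # into module b
        y = participation_coefficient(w, ["a", "a", "b"])
        assert y[0] == pytest.approx(0.5)

    def test_two_node_distance_is_inverse_weight(self):
        w = np.array([[0, 0.5], [0.5, 0]])
        d = shortest_path_matrix(w)
        assert d[0, 1] == pytest.approx(2.0)

    def test_unit_path_distances(self):
        w = _unit_graph([(0, 1), (1, 2)], 3)
        d = shortest_path_matrix(w)
        assert d[0, 2] == pytest.approx(2.0)

    def test_closeness_complete_and_path(self):
        k4 = _unit_graph([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)
        np.testing.assert_allclose(closeness_centrality(k4), 1.0)
        path4 = _unit_graph([(0, 1), (1, 2), (2, 3)], 4)
        assert closeness_centrality(path4)[0] == pytest.approx(3 / 6)

    def test_isolated_node_closeness_zero(self):
        w = _unit_graph([(0, 1)], 3)
        assert closeness_centrality(w)[2] == 0.0

    def test_efficiency_trivials(self):
        k3 = _unit_graph([(0, 1), (0, 2), (1, 2)], 3)
        assert global_efficiency(k3) == pytest.approx(1.0)
        two = np.array([[0, 0.5], [0.5, 0]])
        assert global_efficiency(two) == pytest.approx(0.5)
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_path_length_trivials(self):
        k3 = _unit_graph([(0, 1), (0, 2), (1, 2)], 3)
        assert characteristic_path_length(k3) == pytest.approx(1.0)
        path3 = _unit_graph([(0, 1), (1, 2)], 3)
        assert characteristic_path_length(path3) == pytest.approx(4 / 3)
        with pytest.raises(NMCouplingError):
            characteristic_path_length(np.zeros((3, 3)))

    def test_clustering_trivials(self):
        tri = _unit_graph([(0, 1), (0, 2), (1, 2)], 3)
        cw, ci = clustering_coefficient(tri)
        assert cw == pytest.approx(1.0)
        star = np.zeros((4, 4))
        star[0, 1:] = star[1:, 0] = 1.0
        assert clustering_coefficient(star)[0] == pytest.approx(0.0)

    def test_compute_all_on_k5(self):
        k5 = _unit_graph([(i, j) for i in range(5) for j in range(i + 1, 5)], 5)
        gm = compute_all(k5, ["a", "a", "a", "b", "b"])
        np.testing.assert_allclose(gm.nodal["degree"], 4.0)
        np.testing.assert_allclose(gm.nodal["closeness_centrality"], 1.0)
        assert gm.global_["global_efficiency"] == pytest.approx(1.0)
        assert gm.global_["characteristic_path_length"] == pytest.approx(1.0)
        assert gm.global_["clustering_coefficient"] == pytest.approx(1.0)


# ------------------------------------------------------ oracle equivalence --

class TestOracleEquivalence:
    def test_all_metrics_match_brute_force(self):
        """All six metrics vs Floyd-Warshall / exhaustive enumeration on 200
        random signed graphs of up to 10 nodes."""
        rng = np.random.default_rng(2024)
        module_choices = ["a", "b", "c"]
        for trial in range(200):
            n = int(rng.integers(4, 11))
            w = random_weighted_graph(rng, n, density=float(rng.uniform(0.3, 0.9)))
            labels = [module_choices[i] for i in rng.integers(0, 3, n)]

            d = shortest_path_matrix(w)
            d_oracle = floyd_warshall(w)
            np.testing.assert_allclose(d, d_oracle, rtol=1e-10)

            np.testing.assert_allclose(weighted_degree(w),
                                       np.abs(w).sum(axis=1))
            np.testing.assert_allclose(
                participation_coefficient(w, labels),
                brute_participation(w, labels), atol=1e-12)

            off = ~np.eye(n, dtype=bool)
            reach = off & np.isfinite(d_oracle)
            with np.errstate(divide="ignore", invalid="ignore"):
                inv = np.where(reach & (d_oracle > 0), 1.0 / d_oracle, 0.0)
            np.testing.assert_allclose(global_efficiency(w),
                                       inv[off].sum() / (n * (n - 1)))
            if reach.any():
                np.testing.assert_allclose(characteristic_path_length(w),
                                           d_oracle[reach].mean())
            row_sum = np.where(reach, d_oracle, 0).sum(axis=1)
            with np.errstate(divide="ignore"):
                cl_oracle = np.where(row_sum > 0, (n - 1) / row_sum, 0.0)
            np.testing.assert_allclose(closeness_centrality(w), cl_oracle)

            t_oracle = brute_triangles(w)
            kb = (np.abs(w) > 0).sum(axis=1)
            with np.errstate(invalid="ignore"):
                ci_oracle = np.where(kb >= 2, 2 * t_oracle / (kb * (kb - 1)), 0.0)
            cw, ci = clustering_coefficient(w)
            np.testing.assert_allclose(ci, ci_oracle, atol=1e-10)
            np.testing.assert_allclose(cw, ci_oracle.mean())

    def test_distances_and_clustering_match_networkx(self, rng):
        """Independent library cross-check on connected positive graphs."""
        for _ in range(20):
            n = int(rng.integers(5, 10))
            w = np.abs(random_weighted_graph(rng, n, density=0.9))
            g = nx.from_numpy_array(w)
            for u, v, data in g.edges(data=True):
                data["length"] = 1.0 / data["weight"]
            d_nx = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
            d = shortest_path_matrix(w)
            for i in range(n):
                for j in range(n):
                    if j in d_nx[i]:
                        assert d[i, j] == pytest.approx(d_nx[i][j])
            _, ci = clustering_coefficient(w)
            ci_nx = nx.clustering(g, weight="weight")
            for i in range(n):
                assert ci[i] == pytest.approx(ci_nx[i], abs=1e-10)


# ------------------------------------------------------------- invariants --

class TestInvariants:
    def test_efficiency_at_least_inverse_path_length(self, rng):
        """Jensen: the mean of reciprocals dominates the reciprocal mean."""
        for _ in range(30):
            n = int(rng.integers(5, 10))
            w = np.abs(random_weighted_graph(rng, n, density=0.95))
            d = shortest_path_matrix(w)
            if not np.isfinite(d).all():
                continue
            assert global_efficiency(w) >= 1.0 / characteristic_path_length(w) - 1e-12

    def test_node_relabeling_equivariance(self, rng):
        n = 8
        w = random_weighted_graph(rng, n, density=0.8)
        labels = ["a", "a", "b", "b", "b", "c", "c", "c"]
        perm = rng.permutation(n)
        wp = w[np.ix_(perm, perm)]
        labels_p = [labels[i] for i in perm]
        gm = compute_all(w, labels)
        gmp = compute_all(wp, labels_p)
        for m, vals in gm.nodal.items():
            np.testing.assert_allclose(gmp.nodal[m], vals[perm], atol=1e-10)
        for m, val in gm.global_.items():
            assert gmp.global_[m] == pytest.approx(val)

    def test_edge_deletion_monotonicity(self, rng):
        """Removing an edge cannot raise efficiency or shorten paths."""
        for _ in range(20):
            n = 7
            w = np.abs(random_weighted_graph(rng, n, density=0.9))
            nz = np.argwhere(np.triu(w, 1) > 0)
            if len(nz) == 0:
                continue
            i, j = nz[rng.integers(len(nz))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = 0.0
            d2 = shortest_path_matrix(w2)
            assert global_efficiency(w2) <= global_efficiency(w) + 1e-12
            if np.isfinite(d2).all():
                assert (characteristic_path_length(w2)
                        >= characteristic_path_length(w) - 1e-12)

    def test_composition_consistency(self, rng):
        """compute_all equals the individually invoked operations."""
        w = random_weighted_graph(rng, 9, density=0.7)
        labels = ["a"] * 4 + ["b"] * 5
        gm = compute_all(w, labels)
        np.testing.assert_allclose(gm.nodal["degree"], weighted_degree(w))
        np.testing.assert_allclose(gm.nodal["participation_coefficient"],
                                   participation_coefficient(w, labels))
        np.testing.assert_allclose(gm.nodal["closeness_centrality"],
                                   closeness_centrality(w))
        assert gm.global_["global_efficiency"] == pytest.approx(
            global_efficiency(w))
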