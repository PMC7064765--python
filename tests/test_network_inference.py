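import itertools

import numpy as np
import pytest

from mucodyn.network_inference import (
    AbundanceTable,
    CorrelationResult,
    InteractionMatrix,
    betweenness_centrality,
    component_count,
    diameter,
    eigen_centrality,
    spearman_matrix,
    summarize_network,
    threshold_network,
    to_graph,
    write_edge_list,
    write_graphml,
)

from oracles import (
    betweenness_oracle,
    bfs_ecc,
    eigen_oracle,
    spearman_oracle,
)


def matrix_from_adj(adj, weight=1.0):
    taxa = [f"n{i}" for i in range(adj.shape[0])]
    return InteractionMatrix(taxon_ids=taxa, eta=np.asarray(adj, dtype=float) * weight)


def star_matrix(n_leaves=4):
    adj = np.zeros((n_leaves + 1, n_leaves + 1))
    adj[0, 1:] = adj[1:, 0] = 1.0
    return matrix_from_adj(adj)


# ---------------------------------------------------------------------------


class TestSpearmanMatrix:
    def test_identical_rank_order(self):
        vals = np.column_stack([np.arange(1.0, 7.0), np.arange(1.0, 7.0) ** 2])
        table = AbundanceTable([f"s{i}" for i in range(6)], ["A", "B"], vals)
        res = spearman_matrix(table)
        assert res.rho[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        vals = np.column_stack([np.arange(1.0, 7.0), np.arange(6.0, 0.0, -1.0)])
        table = AbundanceTable([f"s{i}" for i in range(6)], ["A", "B"], vals)
        assert spearman_matrix(table).rho[0, 1] == pytest.approx(-1.0)

    def test_toy_table_matches_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        table = AbundanceTable([f"s{i}" for i in range(5)], ["A", "B"], np.column_stack([x, y]))
        res = spearman_matrix(table)
        assert res.rho[0, 1] == pytest.approx(spearman_oracle(x, y), abs=1e-12)
        assert res.rho[0, 1] == pytest.approx(0.8)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            vals = rng.uniform(0, 10, size=(8, 4))
            table = AbundanceTable(
                [f"s{i}" for i in range(8)], [f"t{i}" for i in range(4)], vals
            )
            res = spearman_matrix(table)
            for i, j in itertools.combinations(range(4), 2):
                assert res.rho[i, j] == pytest.approx(
                    spearman_oracle(vals[:, i], vals[:, j]), abs=1e-10
                )

    def test_symmetric_with_unit_diagonal(self, toy_table):
        res = spearman_matrix(toy_table)
        np.testing.assert_allclose(res.rho, res.rho.T)
        np.testing.assert_allclose(np.diag(res.rho), 1.0)
        np.testing.assert_allclose(res.pvalues, res.pvalues.T)

    def test_constant_taxon_reported_missing(self):
        vals = np.column_stack([np.arange(1.0, 6.0), np.full(5, 3.0), np.arange(5.0, 0.0, -1.0)])
        table = AbundanceTable([f"s{i}" for i in range(5)], ["A", "B", "C"], vals)
        res = spearman_matrix(table)
        assert np.isnan(res.rho[0, 1]) and np.isnan(res.rho[1, 2])
        assert res.rho[0, 2] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, toy_table):
        base = spearman_matrix(toy_table).rho
        transformed = AbundanceTable(
            toy_table.sample_ids,
            toy_table.taxon_ids,
            np.column_stack(
                [
                    np.exp(toy_table.values[:, 0] / 50.0),
                    toy_table.values[:, 1] ** 3 / 1e4,
                    np.sqrt(toy_table.values[:, 2]),
                ]
            ),
        )
        np.testing.assert_allclose(spearman_matrix(transformed).rho, base, atol=1e-12)

    def test_too_few_samples_rejected(self):
        table = AbundanceTable(["s0", "s1"], ["A", "B"], np.ones((2, 2)))
        with pytest.raises(ValueError, match="samples"):
            spearman_matrix(table)


class TestThresholdNetwork:
    def _corr(self, rho_01, p_01):
        rho = np.array([[1.0, rho_01], [rho_01, 1.0]])
        p = np.array([[0.0, p_01], [p_01, 0.0]])
        return CorrelationResult(["A", "B"], rho, p)

    def test_below_rho_threshold_dropped(self):
        eta = threshold_network(self._corr(0.65, 1e-6)).eta
        assert eta[0, 1] == 0.0

    def test_strong_significant_kept(self):
        eta = threshold_network(self._corr(0.9, 5e-4)).eta
        assert eta[0, 1] == pytest.approx(0.9)

    def test_negative_edge_kept_with_sign(self):
        eta = threshold_network(self._corr(-0.8, 1e-5)).eta
        assert eta[0, 1] == pytest.approx(-0.8)

    def test_insignificant_dropped(self):
        eta = threshold_network(self._corr(0.95, 0.01)).eta
        assert eta[0, 1] == 0.0

    def test_nan_dropped(self):
        eta = threshold_network(self._corr(np.nan, np.nan)).eta
        assert eta[0, 1] == 0.0

    def test_diagonal_zero(self, toy_table):
        eta = threshold_network(spearman_matrix(toy_table)).eta
        np.testing.assert_array_equal(np.diag(eta), 0.0)

    def test_idempotent(self, toy_table):
        m1 = threshold_network(spearman_matrix(toy_table))
        as_corr = CorrelationResult(m1.taxon_ids, m1.eta.copy(), np.zeros_like(m1.eta))
        m2 = threshold_network(as_corr)
        off = ~np.eye(len(m1.taxon_ids), dtype=bool)
        np.testing.assert_array_equal(m1.eta[off], m2.eta[off])

    def test_boundary_rho_retained(self):
        eta = threshold_network(self._corr(0.7, 1e-4)).eta
        assert eta[0, 1] == pytest.approx(0.7)


class TestEigenCentrality:
    def test_complete_graph_all_one(self):
        adj = 1.0 - np.eye(4)
        scores = eigen_centrality(matrix_from_adj(adj))
        assert all(v == pytest.approx(1.0) for v in scores.values())

    def test_star_hub_and_leaves(self):
        scores = eigen_centrality(star_matrix(4))
        assert scores["n0"] == pytest.approx(1.0)
        for leaf in ["n1", "n2", "n3", "n4"]:
            assert scores[leaf] == pytest.approx(0.5, abs=1e-8)

    def test_isolated_node_scores_zero(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        scores = eigen_centrality(matrix_from_adj(adj))
        assert scores["n2"] == 0.0

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="empty"):
            eigen_centrality(matrix_from_adj(np.zeros((3, 3))))

    def test_matches_power_iteration_on_random_graphs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(3, 7)
            adj = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
            adj = adj + adj.T
            if adj.sum() == 0:
                continue
            eigvals = np.linalg.eigvalsh(adj)
            if eigvals[-1] - eigvals[-2] < 1e-6:
                continue  # degenerate dominant eigenvalue: score ill-defined
            scores = eigen_centrality(matrix_from_adj(adj))
            expected = eigen_oracle(adj)
            got = np.array([scores[f"n{i}"] for i in range(n)])
            comp = expected > 1e-9
            np.testing.assert_allclose(got[comp], expected[comp], atol=1e-6)

    def test_uses_absolute_weights(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = -0.9
        adj[1, 2] = adj[2, 1] = 0.9
        scores = eigen_centrality(matrix_from_adj(adj))
        assert scores["n0"] == pytest.approx(scores["n2"])


class TestBetweenness:
    def test_three_node_path(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1.0
        scores = betweenness_centrality(matrix_from_adj(adj))
        assert scores["n1"] == pytest.approx(1.0)
        assert scores["n0"] == scores["n2"] == 0.0

    def test_star_hub(self):
        scores = betweenness_centrality(star_matrix(4))
        assert scores["n0"] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert all(scores[f"n{i}"] == 0.0 for i in range(1, 5))

    def test_complete_graph_zero(self):
        scores = betweenness_centrality(matrix_from_adj(1.0 - np.eye(5)))
        assert all(v == pytest.approx(0.0) for v in scores.values())

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(3, 7)
            adj = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
            adj = adj + adj.T
            scores = betweenness_centrality(matrix_from_adj(adj))
            expected = betweenness_oracle(adj)
            got = np.array([scores[f"n{i}"] for i in range(n)])
            np.testing.assert_allclose(got, expected, atol=1e-9)


class TestDiameterAndComponents:
    def test_four_node_path(self):
        adj = np.zeros((4, 4))
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = 1.0
        assert diameter(matrix_from_adj(adj)) == 3

    def test_complete_graph(self):
        assert diameter(matrix_from_adj(1.0 - np.eye(5))) == 1

    def test_random_connected_graph_matches_bfs(self):
        rng = np.random.default_rng(14)
        while True:
            n = 15
            adj = np.triu((rng.random((n, n)) < 0.2).astype(float), 1)
            adj = adj + adj.T
            ecc0 = bfs_ecc(adj, 0)
            if len(ecc0) == n:
                break
        expected = max(max(bfs_ecc(adj, s).values()) for s in range(n))
        assert diameter(matrix_from_adj(adj)) == expected

    def test_disconnected_errors_with_components(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            diameter(matrix_from_adj(adj))

    def test_diameter_ignores_weights(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 0.71
        adj[1, 2] = adj[2, 1] = 0.99
        assert diameter(matrix_from_adj(adj)) == 2

    def test_component_counts(self):
        adj = np.zeros((2, 2))
        adj[0, 1] = adj[1, 0] = 1.0
        assert component_count(matrix_from_adj(adj)) == (1, 0)
        adj = np.zeros((5, 5))
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1.0
        assert component_count(matrix_from_adj(adj)) == (2, 1)


class TestSummaryAndExport:
    def test_summary_fields(self):
        summary = summarize_network(star_matrix(4))
        assert summary.n_nodes == 5
        assert summary.n_edges == 4
        assert summary.n_components == 1
        assert summary.diameter == 2
        df = summary.to_frame()
        assert list(df.columns) == ["taxon", "eigen_centrality", "betweenness"]
        assert len(df) == 5

    def test_edge_list_export(self, tmp_path):
        import pandas as pd

        path = tmp_path / "edges.csv"
        write_edge_list(star_matrix(4), str(path))
        df = pd.read_csv(path)
        assert len(df) == 4
        assert set(df.columns) == {"taxon_a", "taxon_b", "rho", "p"}

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        path = tmp_path / "net.graphml"
        write_graphml(star_matrix(4), str(path))
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 4

    def test_to_graph_edge_weights_signed(self):
        adj = np.zeros((2, 2))
        adj[0, 1] = adj[1, 0] = -0.8
        g = to_graph(matrix_from_adj(adj))
        assert g["n0"]["n1"]["weight"] == pytest.approx(-0.8)
        assert g["n0"]["n1"]["abs_weight"] == pytest.approx(0.8)
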