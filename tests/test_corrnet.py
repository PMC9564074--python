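"""Spearman matrices, edge filtering and spectral clustering.

The Spearman oracle here is deliberately naive: explicit midranking and the
textbook Pearson formula, pair by pair.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import networkx as nx
from gutnet import (
    GutnetError,
    build_graph,
    generate_counts,
    relative_abundance,
    spearman_matrix,
    spectral_clusters,
)
from gutnet.corrnet import eigengap_k, graph_to_edge_frame

from conftest import make_config


def midrank_oracle(x):
    """Average ranks computed by explicit enumeration."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x, y):
    """Textbook Pearson correlation of midranks."""
    rx, ry = midrank_oracle(x), midrank_oracle(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def pvalue_oracle(rho, n):
    if abs(rho) >= 1:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


class TestSpearman:
    def test_classic_no_ties_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2)=4 -> 0.8
        data = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        res = spearman_matrix(data)
        assert res.rho.loc["x", "y"] == pytest.approx(0.8, abs=1e-12)

    def test_perfect_concordance_and_discordance(self):
        x = np.arange(6, dtype=float)
        res = spearman_matrix(pd.DataFrame({"x": x, "up": np.exp(x), "down": -x}))
        assert res.rho.loc["x", "up"] == pytest.approx(1.0)
        assert res.pvalue.loc["x", "up"] == 0.0
        assert res.rho.loc["x", "down"] == pytest.approx(-1.0)

    def test_matches_naive_oracle_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n, k = rng.integers(5, 14), rng.integers(2, 7)
            data = rng.integers(0, 5, size=(n, k)).astype(float)  # many ties
            data += rng.normal(0, 1e-3, size=data.shape) * (rng.random() < 0.5)
            df = pd.DataFrame(data, columns=[f"f{j}" for j in range(k)])
            df = df.loc[:, df.std() > 0]
            if df.shape[1] < 2:
                continue
            res = spearman_matrix(df)
            for a in res.feature_names:
                for b in res.feature_names:
                    if a >= b:
                        continue
                    rho = spearman_oracle(df[a], df[b])
                    assert res.rho.loc[a, b] == pytest.approx(rho, abs=1e-12)
                    assert res.pvalue.loc[a, b] == pytest.approx(
                        pvalue_oracle(rho, len(df)), abs=1e-12
                    )

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        data = rng.random((15, 5))
        res = spearman_matrix(pd.DataFrame(data))
        ref_rho, ref_p = stats.spearmanr(data)
        np.testing.assert_allclose(res.rho.to_numpy(), ref_rho, atol=1e-12)
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(
            res.pvalue.to_numpy()[off], ref_p[off], atol=1e-12
        )

    def test_constant_columns_dropped_and_reported(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "flat": [5, 5, 5, 5], "b": [4, 3, 2, 1]})
        res = spearman_matrix(df)
        assert res.dropped == ["flat"]
        assert res.feature_names == ["a", "b"]

    def test_too_few_samples_raises(self):
        with pytest.raises(GutnetError):
            spearman_matrix(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))

    def test_all_constant_raises(self):
        with pytest.raises(GutnetError):
            spearman_matrix(pd.DataFrame({"a": [1, 1, 1], "b": [2, 2, 2]}))


class TestBuildGraph:
    def _corr(self, rho_ab, p_ab, rho_ac=0.1, p_ac=0.5):
        names = ["a", "b", "c"]
        rho = pd.DataFrame(np.eye(3), index=names, columns=names)
        p = pd.DataFrame(np.zeros((3, 3)), index=names, columns=names)
        rho.loc["a", "b"] = rho.loc["b", "a"] = rho_ab
        p.loc["a", "b"] = p.loc["b", "a"] = p_ab
        rho.loc["a", "c"] = rho.loc["c", "a"] = rho_ac
        p.loc["a", "c"] = p.loc["c", "a"] = p_ac
        p.loc["b", "c"] = p.loc["c", "b"] = 0.2
        from gutnet.corrnet import CorrelationResult

        return CorrelationResult(rho, p, n_samples=10)

    def test_raw_p_threshold(self):
        graph = build_graph(self._corr(0.5, 0.04), alpha=0.05)
        assert set(graph.edges) == {("a", "b")}
        assert set(graph.nodes) == {"a", "b", "c"}  # isolated node kept

    def test_alpha_one_gives_complete_graph(self):
        graph = build_graph(self._corr(0.5, 0.04), alpha=1.0)
        assert graph.number_of_edges() == 3

    def test_negative_rho_keeps_magnitude(self):
        graph = build_graph(self._corr(-0.9, 0.01), alpha=0.05)
        assert graph["a"]["b"]["weight"] == pytest.approx(0.9)
        assert graph["a"]["b"]["rho"] == pytest.approx(-0.9)

    def test_lowering_alpha_never_adds_edges(self):
        rng = np.random.default_rng(7)
        res = spearman_matrix(pd.DataFrame(rng.random((10, 8))))
        edges = None
        for alpha in (0.5, 0.2, 0.05, 0.01):
            current = set(build_graph(res, alpha=alpha).edges)
            if edges is not None:
                assert current <= edges
            edges = current

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.random((12, 5)), columns=list("abcde"))
        transformed = data.copy()
        transformed["a"] = np.exp(3 * transformed["a"])
        transformed["c"] = transformed["c"] ** 3
        g1 = build_graph(spearman_matrix(data), 0.3)
        g2 = build_graph(spearman_matrix(transformed), 0.3)
        assert set(g1.edges) == set(g2.edges)
        for u, v in g1.edges:
            assert g1[u][v]["weight"] == pytest.approx(g2[u][v]["weight"], abs=1e-12)


class TestSpectralClusters:
    def _two_cliques(self):
        graph = nx.Graph()
        for base in ("x", "y"):
            members = [f"{base}{i}" for i in range(4)]
            for i, u in enumerate(members):
                for v in members[i + 1 :]:
                    graph.add_edge(u, v, weight=1.0)
        return graph

    def test_disconnected_cliques_split_exactly(self):
        labels = spectral_clusters(self._two_cliques(), k=2, seed=0)
        x = {labels[f"x{i}"] for i in range(4)}
        y = {labels[f"y{i}"] for i in range(4)}
        assert len(x) == 1 and len(y) == 1 and x != y

    def test_seeded_determinism(self):
        graph = self._two_cliques()
        a = spectral_clusters(graph, k=2, seed=5)
        b = spectral_clusters(graph, k=2, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_recovers_planted_blocks(self):
        # two strong 4-taxon blocks among unstructured background taxa;
        # clustering the planted subgraph splits them exactly
        cfg = make_config(
            n_groups=1,
            n_samples_per_group=100,
            n_taxa=40,
            block_spec=[[(4, 0.8), (4, 0.8)]],
            sequencing_depth=10_000,
            baseline_log_sd=0.5,
            seed=21,
        )
        table = generate_counts(cfg)
        res = spearman_matrix(relative_abundance(table))
        planted_nodes = [f"g{i:03d}" for i in range(8)]
        graph = build_graph(res, 0.05).subgraph(planted_nodes)
        labels = spectral_clusters(graph, k=2, seed=0)
        planted = [0] * 4 + [1] * 4
        assert adjusted_rand_score(planted, labels[planted_nodes]) == 1.0

    def test_k_larger_than_nodes_raises(self):
        with pytest.raises(GutnetError):
            spectral_clusters(self._two_cliques(), k=20, seed=0)

    def test_eigengap_sees_two_components(self):
        assert eigengap_k(self._two_cliques()) == 2


def test_edge_frame_is_sorted_and_complete(tiny_table):
    res = spearman_matrix(relative_abundance(tiny_table))
    graph = build_graph(res, alpha=0.9)
    frame = graph_to_edge_frame(graph)
    assert len(frame) == graph.number_of_edges()
    assert list(frame.columns) == ["node_i", "node_j", "weight", "rho", "p"]
    assert frame.equals(frame.sort_values(["node_i", "node_j"], ignore_index=True))
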