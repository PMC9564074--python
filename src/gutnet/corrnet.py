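"""Significance-filtered Spearman co-occurrence networks and spectral clustering.

A correlation network is built per experimental group from the genus relative
abundances: pairwise Spearman rank correlations, edges for pairs whose
two-sided p-value falls below ``alpha`` (raw, uncorrected — the within-group
edge filter is intentionally liberal), edge weight the absolute value of the
correlation coefficient.  Network nodes can then be partitioned by spectral
clustering of the weighted adjacency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .containers import GutnetError

__all__ = [
    "CorrelationResult",
    "spearman_matrix",
    "build_graph",
    "spectral_clusters",
    "eigengap_k",
    "graph_to_edge_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Symmetric Spearman rho and two-sided p matrices over a feature set."""

    rho: pd.DataFrame
    pvalue: pd.DataFrame
    n_samples: int
    dropped: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.rho.columns)


def _spearman_arrays(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """rho and two-sided p matrices for a dense (n x k) array, no filtering."""
    n = arr.shape[0]
    ranks = stats.rankdata(arr, axis=0, method="average")
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    np.fill_diagonal(p, 0.0)
    return rho, p


def spearman_matrix(
    data: pd.DataFrame | np.ndarray, min_variance: float = 0.0
) -> CorrelationResult:
    """All-pairs Spearman correlation with t-approximation p-values.

    Columns whose variance is <= ``min_variance`` (constant taxa, for which
    rank correlation is undefined) are excluded and reported in
    ``result.dropped``.  rho is the Pearson correlation of midranks; the
    two-sided p-value uses ``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2
    degrees of freedom (p = 0 at |rho| = 1).

    Raises on fewer than 3 samples or if every column is degenerate.
    """
    df = pd.DataFrame(data)
    n = df.shape[0]
    if n < 3:
        raise GutnetError(f"need >= 3 samples for a correlation matrix, got {n}")
    variances = df.var(axis=0, ddof=0)
    keep = variances > min_variance
    dropped = list(df.columns[~keep])
    if dropped:
        logger.warning("dropping %d degenerate feature(s): %s", len(dropped), dropped[:10])
    df = df.loc[:, keep]
    if df.shape[1] < 2:
        raise GutnetError("fewer than 2 non-degenerate features; cannot correlate")
    rho, p = _spearman_arrays(df.to_numpy(dtype=float))
    cols = df.columns
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        pvalue=pd.DataFrame(p, index=cols, columns=cols),
        n_samples=n,
        dropped=dropped,
    )


def build_graph(corr: CorrelationResult, alpha: float = 0.05) -> nx.Graph:
    """Retain pairs with p < alpha; edge weight = |rho|, isolated nodes kept.

    Edges carry ``weight`` (=|rho|), ``rho`` and ``p`` attributes.
    """
    if not (0 < alpha <= 1):
        raise GutnetError(f"alpha must be in (0, 1], got {alpha}")
    graph = nx.Graph()
    names = corr.feature_names
    graph.add_nodes_from(names)
    rho = corr.rho.to_numpy()
    p = corr.pvalue.to_numpy()
    iu, ju = np.triu_indices(len(names), k=1)
    keep = p[iu, ju] < alpha
    for i, j in zip(iu[keep], ju[keep]):
        r = rho[i, j]
        graph.add_edge(names[i], names[j], weight=abs(r), rho=float(r), p=float(p[i, j]))
    return graph


def _normalized_laplacian_embedding(adj: np.ndarray, k: int) -> np.ndarray:
    """First k eigenvectors of the symmetric normalized Laplacian.

    Rows of isolated nodes (zero degree) are embedded at the origin, making
    their cluster assignment deterministic.
    """
    deg = adj.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    lap = np.eye(len(adj)) - inv_sqrt[:, None] * adj * inv_sqrt[None, :]
    # isolated nodes: zero out their rows/cols so they sit at the origin
    _, vecs = eigh(lap, subset_by_index=[0, k - 1])
    emb = vecs * (deg > 0)[:, None]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    out = np.zeros_like(emb)
    np.divide(emb, norms, out=out, where=norms > 0)
    return out


def spectral_clusters(
    graph: nx.Graph, k: int | None = None, seed: int = 0, k_max: int = 10
) -> pd.Series:
    """Spectral clustering of the weighted adjacency into k groups.

    Normalized-Laplacian embedding followed by seeded k-means; with
    ``k=None`` the number of clusters is chosen by the eigengap heuristic
    (largest gap among the smallest ``k_max`` Laplacian eigenvalues).
    Returns labels in ``{0..k-1}`` indexed by node name.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise GutnetError("cannot cluster an empty graph")
    if k is None:
        k = eigengap_k(graph, k_max=k_max)
    if k < 2:
        raise GutnetError(f"k must be >= 2, got {k}")
    if k > n:
        raise GutnetError(f"k={k} exceeds node count {n}")
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    emb = _normalized_laplacian_embedding(adj, k)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(emb)
    return pd.Series(labels, index=nodes, name="cluster")


def eigengap_k(graph: nx.Graph, k_max: int = 10) -> int:
    """Cluster count by the largest gap in the normalized Laplacian spectrum."""
    nodes = list(graph.nodes)
    n = len(nodes)
    if n < 2:
        raise GutnetError("eigengap heuristic needs >= 2 nodes")
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    deg = adj.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    lap = np.eye(n) - inv_sqrt[:, None] * adj * inv_sqrt[None, :]
    upper = min(k_max + 1, n)
    vals = eigh(lap, subset_by_index=[0, upper - 1], eigvals_only=True)
    gaps = np.diff(vals)  # gap after eigenvalue i -> k = i+1 clusters
    if len(gaps) < 2:
        return 2
    return int(np.argmax(gaps[1:]) + 2)  # k >= 2


def graph_to_edge_frame(graph: nx.Graph) -> pd.DataFrame:
    """Weighted edge list as a DataFrame (node_i, node_j, weight, rho, p)."""
    rows = [
        {
            "node_i": u,
            "node_j": v,
            "weight": d.get("weight", np.nan),
            "rho": d.get("rho", np.nan),
            "p": d.get("p", np.nan),
        }
        for u, v, d in graph.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "rho", "p"])
    return frame.sort_values(["node_i", "node_j"], ignore_index=True)
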