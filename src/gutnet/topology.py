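"""Global topology statistics of correlation networks and their bootstrap.

Five global parameters summarize how "organized" a co-occurrence network is:

* **density** — 2m / (n(n-1)), the fraction of realized edges;
* **shannon_entropy** — Shannon entropy (nats) of the empirical degree
  distribution: 0 for degree-regular graphs, larger the more heterogeneous
  the degree structure;
* **centralization** — Freeman degree centralization,
  ``sum(d_max - d_i) / ((n-1)(n-2))``: 1 for a star, 0 for regular graphs;
* **heterogeneity** — coefficient of variation of the degrees (sd/mean);
* **clustering_coefficient** — global transitivity, 3 x triangles /
  connected triples.

All five are computed on the unweighted edge skeleton.  Their sampling
distributions per experimental group come from bootstrap resampling of the
group's biological replicates (samples, not taxa): each replicate redraws
the samples with replacement, rebuilds the Spearman network at the same
significance threshold, and recomputes the summary.  Groups are compared
per parameter by one-way ANOVA with Tukey HSD on the replicate vectors.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .community import AnovaResult, anova_tukey
from .containers import CountTable, GutnetError
from .corrnet import _spearman_arrays
from .profiles import relative_abundance

__all__ = [
    "NetworkSummary",
    "BootstrapDistribution",
    "network_summary",
    "bootstrap_topology",
    "compare_groups",
    "PARAMETERS",
]

logger = logging.getLogger(__name__)

PARAMETERS = (
    "density",
    "shannon_entropy",
    "centralization",
    "heterogeneity",
    "clustering_coefficient",
)


@dataclass
class NetworkSummary:
    density: float
    shannon_entropy: float
    centralization: float
    heterogeneity: float
    clustering_coefficient: float

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETERS}


def degree_entropy(degrees: np.ndarray) -> float:
    """Shannon entropy (nats) of the empirical degree distribution."""
    counts = np.array(list(Counter(degrees.tolist()).values()), dtype=float)
    f = counts / counts.sum()
    return float(-(f * np.log(f)).sum())


def _summary_from_adjacency(adj: np.ndarray, warn: bool = True) -> NetworkSummary:
    """Five parameters from a boolean adjacency matrix (no self-loops)."""
    n = adj.shape[0]
    if n < 2:
        raise GutnetError(f"network summary needs >= 2 nodes, got {n}")
    a = adj.astype(float)
    degrees = a.sum(axis=1)
    m = degrees.sum() / 2.0
    density = 2.0 * m / (n * (n - 1))
    entropy = degree_entropy(degrees)
    if n > 2:
        centralization = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0
    mean_deg = degrees.mean()
    if mean_deg > 0:
        heterogeneity = float(degrees.std(ddof=0) / mean_deg)
    else:
        if warn:
            warnings.warn("graph has no edges; heterogeneity reported as 0", stacklevel=3)
        heterogeneity = 0.0
    triples = float((degrees * (degrees - 1)).sum())  # 2 x connected triples
    if triples > 0:
        closed = float(np.trace(a @ a @ a))  # 6 x triangles
        clustering = closed / triples
    else:
        clustering = 0.0
    return NetworkSummary(
        density=float(density),
        shannon_entropy=entropy,
        centralization=centralization,
        heterogeneity=heterogeneity,
        clustering_coefficient=clustering,
    )


def network_summary(graph: nx.Graph) -> NetworkSummary:
    """The five global topology parameters of a graph (unweighted skeleton)."""
    n = graph.number_of_nodes()
    if n < 2:
        raise GutnetError(f"network summary needs >= 2 nodes, got {n}")
    adj = nx.to_numpy_array(graph, weight=None)
    return _summary_from_adjacency(adj)


@dataclass
class BootstrapDistribution:
    """B bootstrap replicates of one topology parameter for one group."""

    group: str
    parameter: str
    replicates: np.ndarray
    n_redrawn: int = 0

    @property
    def B(self) -> int:
        return len(self.replicates)


def bootstrap_topology(
    table: CountTable,
    group: str,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    use_relative: bool = True,
    min_variance: float = 0.0,
) -> dict[str, BootstrapDistribution]:
    """Bootstrap the topology parameters of one group's network.

    Each replicate resamples the group's samples with replacement (same n),
    rebuilds the significance-filtered Spearman network and recomputes the
    five parameters.  Replicates whose resample leaves fewer than two
    non-degenerate taxa are redrawn; a redraw rate above 50% raises.
    Deterministic given ``seed``.
    """
    sub = table.subset(group)
    n = sub.n_samples
    if n < 3:
        raise GutnetError(f"group {group!r} has {n} samples; bootstrap needs >= 3")
    if B < 1:
        raise GutnetError("B must be >= 1")
    data = (relative_abundance(sub) if use_relative else sub.counts).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = np.empty((B, len(PARAMETERS)))
    redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            resampled = data[idx]
            keep = resampled.var(axis=0) > min_variance
            if keep.sum() >= 2:
                break
            redrawn += 1
            if redrawn > max(B, 10):
                raise GutnetError(
                    f"bootstrap for group {group!r}: more than 50% of "
                    "replicates were degenerate"
                ) from None
        _, p = _spearman_arrays(resampled[:, keep])
        adj = p < alpha
        np.fill_diagonal(adj, False)
        summary = _summary_from_adjacency(adj, warn=False)
        rows[b] = [getattr(summary, name) for name in PARAMETERS]
    if redrawn:
        logger.info("group %s: %d degenerate bootstrap resamples redrawn", group, redrawn)
    return {
        p: BootstrapDistribution(group, p, rows[:, i].copy(), n_redrawn=redrawn)
        for i, p in enumerate(PARAMETERS)
    }


def compare_groups(
    dists: dict[str, dict[str, BootstrapDistribution]] , parameter: str
) -> AnovaResult:
    """One-way ANOVA + Tukey HSD across groups on one parameter's replicates."""
    if parameter not in PARAMETERS:
        raise GutnetError(f"unknown parameter {parameter!r}")
    samples = {group: by_param[parameter].replicates for group, by_param in dists.items()}
    return anova_tukey(samples)
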