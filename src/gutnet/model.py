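"""Model/Results interface for the network-organization analysis.

:class:`MicrobiomeNetworkModel` is constructed from a :class:`CountTable`
and, on :meth:`~MicrobiomeNetworkModel.fit`, builds one significance-filtered
Spearman co-occurrence network per experimental group, clusters its nodes,
bootstraps the five global topology parameters (density, degree entropy,
centralization, heterogeneity, transitivity) by resampling the group's
biological replicates, and compares groups per parameter by one-way ANOVA
with Tukey HSD.  The returned :class:`MicrobiomeNetworkResults` carries the
graphs, bootstrap distributions, comparison tables and a text
:meth:`~MicrobiomeNetworkResults.summary`.

Example
-------
>>> from gutnet import study_config, generate_counts, MicrobiomeNetworkModel
>>> table = generate_counts(study_config(seed=7))
>>> res = MicrobiomeNetworkModel(table).fit(n_boot=200, seed=7)
>>> print(res.summary())                                    # doctest: +SKIP
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .community import AnovaResult
from .containers import CountTable, GutnetError
from .corrnet import CorrelationResult, build_graph, spearman_matrix, spectral_clusters
from .profiles import relative_abundance
from .topology import (
    PARAMETERS,
    BootstrapDistribution,
    bootstrap_topology,
    compare_groups,
    network_summary,
)

__all__ = ["MicrobiomeNetworkModel", "MicrobiomeNetworkResults"]


class MicrobiomeNetworkModel:
    """Per-group co-occurrence network model of a genus count table.

    Parameters
    ----------
    table
        Count table with >= 3 samples in every group.
    alpha
        Raw two-sided significance threshold on an edge's Spearman p-value.
    use_relative
        Correlate relative abundances (default) rather than raw counts;
        rank correlation differs between the two only through per-sample
        depth variation.
    min_variance
        Features with variance <= this are dropped before correlation.
    """

    def __init__(
        self,
        table: CountTable,
        alpha: float = 0.05,
        use_relative: bool = True,
        min_variance: float = 0.0,
    ) -> None:
        if not (0 < alpha <= 1):
            raise GutnetError(f"alpha must be in (0, 1], got {alpha}")
        self.table = table
        self.alpha = alpha
        self.use_relative = use_relative
        self.min_variance = min_variance

    @classmethod
    def from_tsv(cls, counts_path, metadata_path, **kwargs) -> "MicrobiomeNetworkModel":
        return cls(CountTable.read_tsv(counts_path, metadata_path), **kwargs)

    def _group_data(self, group: str) -> pd.DataFrame:
        sub = self.table.subset(group)
        return relative_abundance(sub) if self.use_relative else sub.counts

    def fit(
        self,
        n_boot: int = 1000,
        seed: int = 0,
        k_clusters: int | None = None,
    ) -> "MicrobiomeNetworkResults":
        """Build, cluster, bootstrap and compare the per-group networks.

        ``k_clusters=None`` selects each group's cluster count by the
        eigengap heuristic.  Deterministic given ``seed``.
        """
        groups = self.table.group_names
        correlations: dict[str, CorrelationResult] = {}
        graphs: dict[str, nx.Graph] = {}
        clusters: dict[str, pd.Series] = {}
        summaries = {}
        bootstrap: dict[str, dict[str, BootstrapDistribution]] = {}
        for i, group in enumerate(groups):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corr = spearman_matrix(self._group_data(group), self.min_variance)
                graph = build_graph(corr, alpha=self.alpha)
                correlations[group] = corr
                graphs[group] = graph
                summaries[group] = network_summary(graph).to_dict()
                try:
                    clusters[group] = spectral_clusters(graph, k=k_clusters, seed=seed)
                except GutnetError:
                    clusters[group] = pd.Series(
                        0, index=list(graph.nodes), name="cluster"
                    )
                bootstrap[group] = bootstrap_topology(
                    self.table,
                    group,
                    B=n_boot,
                    alpha=self.alpha,
                    seed=seed + 1000 * (i + 1),
                    use_relative=self.use_relative,
                    min_variance=self.min_variance,
                )
        comparisons: dict[str, AnovaResult] = {}
        if len(groups) >= 2 and n_boot >= 2:
            for parameter in PARAMETERS:
                try:
                    comparisons[parameter] = compare_groups(bootstrap, parameter)
                except GutnetError:
                    pass  # e.g. a parameter constant in every group
        return MicrobiomeNetworkResults(
            model=self,
            correlations=correlations,
            graphs=graphs,
            clusters=clusters,
            summaries=pd.DataFrame(summaries).T.loc[list(groups), list(PARAMETERS)],
            bootstrap=bootstrap,
            comparisons=comparisons,
            n_boot=n_boot,
            seed=seed,
        )


@dataclass
class MicrobiomeNetworkResults:
    """Fitted per-group networks, bootstrap distributions and comparisons."""

    model: MicrobiomeNetworkModel
    correlations: dict[str, CorrelationResult]
    graphs: dict[str, nx.Graph]
    clusters: dict[str, pd.Series]
    summaries: pd.DataFrame  # groups x parameters (point estimates)
    bootstrap: dict[str, dict[str, BootstrapDistribution]]
    comparisons: dict[str, AnovaResult] = field(default_factory=dict)
    n_boot: int = 0
    seed: int = 0

    @property
    def group_names(self) -> list[str]:
        return list(self.graphs)

    def bootstrap_frame(self, parameter: str) -> pd.DataFrame:
        """Replicate values of one parameter, one column per group."""
        return pd.DataFrame(
            {g: dists[parameter].replicates for g, dists in self.bootstrap.items()}
        )

    def comparison_table(self) -> pd.DataFrame:
        """Per parameter: ANOVA F and p plus Tukey-adjusted pairwise p-values."""
        rows = []
        for parameter, res in self.comparisons.items():
            row = {"parameter": parameter, "F": res.F, "p": res.p}
            for _, pair in res.pairwise.iterrows():
                row[f"tukey_p[{pair.group_a}|{pair.group_b}]"] = pair.p_adjusted
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of networks, bootstrap ranges and comparisons."""
        lines = [
            "Microbiome co-occurrence network analysis",
            "=" * 57,
            f"groups: {', '.join(self.group_names)}   "
            f"edge filter: Spearman p < {self.model.alpha}   "
            f"bootstrap B = {self.n_boot}",
            "",
            "Network size",
        ]
        for g, graph in self.graphs.items():
            k = self.clusters[g].nunique()
            lines.append(
                f"  {g}: {graph.number_of_nodes()} nodes, "
                f"{graph.number_of_edges()} edges, {k} spectral clusters"
            )
        lines += ["", "Topology parameters (point estimate [bootstrap replicate 2.5-97.5%])"]
        for parameter in self.summaries.columns:
            lines.append(f"  {parameter}:")
            for g in self.group_names:
                reps = self.bootstrap[g][parameter].replicates
                lo, hi = np.percentile(reps, [2.5, 97.5])
                lines.append(
                    f"    {g:>12}: {self.summaries.loc[g, parameter]:.4f} "
                    f"[{lo:.4f}, {hi:.4f}]"
                )
        if self.comparisons:
            lines += ["", "Group comparisons (one-way ANOVA + Tukey HSD on replicates)"]
            table = self.comparison_table()
            lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def plot_parameter(self, parameter: str, ax=None):
        """Boxplot of a parameter's bootstrap replicates per group."""
        from . import plotting

        return plotting.parameter_boxplot(self, parameter, ax=ax)
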