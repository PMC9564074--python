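"""Diagnostic plots: abundance bars, bootstrap boxplots, PC scatter, networks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe default

import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

__all__ = ["stacked_abundance", "parameter_boxplot", "pc_scatter", "draw_network"]


def stacked_abundance(top_k_frame: pd.DataFrame, ax=None):
    """Stacked bars of per-group mean relative abundances (top-k + Other)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    top_k_frame.plot(kind="bar", stacked=True, ax=ax, width=0.8, legend=False)
    ax.set_ylabel("mean relative abundance")
    ax.set_ylim(0, 1)
    ax.legend(loc="center left", bbox_to_anchor=(1.0, 0.5), fontsize=6)
    return ax


def parameter_boxplot(results, parameter: str, ax=None):
    """Boxplot of one topology parameter's bootstrap replicates per group."""
    frame = results.bootstrap_frame(parameter)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([frame[c] for c in frame.columns], tick_labels=list(frame.columns))
    ax.set_ylabel(parameter)
    return ax


def pc_scatter(scores: pd.DataFrame, groups: pd.Series, explained, ax=None):
    """PC1/PC2 scatter colored by group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for group in dict.fromkeys(groups):
        mask = (groups == group).to_numpy()
        ax.scatter(scores.loc[mask, "PC1"], scores.loc[mask, "PC2"], label=group, s=20)
    ax.set_xlabel(f"PC1 ({100 * explained[0]:.0f}% var)")
    ax.set_ylabel(f"PC2 ({100 * explained[1]:.0f}% var)")
    ax.legend(fontsize=7)
    return ax


def draw_network(graph: nx.Graph, clusters: pd.Series | None = None, ax=None, seed: int = 0):
    """Spring-layout drawing with edge width by weight, color by cluster."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pos = nx.spring_layout(graph, seed=seed, weight="weight")
    colors = clusters.loc[list(graph.nodes)] if clusters is not None else "tab:blue"
    widths = [2 * d.get("weight", 0.5) for _, _, d in graph.edges(data=True)]
    nx.draw_networkx_nodes(graph, pos, node_size=30, node_color=colors, cmap="tab10", ax=ax)
    nx.draw_networkx_edges(graph, pos, width=widths, alpha=0.4, ax=ax)
    ax.set_axis_off()
    return ax
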