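"""Multi-omics correlation network across genera, pathways and phenotypes.

Feature blocks (genus abundances, pathway abundances, bone phenotypes, blood
pressure) are aligned on sample IDs, min-max rescaled to [0, 1], and pooled
into one Spearman correlation matrix.  All pairwise p-values are jointly
adjusted by the Benjamini-Yekutieli procedure — valid under arbitrary
dependence, which correlated omics features certainly exhibit — and pairs
with adjusted p below ``alpha`` become edges weighted by |rho|.  Because
Spearman correlation is rank-based, the min-max rescaling changes no edge;
it is kept as the display convention for the merged table.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import GutnetError, OmicsBlock
from .corrnet import spearman_matrix

__all__ = ["rescale_unit", "by_adjust", "multiomic_graph"]

logger = logging.getLogger(__name__)


def rescale_unit(block: OmicsBlock) -> OmicsBlock:
    """Min-max rescale every feature to [0, 1]; constant features -> 0, flagged."""
    values = block.values.to_numpy(dtype=float)
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe = np.where(constant, 1.0, span)
    scaled = (values - lo) / safe
    scaled[:, constant] = 0.0
    out = OmicsBlock(
        pd.DataFrame(scaled, index=block.values.index, columns=block.values.columns),
        tag=block.tag,
        flags=dict(block.flags),
    )
    flagged = list(block.values.columns[constant])
    if flagged:
        out.flags["constant"] = flagged
        logger.warning("block %r: constant feature(s) mapped to 0: %s", block.tag, flagged)
    return out


def by_adjust(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment (arbitrary dependence).

    Sorted p-values are inflated by ``m * c(m) / k`` with the harmonic
    number ``c(m) = sum_{i<=m} 1/i``, then a cumulative minimum from the
    largest rank enforces monotonicity; results are capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise GutnetError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def multiomic_graph(
    blocks: list[OmicsBlock],
    alpha: float = 0.05,
    between_blocks_only: bool = False,
) -> nx.Graph:
    """BY-filtered Spearman network over the pooled, aligned feature blocks.

    Blocks are inner-joined on sample IDs (dropped samples are logged);
    fewer than 4 shared samples raises.  With ``between_blocks_only`` the
    adjustment and the edge filter consider only pairs whose endpoints lie
    in different blocks.  Nodes carry a ``block`` attribute with the block
    tag; edges carry ``weight`` (=|rho|), ``rho``, ``p`` and ``p_adjusted``.
    """
    if len(blocks) < 2:
        raise GutnetError("need >= 2 omics blocks")
    shared = blocks[0].values.index
    for block in blocks[1:]:
        shared = shared.intersection(block.values.index)
    dropped = sorted(set().union(*(b.values.index for b in blocks)) - set(shared))
    if dropped:
        logger.warning("dropping %d sample(s) absent from some block: %s", len(dropped), dropped)
    if len(shared) < 4:
        raise GutnetError(f"only {len(shared)} shared samples after alignment; need >= 4")
    rescaled = [rescale_unit(b) for b in rescaled_input(blocks, shared)]
    merged = pd.concat([b.prefixed() for b in rescaled], axis=1)
    if merged.columns.duplicated().any():
        dupes = list(merged.columns[merged.columns.duplicated()])
        raise GutnetError(f"duplicate feature names after tag prefixing: {dupes}")
    block_of = {}
    for b in rescaled:
        for name in b.prefixed().columns:
            block_of[name] = b.tag
    corr = spearman_matrix(merged)
    names = corr.feature_names
    rho = corr.rho.to_numpy()
    p = corr.pvalue.to_numpy()
    iu, ju = np.triu_indices(len(names), k=1)
    if between_blocks_only:
        mask = np.array(
            [block_of[names[i]] != block_of[names[j]] for i, j in zip(iu, ju)]
        )
        iu, ju = iu[mask], ju[mask]
    adjusted = by_adjust(p[iu, ju])
    graph = nx.Graph()
    for name in names:
        graph.add_node(name, block=block_of[name])
    keep = adjusted < alpha
    for i, j, q in zip(iu[keep], ju[keep], adjusted[keep]):
        r = rho[i, j]
        graph.add_edge(
            names[i],
            names[j],
            weight=abs(float(r)),
            rho=float(r),
            p=float(p[i, j]),
            p_adjusted=float(q),
        )
    return graph


def rescaled_input(blocks: list[OmicsBlock], shared) -> list[OmicsBlock]:
    """Blocks restricted to the shared samples, in input order."""
    return [OmicsBlock(b.values.loc[shared], b.tag, dict(b.flags)) for b in blocks]
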