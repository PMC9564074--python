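"""Differential-abundance summaries and PC projection of selected features.

Selection uses a nonparametric engine: a per-feature Kruskal-Wallis test
across the experimental groups on relative abundances (depth-invariant),
with Benjamini-Hochberg control of the false discovery rate across features.
Group-pair log2 fold changes of pseudocounted mean relative abundances are
reported for display, and selected features can be projected onto their
first two principal components.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountTable, GutnetError
from .profiles import relative_abundance

__all__ = ["log2_fold_change", "select_differential", "pc_projection"]

logger = logging.getLogger(__name__)


def log2_fold_change(
    table: CountTable, group_a: str, group_b: str, pseudocount: float = 0.5
) -> pd.Series:
    """Per-feature ``log2((mean_a + pc) / (mean_b + pc))`` on relative abundances.

    Antisymmetric under exchanging the two groups.  The pseudocount keeps
    zero-mean features displayable; it must be > 0.
    """
    if pseudocount <= 0:
        raise GutnetError("pseudocount must be > 0")
    for g in (group_a, group_b):
        if g not in set(table.groups):
            raise GutnetError(f"unknown group label: {g!r}")
    rel = relative_abundance(table)
    mean_a = rel.loc[table.groups == group_a].mean(axis=0)
    mean_b = rel.loc[table.groups == group_b].mean(axis=0)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    lfc.name = f"log2FC[{group_a}/{group_b}]"
    return lfc


def select_differential(
    table: CountTable, alpha: float = 0.05, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Kruskal-Wallis + BH selection of differentially abundant features.

    Returns a feature-indexed frame with the raw KW p-value, BH-adjusted
    p-value, ``selected`` flag (adjusted p < alpha), and pairwise log2 fold
    changes for every group pair.  Constant features get p = 1 by
    convention (no rank information) and are logged.
    """
    groups = table.group_names
    if len(groups) < 2:
        raise GutnetError("differential selection needs >= 2 groups")
    for g in groups:
        if (table.groups == g).sum() < 2:
            raise GutnetError(f"group {g!r} has fewer than 2 samples")
    rel = relative_abundance(table)
    by_group = [rel.loc[table.groups == g].to_numpy() for g in groups]
    pvals = np.ones(rel.shape[1])
    constant = []
    for j, feature in enumerate(rel.columns):
        columns = [arr[:, j] for arr in by_group]
        pooled = np.concatenate(columns)
        if np.ptp(pooled) == 0:
            constant.append(feature)
            continue  # p stays 1 by convention
        pvals[j] = stats.kruskal(*columns).pvalue
    if constant:
        logger.info("%d constant feature(s) given p=1: %s", len(constant), constant[:10])
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"p": pvals, "p_adjusted": adjusted, "selected": adjusted < alpha},
        index=rel.columns,
    )
    for a, b in ((a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]):
        out[f"log2FC[{a}/{b}]"] = log2_fold_change(table, a, b, pseudocount)
    return out


def pc_projection(
    data: pd.DataFrame, standardize: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scores on the first two principal components plus variance fractions.

    Columns are centered (and optionally standardized); scores are the data
    projected on the top-2 right singular vectors.  PC signs are arbitrary.
    Raises if the centered matrix has rank < 2, listing degenerate features.
    """
    df = pd.DataFrame(data)
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise GutnetError("PC projection needs >= 2 features and >= 3 samples")
    x = df.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        degenerate = list(df.columns[sd == 0])
        if degenerate:
            raise GutnetError(f"constant features cannot be standardized: {degenerate}")
        x = x / sd
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    # rank 1 is legitimate (all variance on PC1); rank 0 is not
    if s[0] <= 0:
        degenerate = list(df.columns[x.std(axis=0) == 0])
        raise GutnetError(
            f"feature matrix has rank 0; degenerate features: {degenerate}"
        )
    scores = x @ vt[:2].T
    var = s**2
    explained = var[:2] / var.sum()
    frame = pd.DataFrame(scores, index=df.index, columns=["PC1", "PC2"])
    return frame, explained
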