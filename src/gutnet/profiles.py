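"""Relative abundance, per-sample alpha diversity, and top-k genus summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountTable, GutnetError

__all__ = ["relative_abundance", "diversity", "top_k_taxa", "DiversityProfile"]


def _check_totals(table: CountTable) -> np.ndarray:
    totals = table.counts.sum(axis=1).to_numpy(dtype=float)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise GutnetError(f"samples with zero total counts: {bad}")
    return totals


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample proportions: each row sums to 1."""
    totals = _check_totals(table)
    return table.counts.div(totals, axis=0)


@dataclass
class DiversityProfile:
    """Per-sample richness (observed taxa) and Shannon diversity."""

    richness: pd.Series
    shannon: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"richness": self.richness, "shannon": self.shannon})


def diversity(table: CountTable, base: str = "e") -> DiversityProfile:
    """Observed richness and Shannon entropy of each sample's composition.

    Richness counts taxa with count > 0.  Shannon is ``-sum p_i log p_i``
    over taxa present in the sample, in nats by default (``base='2'`` for
    bits).
    """
    _check_totals(table)
    rel = relative_abundance(table).to_numpy()
    richness = (table.counts.to_numpy() > 0).sum(axis=1)
    log = np.log2 if base == "2" else np.log
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rel > 0, rel * log(rel), 0.0)
    shannon = -terms.sum(axis=1)
    idx = table.counts.index
    return DiversityProfile(
        pd.Series(richness, index=idx, name="richness"),
        pd.Series(shannon, index=idx, name="shannon"),
    )


def top_k_taxa(table: CountTable, k: int = 20) -> pd.DataFrame:
    """Per-group mean relative abundance of the k most abundant taxa + "Other".

    Ranking is computed on the pooled dataset (mean relative abundance over
    all samples, ties broken by taxon name) so every group shares one
    legend.  Returns a ``groups x (k taxa + "Other")`` frame whose rows sum
    to 1.  If ``k >= n_taxa`` all taxa are named and "Other" is zero.
    """
    if k < 1:
        raise GutnetError("k must be >= 1")
    rel = relative_abundance(table)
    overall = rel.mean(axis=0)
    ranking = sorted(overall.index, key=lambda t: (-overall[t], t))
    top = ranking[: min(k, len(ranking))]
    rows = {}
    for group in table.group_names:
        gm = rel.loc[table.groups == group].mean(axis=0)
        named = gm[top]
        other = 0.0 if len(top) == len(ranking) else max(1.0 - named.sum(), 0.0)
        rows[group] = pd.concat([named, pd.Series({"Other": other})])
    return pd.DataFrame(rows).T
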