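"""Community-level and univariate group comparisons.

Bray-Curtis dissimilarity on relative abundances, PERMANOVA (Anderson's
pseudo-F with a seeded permutation test, optionally exhaustive enumeration),
pairwise Adonis with multiplicity correction, the Mann-Whitney U test, and
one-way ANOVA with Tukey HSD post hoc comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .containers import CountTable, GutnetError
from .profiles import relative_abundance

__all__ = [
    "bray_curtis",
    "permanova",
    "pairwise_adonis",
    "mann_whitney_u",
    "anova_tukey",
    "PermanovaResult",
    "AnovaResult",
]


def bray_curtis(table: CountTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity on relative abundances.

    ``d(a, b) = sum |a_i - b_i| / sum (a_i + b_i)``; 0 for identical
    profiles, 1 for disjoint supports.
    """
    rel = relative_abundance(table).to_numpy()
    d = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class PermanovaResult:
    """Anderson's pseudo-F partition of squared distances and permutation p."""

    pseudo_F: float
    R2: float
    p: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "pseudo_F": self.pseudo_F,
            "R2": self.R2,
            "p": self.p,
            "n_permutations": self.n_permutations,
        }


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int, ss_total: float) -> tuple[float, float]:
    n = len(codes)
    ss_within = _ss_within(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    SS_total = sum of squared distances over all pairs divided by n;
    SS_within sums squared within-group distances scaled by group size;
    ``pseudo_F = (SS_between/(g-1)) / (SS_within/(n-g))``.  The p-value
    counts label permutations whose pseudo-F reaches the observed one,
    including the identity: ``p = (#{F_perm >= F_obs} + 1) / (n_perm + 1)``.
    With ``exhaustive=True`` all distinct label arrangements are enumerated
    and the p-value is the exact fraction.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(pd.Series(list(groups)))
    n = len(labels)
    if d.shape != (n, n):
        raise GutnetError(f"distance matrix shape {d.shape} does not match {n} labels")
    uniq, codes = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise GutnetError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise GutnetError("each group needs >= 2 samples (singleton group found)")
    if not exhaustive and n_perm < 1:
        raise GutnetError("n_perm must be >= 1")
    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)
    f_obs, r2 = _pseudo_f(d2, codes, g, ss_total)

    if exhaustive:
        count = 0
        hits = 0
        for arrangement in _distinct_arrangements(codes):
            f_perm, _ = _pseudo_f(d2, arrangement, g, ss_total)
            count += 1
            if f_perm >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(float(f_obs), float(r2), hits / count, count)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(d2, rng.permutation(codes), g, ss_total)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(float(f_obs), float(r2), (hits + 1) / (n_perm + 1), n_perm)


def _distinct_arrangements(codes: np.ndarray):
    """All distinct orderings of a label multiset (exhaustive permutations)."""
    from sympy.utilities.iterables import multiset_permutations

    for perm in multiset_permutations(list(codes)):
        yield np.asarray(perm)


def pairwise_adonis(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    adjust: str = "bh",
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA restricted to every group pair, with adjusted p-values.

    ``adjust`` is "bh" (Benjamini-Hochberg, default) or "by"
    (Benjamini-Yekutieli).
    """
    if adjust not in ("bh", "by"):
        raise GutnetError(f"unknown adjustment {adjust!r}")
    d = np.asarray(dist, dtype=float)
    labels = pd.Series(list(groups)).reset_index(drop=True)
    names = list(dict.fromkeys(labels))
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(names, 2)):
        mask = labels.isin([a, b]).to_numpy()
        sub = d[np.ix_(mask, mask)]
        res = permanova(sub, labels[mask], n_perm=n_perm, seed=seed + i)
        rows.append(
            {"group_a": a, "group_b": b, "pseudo_F": res.pseudo_F, "R2": res.R2, "p": res.p}
        )
    out = pd.DataFrame(rows)
    method = "fdr_bh" if adjust == "bh" else "fdr_by"
    out["p_adjusted"] = multipletests(out["p"].to_numpy(), method=method)[1]
    return out


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (of x) with a two-sided p-value.

    Exact enumeration when ``n_x * n_y <= 400`` and there are no ties across
    the pooled sample; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise GutnetError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AnovaResult:
    """One-way ANOVA F and p with Tukey-HSD adjusted pairwise p-values."""

    F: float
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, diff, p_adjusted

    def __str__(self) -> str:
        lines = [f"one-way ANOVA: F = {self.F:.4g}, p = {self.p:.4g}", "Tukey HSD:"]
        lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


def anova_tukey(samples: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA across named groups plus Tukey HSD post hoc pairs.

    Raises if fewer than two groups, any group has < 2 observations, or all
    groups are internally constant (no within-group variance).
    """
    names = list(samples)
    arrays = [np.asarray(samples[name], dtype=float) for name in names]
    if len(arrays) < 2:
        raise GutnetError("ANOVA needs >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise GutnetError("every group needs >= 2 replicates")
    if all(np.ptp(a) == 0 for a in arrays):
        raise GutnetError("zero within-group variance in all groups")
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adjusted": float(hsd.pvalue[i, j]),
            }
        )
    return AnovaResult(float(f), float(p), pd.DataFrame(rows))
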