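"""Bray-Curtis, PERMANOVA, pairwise Adonis, Mann-Whitney, ANOVA/Tukey."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from gutnet import (
    CountTable,
    GutnetError,
    anova_tukey,
    bray_curtis,
    mann_whitney_u,
    pairwise_adonis,
    permanova,
)


def table_from(rows, groups):
    idx = [f"s{i}" for i in range(len(rows))]
    return CountTable(
        pd.DataFrame(rows, index=idx, columns=[f"t{j}" for j in range(len(rows[0]))]),
        pd.Series(groups, index=idx),
    )


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(table_from([[3, 1, 2], [3, 1, 2]], ["A", "A"]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d = bray_curtis(table_from([[5, 0], [0, 7]], ["A", "B"]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # equal totals, so raw-count and proportion arithmetic agree: 2/8
        d = bray_curtis(table_from([[2, 2], [1, 3]], ["A", "B"]))
        assert d.iloc[0, 1] == pytest.approx(0.25)

    def test_symmetric_zero_diagonal_bounded(self):
        rng = np.random.default_rng(4)
        table = table_from(rng.integers(0, 50, size=(6, 8)) + 1, ["A"] * 3 + ["B"] * 3)
        d = bray_curtis(table).to_numpy()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()


def permanova_oracle_exhaustive(d, labels):
    """Full enumeration of distinct label orderings, textbook partitioning."""
    d = np.asarray(d, float)
    labels = np.asarray(labels)
    n = len(labels)
    d2 = d**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    groups = sorted(set(labels))
    g = len(groups)

    def f_of(lab):
        ss_w = 0.0
        for grp in groups:
            idx = np.flatnonzero(lab == grp)
            ss_w += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
        return ((ss_total - ss_w) / (g - 1)) / (ss_w / (n - g))

    f_obs = f_of(labels)
    seen = set()
    hits = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if f_of(np.asarray(perm)) >= f_obs - 1e-12:
            hits += 1
    return f_obs, hits / total


class TestPermanova:
    def _two_clusters(self):
        # two far-separated clusters of 3 samples each
        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(10, 0.1, (3, 2))])
        d = squareform(pdist(x))
        labels = np.array(["A"] * 3 + ["B"] * 3)
        return d, labels

    def test_exhaustive_matches_enumeration_oracle(self):
        d, labels = self._two_clusters()
        f_oracle, p_oracle = permanova_oracle_exhaustive(d, labels)
        res = permanova(d, labels, exhaustive=True)
        assert res.pseudo_F == pytest.approx(f_oracle, rel=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=0)
        # 20 distinct splits, observed split and its mirror attain the max F
        assert res.p == pytest.approx(1 / 10)
        assert res.n_permutations == 20

    def test_seeded_determinism(self):
        d, labels = self._two_clusters()
        a = permanova(d, labels, n_perm=99, seed=5)
        b = permanova(d, labels, n_perm=99, seed=5)
        assert a.p == b.p and a.pseudo_F == b.pseudo_F

    def test_p_has_permutation_floor(self):
        d, labels = self._two_clusters()
        res = permanova(d, labels, n_perm=99, seed=1)
        assert res.p >= 1 / 100
        assert 0 <= res.R2 <= 1

    def test_univariate_euclidean_reduces_to_anova_f(self):
        # PERMANOVA pseudo-F on Euclidean distances of 1-D data equals the
        # classical one-way ANOVA F statistic
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        labels = np.array(["A", "B", "C"] * 4)
        d = np.abs(y[:, None] - y[None, :])
        res = permanova(d, labels, n_perm=9, seed=0)
        f_classic = stats.f_oneway(*(y[labels == g] for g in "ABC")).statistic
        assert res.pseudo_F == pytest.approx(float(f_classic), rel=1e-10)

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(11)
        x = rng.normal(size=(12, 4))
        x[:6] += 1.5
        d = squareform(pdist(x))
        labels = ["A"] * 6 + ["B"] * 6
        res = permanova(d, labels, n_perm=999, seed=0)
        ref = skbio_permanova(DistanceMatrix(d), grouping=labels, permutations=999)
        assert res.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-10)
        assert res.p == pytest.approx(float(ref["p-value"]), abs=0.05)

    def test_singleton_group_raises(self):
        d = squareform(pdist(np.random.default_rng(0).normal(size=(4, 2))))
        with pytest.raises(GutnetError):
            permanova(d, ["A", "A", "A", "B"], n_perm=9)


class TestPairwiseAdonis:
    def test_three_groups_give_three_pairs(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 3))
        x[8:] += 4.0  # group C is the outlier
        d = squareform(pdist(x))
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        out = pairwise_adonis(d, labels, n_perm=199, seed=0)
        assert len(out) == 3
        assert set(map(tuple, out[["group_a", "group_b"]].to_numpy())) == {
            ("A", "B"), ("A", "C"), ("B", "C"),
        }
        # the outlying group carries the small p-values
        pc = out.set_index(["group_a", "group_b"])["p"]
        assert max(pc[("A", "C")], pc[("B", "C")]) < pc[("A", "B")]
        # BH oracle: step-up on the three raw p-values
        p = out["p"].to_numpy()
        order = np.argsort(p)[::-1]
        adj = np.minimum.accumulate((p * 3 / (np.argsort(np.argsort(p)) + 1))[order])[
            np.argsort(order)
        ]
        np.testing.assert_allclose(out["p_adjusted"], np.minimum(adj, 1.0), atol=1e-12)

    def test_identical_groups_near_one(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 3))
        d = squareform(pdist(x))
        out = pairwise_adonis(d, ["A"] * 4 + ["B"] * 4 + ["C"] * 4, n_perm=199, seed=0)
        # no pair should look significant; exact values bounce with the draw
        assert (out["p_adjusted"] > 0.05).all()


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        # all 6 arrangements of ranks: the observed extreme one has p = 2/6
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_symmetric(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n_x n_y / 2
        assert p == pytest.approx(1.0)

    def test_u_conservation_under_swap(self):
        x, y = [1.5, 2.5, 9.0], [0.5, 3.5, 4.5, 8.0]
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == len(x) * len(y)

    def test_empty_raises(self):
        with pytest.raises(GutnetError):
            mann_whitney_u([], [1.0])


class TestAnovaTukey:
    def test_two_groups_match_pooled_t_test(self):
        # with k=2 Tukey HSD reduces to the pooled-variance t-test
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=8), rng.normal(1.0, 1, size=9)
        res = anova_tukey({"a": a, "b": b})
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.pairwise["p_adjusted"].iloc[0] == pytest.approx(t.pvalue, abs=1e-9)
        assert res.p == pytest.approx(t.pvalue, abs=1e-9)

    def test_all_constant_raises(self):
        with pytest.raises(GutnetError):
            anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_null_f_near_one_on_average(self):
        rng = np.random.default_rng(9)
        fs = [
            anova_tukey({g: rng.normal(size=10) for g in "abc"}).F for _ in range(300)
        ]
        assert np.mean(fs) == pytest.approx(1.0, abs=0.15)
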