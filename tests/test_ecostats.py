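"""Community statistics: diversity, ANOVA/Tukey, Bray-Curtis, ANOSIM, nMDS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from reefscan import data
from reefscan.ecostats import (
    anosim,
    anova_tukey,
    bray_curtis,
    community_matrix,
    nmds,
    normality_test,
    shannon,
    sqrt_transform,
)


class TestShannon:
    @pytest.mark.parametrize("survey,H,E", [
        ("2015", 1.14, None),   # E computes to 0.50, published as 0.49
        ("2017", 1.27, 0.55),
        ("2019-PQ", 0.82, None),
    ])
    def test_reference_survey_indices(self, survey, H, E):
        """The published H (and, for 2017, E) values from the mean covers."""
        cover = data.reference_mean_covers()[survey].to_numpy()
        div = shannon(cover, S=10)
        assert round(div.H, 2) == H
        if E is not None:
            assert round(div.E, 2) == E

    def test_uniform_community_maximal(self):
        div = shannon(np.full(10, 10.0))
        assert div.H == pytest.approx(np.log(10))
        assert div.E == pytest.approx(1.0)

    def test_single_category_zero(self):
        div = shannon([100.0] + [0.0] * 9)
        assert div.H == 0.0 and div.E == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon(np.zeros(10))

    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=10)
           .filter(lambda v: sum(v) > 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_entropy_bounds(self, covers):
        div = shannon(covers)
        assert -1e-9 <= div.H <= np.log(len(covers)) + 1e-9
        assert -1e-9 <= div.E <= 1.0 + 1e-9


class TestTransforms:
    def test_sqrt_values_and_double_transform_guard(self, scheme):
        rows = [("2019", t, "PQ", g, v) for t in (1, 2)
                for g, v in [("A", 81.0), ("B", 19.0)]]
        table = pd.DataFrame(rows, columns=["survey", "transect", "method",
                                            "category", "cover_pct"])
        cm = community_matrix(table)
        sq = sqrt_transform(cm)
        assert sq.values.loc[0, "A"] == pytest.approx(9.0)
        assert sq.values.loc[0, "B"] == pytest.approx(np.sqrt(19.0))
        with pytest.raises(ValueError, match="already"):
            sqrt_transform(sq)

    def test_community_matrix_row_sums_validated(self):
        rows = [("2019", 1, "PQ", "A", 120.0)]
        table = pd.DataFrame(rows, columns=["survey", "transect", "method",
                                            "category", "cover_pct"])
        with pytest.raises(ValueError, match="row sums"):
            community_matrix(table)


class TestNormality:
    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_test([3.0, 3.0, 3.0, 3.0])

    def test_statistic_bounded_by_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            w, p = normality_test(rng.normal(size=20))
            assert w <= 1.0

    def test_matches_independent_reference_value(self):
        """Frozen W and p cross-checked against an independent
        implementation of the Shapiro-Wilk algorithm."""
        x = [2.3, 4.1, 3.3, 5.8, 2.9, 3.7, 4.4, 6.1, 3.0, 4.9, 5.2, 2.1]
        w, p = normality_test(x)
        assert w == pytest.approx(0.9591560777, abs=1e-6)
        assert p == pytest.approx(0.7717168182, abs=1e-6)


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        res = anova_tukey({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0],
                           "c": [1.0, 2.0, 3.0]})
        assert res.F == pytest.approx(0.0)
        assert not res.tukey["reject"].any()
        assert len(set(res.letters.values())) == 1

    def test_two_groups_equals_t_test(self):
        a, b = [3.1, 4.2, 2.8, 3.9], [5.0, 6.1, 5.7, 4.9]
        res = anova_tukey({"a": a, "b": b})
        from scipy import stats as sps

        t, p = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t * t)
        assert res.p == pytest.approx(p)

    def test_matches_textbook_arithmetic(self):
        """Hand-computed F for a 3-group, 3-replicate worked dataset."""
        groups = {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 3.0, 4.0],
                  "g3": [4.0, 5.0, 6.0]}
        flat = np.concatenate(list(groups.values()))
        grand = flat.mean()
        ss_between = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                        for v in groups.values())
        f_oracle = (ss_between / 2) / (ss_within / 6)
        res = anova_tukey(groups)
        assert res.F == pytest.approx(f_oracle)

    def test_letters_separate_distinct_groups(self):
        res = anova_tukey({"lo": [1.0, 1.1, 0.9, 1.0],
                           "hi": [9.0, 9.2, 8.9, 9.1]})
        assert res.letters["lo"] != res.letters["hi"]

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            anova_tukey({"a": [1.0], "b": [2.0, 3.0]})


def _brute_bray_curtis(x):
    n = len(x)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(abs(x[i][k] - x[j][k]) for k in range(len(x[i])))
            den = sum(x[i][k] + x[j][k] for k in range(len(x[i])))
            d[i, j] = num / den if den else 0.0
    return d


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        x = np.tile([10.0, 20.0, 70.0], (3, 1))
        assert np.allclose(bray_curtis(x), 0.0)

    def test_disjoint_support_one(self):
        x = np.array([[50.0, 50.0, 0.0, 0.0], [0.0, 0.0, 30.0, 70.0]])
        d = bray_curtis(x)
        assert d[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        x = np.random.default_rng(7).random((10, 6)) * 50
        d = bray_curtis(x)
        assert np.allclose(d, _brute_bray_curtis(x), atol=1e-12)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_negative_data_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            bray_curtis(np.array([[1.0, -2.0], [3.0, 4.0]]))


def _brute_anosim_r(d, labels):
    """Direct rank-formula oracle (independent of the implementation)."""
    from scipy.stats import rankdata

    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    ranks = rankdata([d[i, j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4)


class TestAnosim:
    def _two_cloud(self, sep, n=4, seed=0):
        rng = np.random.default_rng(seed)
        x = np.abs(np.vstack([rng.normal(1, 0.1, (n, 5)),
                              rng.normal(1 + sep, 0.1, (n, 5))]))
        return bray_curtis(x), np.array(["a"] * n + ["b"] * n)

    def test_complete_separation_r_one(self):
        d, labels = self._two_cloud(sep=10.0)
        res = anosim(d, labels, n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_n6(self):
        """All 20 relabelings of two groups of three, enumerated exactly."""
        d, _ = self._two_cloud(sep=1.0, n=3, seed=3)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        r_obs = _brute_anosim_r(d, labels)
        res = anosim(d, labels, n_permutations=9999, seed=1)
        assert res.R == pytest.approx(r_obs, abs=1e-12)
        perm_rs = []
        for pos in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            for i in pos:
                lab[i] = "a"
            perm_rs.append(_brute_anosim_r(d, lab))
        exact_p = np.mean([r >= r_obs - 1e-12 for r in perm_rs])
        assert res.p == pytest.approx(exact_p, abs=0.05)

    def test_null_mean_r_near_zero(self):
        """Random relabelings: the permutation null is centered on zero."""
        d, labels = self._two_cloud(sep=0.0, n=5, seed=4)
        rng = np.random.default_rng(0)
        rs = [_brute_anosim_r(d, labels[rng.permutation(len(labels))])
              for _ in range(300)]
        assert abs(np.mean(rs)) < 0.05

    def test_monotone_transform_invariance(self):
        d, labels = self._two_cloud(sep=0.5, seed=5)
        a = anosim(d, labels, n_permutations=99, seed=2)
        b = anosim(d ** 2, labels, n_permutations=99, seed=2)
        assert a.R == pytest.approx(b.R, abs=1e-12)
        assert a.p == b.p

    def test_seeded_p_reproducible(self):
        d, labels = self._two_cloud(sep=0.5, seed=6)
        a = anosim(d, labels, n_permutations=999, seed=9)
        b = anosim(d, labels, n_permutations=999, seed=9)
        assert (a.R, a.p) == (b.R, b.p)

    def test_agrees_with_independent_library(self):
        """Cross-check R against scikit-bio's ANOSIM on the same input."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        d, labels = self._two_cloud(sep=0.8, n=5, seed=7)
        ours = anosim(d, labels, n_permutations=999, seed=0)
        theirs = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(d), grouping=list(labels),
            permutations=999)
        assert ours.R == pytest.approx(float(theirs["test statistic"]), abs=1e-9)

    def test_group_of_one_rejected(self):
        d = bray_curtis(np.random.default_rng(1).random((4, 3)))
        with pytest.raises(ValueError, match="size 1"):
            anosim(d, ["a", "a", "a", "b"], n_permutations=9, seed=0)

    def test_synthetic_2017_vs_2019_complete_separation(self, scheme):
        """Simulated surveys with the published mean separation give R = 1
        in nearly every seed: the two communities do not overlap."""
        from reefscan.scene import simulate_survey_set

        means = data.reference_mean_covers()
        hits = 0
        for seed in range(5):
            sset = simulate_survey_set(
                {"2017": dict(means["2017"]), "2019": dict(means["2019-PQ"])},
                n_transects=5, seed=seed, scheme=scheme,
                transect_length_m=1.0, swath_width_m=0.5, pixel_size_m=0.02)
            cm = community_matrix(sset.truth, categories=scheme.group_names)
            res = anosim(bray_curtis(cm), cm.meta["survey"].to_numpy(),
                         n_permutations=199, seed=seed)
            hits += res.R == pytest.approx(1.0)
        assert hits >= 5 * 0.95 - 1e-9


class TestNmds:
    def test_perfect_recovery_of_euclidean_configuration(self):
        pts = np.random.default_rng(1).normal(size=(12, 2))
        d = squareform(pdist(pts))
        res = nmds(d, k=2, n_restarts=10, seed=0)
        assert res.stress < 0.01

    def test_stress_non_increasing_within_run(self):
        x = np.random.default_rng(2).random((10, 4)) * 40
        d = bray_curtis(x / x.sum(axis=1, keepdims=True) * 100)
        res = nmds(d, k=2, n_restarts=5, seed=1)
        diffs = np.diff(res.stress_history)
        assert (diffs <= 1e-8).all()

    def test_shepard_rank_correlation(self):
        """Ordination distances preserve the rank order of dissimilarities
        on a 15-sample simulated community set."""
        rng = np.random.default_rng(3)
        comm = np.abs(np.vstack([rng.normal(m, 1.0, (5, 6))
                                 for m in (2.0, 6.0, 12.0)]))
        d = bray_curtis(comm)
        res = nmds(d, k=2, n_restarts=10, seed=2)
        iu = np.triu_indices(15, 1)
        conf = squareform(pdist(res.coordinates))
        from scipy.stats import spearmanr

        rho = spearmanr(d[iu], conf[iu]).statistic
        assert rho > 0.95

    def test_too_few_samples_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="at least"):
            nmds(d, k=2)
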