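"""ROC AUC, rank-sum test, correlation ratio and balanced subsampling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from msimarker.discover import (ComparisonSpec, correlation_ratio, discover,
                                roc_auc, subsample_balanced, wilcoxon_ranksum)

from conftest import make_peak_matrix


def brute_force_auc(a, b):
    """P(a > b) + half the ties, by explicit pair enumeration."""
    wins = sum(1.0 for x in a for y in b if x > y)
    ties = sum(1.0 for x in a for y in b if x == y)
    return (wins + 0.5 * ties) / (len(a) * len(b))


def permutation_ranksum_p(a, b):
    """Exact two-sided rank-sum p over all group labelings of the pooled data."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    mean = ranks.sum() * n_a / len(pooled)
    stat_obs = abs(obs - mean)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - mean) >= stat_obs - 1e-12:
            count += 1
    return count / total


class TestRocAuc:
    def test_enumerated_example(self):
        # pairs: 3>2, 3<5, 1<2, 1<5, 4>2, 4<5 -> 2 of 6
        assert roc_auc([3, 1, 4], [2, 5]) == pytest.approx(2 / 6)

    def test_perfect_separation(self):
        assert roc_auc([10, 11, 12], [1, 2]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([5, 5], [5, 5, 5]) == 0.5

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=8),
        st.lists(st.integers(0, 6), min_size=1, max_size=8),
    )
    @settings(deadline=None, derandomize=True, max_examples=300)
    def test_matches_pair_enumeration(self, a, b):
        assert roc_auc(a, b) == pytest.approx(brute_force_auc(a, b), abs=1e-12)

    def test_matches_enumeration_on_large_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 60))
            b = rng.normal(size=rng.integers(5, 60))
            assert roc_auc(a, b) == pytest.approx(brute_force_auc(a, b), abs=1e-12)

    @given(
        st.lists(st.integers(0, 9), min_size=1, max_size=10),
        st.lists(st.integers(0, 9), min_size=1, max_size=10),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_complement_identity(self, a, b):
        assert roc_auc(a, b) + roc_auc(b, a) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=30), rng.normal(size=40)
        assert roc_auc(np.exp(a), np.exp(b)) == pytest.approx(roc_auc(a, b))
        assert roc_auc(a**3, b**3) == pytest.approx(roc_auc(a, b))


class TestWilcoxonRanksum:
    def test_aneurysm_diameter_comparison(self):
        # perfectly separated 5 vs 5: exact two-sided p = 2/252
        aaa = [60, 81, 80, 110, 68]
        taa = [58, 59, 52, 57, 46]
        p = wilcoxon_ranksum(aaa, taa)
        assert p == pytest.approx(2 / 252, abs=1e-12)
        assert round(p, 2) == 0.01

    def test_identical_samples(self):
        assert wilcoxon_ranksum([4, 4, 4], [4, 4, 4, 4]) == 1.0

    @pytest.mark.parametrize("n_a,n_b", [(4, 4), (5, 5)])
    def test_exact_matches_full_permutation_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            a = rng.permutation(np.arange(n_a + n_b) + 1.0)[:n_a]
            b = np.setdiff1d(np.arange(n_a + n_b) + 1.0, a)
            assert wilcoxon_ranksum(a, b) == pytest.approx(
                permutation_ranksum_p(a, b), abs=1e-12
            )

    def test_normal_approximation_close_to_exact_at_twelve(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=12)
        b = rng.normal(0.8, 1.0, size=12)
        exact = wilcoxon_ranksum(a, b)  # tie-free, both n <= 12
        approx = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        assert abs(exact - approx) < 0.01


class TestCorrelationRatio:
    def test_indicator_correlates_perfectly(self):
        labels = [1, 1, 0, 0, 1]
        assert correlation_ratio(labels, labels) == pytest.approx(1.0)

    def test_constant_intensities_warn_and_return_zero(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert correlation_ratio([2, 2, 2, 2], [0, 1, 0, 1]) == 0.0

    def test_matches_pearson_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.normal(size=20)
            y = rng.integers(0, 2, size=20)
            if y.min() == y.max():
                continue
            assert correlation_ratio(x, y) == pytest.approx(
                sps.pearsonr(x, y.astype(float)).statistic, abs=1e-12
            )


class TestSubsampleBalanced:
    def _matrix(self, n_a, n_b):
        rng = np.random.default_rng(0)
        return make_peak_matrix(rng.lognormal(size=(n_a + n_b, 3)),
                                ["A"] * n_a + ["B"] * n_b)

    def test_equal_groups(self):
        sub = subsample_balanced(self._matrix(10, 10),
                                 ComparisonSpec("A", "B", "media", n_subsample=5, seed=1))
        assert (sub.meta["group"] == "A").sum() == 5
        assert (sub.meta["group"] == "B").sum() == 5

    def test_balanced_at_smaller_group(self):
        sub = subsample_balanced(self._matrix(10, 3),
                                 ComparisonSpec("A", "B", "media", n_subsample=5, seed=1))
        assert (sub.meta["group"] == "A").sum() == 3
        assert (sub.meta["group"] == "B").sum() == 3

    def test_absent_group_raises(self):
        with pytest.raises(ValueError, match="'C'.*'media'"):
            subsample_balanced(self._matrix(4, 4),
                               ComparisonSpec("A", "C", "media", seed=0))

    def test_seeded_and_uniform_selection(self):
        pm = self._matrix(10, 10)
        spec = ComparisonSpec("A", "B", "media", n_subsample=4, seed=9)
        first = subsample_balanced(pm, spec).meta["x"].tolist()
        assert subsample_balanced(pm, spec).meta["x"].tolist() == first
        # selection frequency of each A-row over 1000 reseeds ~ Binomial(1000, 0.4)
        counts = np.zeros(10)
        for seed in range(1000):
            sub = subsample_balanced(
                pm, ComparisonSpec("A", "B", "media", n_subsample=4, seed=seed))
            rows = sub.meta.loc[sub.meta["group"] == "A", "x"].to_numpy()
            counts[rows] += 1
        # 5 sigma band around the expected 400
        sd = np.sqrt(1000 * 0.4 * 0.6)
        assert np.all(np.abs(counts - 400) < 5 * sd)


class TestDiscover:
    def test_planted_shift_direction_and_flag(self):
        rng = np.random.default_rng(2)
        n = 200
        X = rng.lognormal(0.0, 0.5, size=(2 * n, 3))
        X[:n, 1] *= 4.0  # boosted in group A
        pm = make_peak_matrix(X, ["A"] * n + ["B"] * n)
        stats = discover(pm, ComparisonSpec("A", "B", "media", seed=0))
        boosted = stats[1]
        assert boosted.candidate
        assert boosted.direction == "higher-in-a"
        assert boosted.auc > 0.9
        assert not stats[0].candidate and not stats[2].candidate
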