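import numpy as np
import pandas as pd
import pytest

from ccvoid.errors import UsageError
from ccvoid.stats import (LongitudinalMatrix, gg_epsilon, icc, mauchly_test,
                          rm_anova)


def textbook_rm_anova_F(X):
    """Independent sums-of-squares computation from first principles."""
    n, k = X.shape
    grand = X.mean()
    ss_time = n * sum((X[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = k * sum((X[i, :].mean() - grand) ** 2 for i in range(n))
    ss_err = sum((X[i, j] - X[i, :].mean() - X[:, j].mean() + grand) ** 2
                 for i in range(n) for j in range(k))
    return (ss_time / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


class TestRMAnova:
    def test_zero_within_subject_variance_degenerate(self):
        X = np.tile(np.array([[1.0], [5.0], [9.0]]), (1, 4))
        res = rm_anova(LongitudinalMatrix(X))
        assert res.F == 0.0
        assert res.p_reported == 1.0
        assert res.degenerate == "zero_within_subject_variance"

    def test_perfect_time_effect_flagged(self):
        """Values [[1,2,3],[2,3,4],[3,4,5]]: SS_time = 6, SS_error = 0."""
        X = np.array([[1, 2, 3], [2, 3, 4], [3, 4, 5]], dtype=float)
        res = rm_anova(LongitudinalMatrix(X))
        assert np.isinf(res.F)
        assert res.degenerate == "perfect_fit"

    def test_two_timepoints_no_adjustment(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        res = rm_anova(LongitudinalMatrix(X))
        assert res.gg_epsilon == 1.0
        assert res.mauchly_W == 1.0 and res.mauchly_p == 1.0
        assert res.p_gg == pytest.approx(res.p_unadjusted)

    def test_matches_textbook_F(self, rng):
        X = rng.normal(size=(12, 4))
        res = rm_anova(LongitudinalMatrix(X))
        assert res.F == pytest.approx(textbook_rm_anova_F(X), abs=1e-10)

    def test_gg_adjusted_p_conservative_where_it_matters(self, rng):
        """Shrinking both dfs by epsilon makes the GG p conservative in the
        rejection-relevant regime (small p). Far from rejection the ordering
        can reverse — the two F survival curves cross once, well above any
        conventional significance level — so the adjustment never creates a
        rejection the unadjusted test would not also make."""
        checked = 0
        while checked < 20:
            X = rng.normal(size=(rng.integers(5, 12), rng.integers(3, 6)))
            X[:, -1] += rng.uniform(0, 2)  # push some draws toward rejection
            res = rm_anova(LongitudinalMatrix(X))
            assert not (res.p_gg < 0.05 < res.p_unadjusted)
            if res.p_unadjusted <= 0.1:
                assert res.p_gg >= res.p_unadjusted - 1e-12
                checked += 1

    def test_policy_always_reports_gg(self, rng):
        X = rng.normal(size=(10, 4))
        res = rm_anova(LongitudinalMatrix(X), policy="always")
        assert res.p_reported == res.p_gg

    def test_too_small_design_rejected(self):
        with pytest.raises(UsageError):
            LongitudinalMatrix(np.zeros((1, 5)))
        with pytest.raises(UsageError):
            LongitudinalMatrix(np.zeros((5, 1)))


class TestMauchly:
    def test_two_timepoints_trivial(self):
        m = mauchly_test(LongitudinalMatrix(np.random.default_rng(0).normal(size=(8, 2))))
        assert (m.W, m.df, m.p) == (1.0, 0, 1.0)

    def test_spherical_covariance_W_near_one(self, rng):
        """Identity-covariance data: W -> 1 as n grows."""
        X = rng.normal(size=(500, 4))
        assert mauchly_test(LongitudinalMatrix(X)).W > 0.97

    def test_null_rejection_rate_near_alpha(self):
        """Under compound symmetry, Mauchly rejects at about the nominal
        rate (moderate n, chi-square approximation)."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 400
        for _ in range(reps):
            X = rng.normal(size=(60, 3)) + rng.normal(size=(60, 1))
            if mauchly_test(LongitudinalMatrix(X)).p < 0.05:
                rejections += 1
        assert 0.025 <= rejections / reps <= 0.085

    def test_singular_covariance_warns(self):
        X = np.random.default_rng(0).normal(size=(3, 5))  # n <= k
        with pytest.warns(UserWarning, match="singular"):
            m = mauchly_test(LongitudinalMatrix(X))
        assert m.W == 0.0 and m.p == 0.0


class TestEpsilon:
    def test_spherical_equals_one(self, rng):
        X = rng.normal(size=(2000, 4))
        assert gg_epsilon(LongitudinalMatrix(X)) > 0.98

    def test_rank_one_covariance_hits_lower_bound(self):
        """A single common factor across k=5 timepoints: one nonzero
        eigenvalue, epsilon = 1/(k-1) = 0.25."""
        rng = np.random.default_rng(1)
        f = rng.normal(size=(40, 1))
        X = f * np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        assert gg_epsilon(LongitudinalMatrix(X)) == pytest.approx(0.25, abs=1e-9)

    def test_bounds_hold(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 7))
            X = rng.normal(size=(int(rng.integers(k + 2, 20)), k))
            eps = gg_epsilon(LongitudinalMatrix(X))
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_two_timepoints_is_one(self):
        assert gg_epsilon(LongitudinalMatrix(np.random.default_rng(0).normal(size=(6, 2)))) == 1.0


class TestICC:
    def test_identical_columns_perfect_agreement(self):
        X = np.tile(np.array([[1.0], [4.0], [9.0], [2.0]]), (1, 2))
        assert icc(X, "icc2_1").icc == pytest.approx(1.0)

    def test_offset_rater_consistency_vs_agreement(self):
        """A constant rater offset leaves consistency ICC at 1 but lowers
        absolute-agreement ICC (the offset is real disagreement)."""
        base = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        X = np.column_stack([base, base + 5.0])
        assert icc(X, "icc3_1").icc == pytest.approx(1.0)
        assert icc(X, "icc2_1").icc < 1.0

    def test_small_table_hand_computed(self):
        """4 subjects x 2 raters, ICC(2,1) from the mean squares directly."""
        X = np.array([[9.0, 10.0], [6.0, 6.0], [8.0, 9.0], [7.0, 8.0]])
        n, k = X.shape
        grand = X.mean()
        msr = k * ((X.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((X.mean(0) - grand) ** 2).sum() / (k - 1)
        sse = ((X - X.mean(1, keepdims=True) - X.mean(0) + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(X, "icc2_1").icc == pytest.approx(expected, abs=1e-12)

    def test_zero_between_subject_variance_flagged(self):
        X = np.array([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        with pytest.warns(UserWarning):
            res = icc(X)
        assert np.isnan(res.icc)
        assert res.degenerate == "zero_between_subject_variance"

    def test_ci_brackets_estimate(self, rng):
        X = rng.normal(size=(15, 3)) + 3 * rng.normal(size=(15, 1))
        res = icc(X, "icc2_1")
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_icc_at_most_one(self, rng):
        for _ in range(20):
            X = rng.normal(size=(8, 3))
            r = icc(X, "icc2_1")
            assert r.icc <= 1.0


class TestLongFormat:
    def test_listwise_deletion(self):
        df = pd.DataFrame({
            "subject_id": ["a", "a", "b", "b", "c"],
            "timepoint": ["t1", "t2", "t1", "t2", "t1"],
            "y": [1.0, 2.0, 3.0, 4.0, 5.0]})
        with pytest.warns(UserWarning, match="listwise"):
            mat = LongitudinalMatrix.from_long(df, "y")
        assert mat.values.shape == (2, 2)
        assert "c" not in mat.subject_ids
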