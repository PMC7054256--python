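import numpy as np
import pandas as pd
import pytest

from eegac.bank import published_bank
from eegac.cohort import (
    FeatureTable,
    bootstrap_mcc,
    knn_compare,
    normalize_subject,
    paired_tests,
    summed_band_intensity,
)
from eegac.intensity import decompose


def _table(values, subjects, conditions, columns=None, kind="summed_intensity"):
    idx = pd.MultiIndex.from_tuples(
        list(zip(subjects, conditions)), names=["subject", "condition"]
    )
    cols = columns or [f"c{i}" for i in range(np.shape(values)[1])]
    return FeatureTable(values=pd.DataFrame(values, index=idx, columns=cols), feature_kind=kind)


class TestSummedIntensity:
    def test_zero_signal_gives_zeros(self, bank):
        stack = decompose(np.zeros(4096), bank, 256.0)
        assert np.allclose(summed_band_intensity(stack), 0.0)

    def test_positive_homogeneity(self, bank):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(8192)
        s1 = summed_band_intensity(decompose(x, bank, 256.0))
        s2 = summed_band_intensity(decompose(2.0 * x, bank, 256.0))
        assert np.allclose(s2, 2.0 * s1, rtol=1e-9)

    def test_composite_low_band_dominates_top_band(self, composite_stack):
        s = summed_band_intensity(composite_stack)
        assert s[0] > s[11]


class TestNormalizeSubject:
    def test_relative_intensity(self):
        ft = _table([[2.0, 2.0, 4.0, 0.0]], ["s1"], ["a"])
        out = normalize_subject(ft)
        assert out.values.iloc[0].tolist() == [0.25, 0.25, 0.5, 0.0]

    def test_rows_sum_to_one_per_lead(self):
        rng = np.random.default_rng(0)
        cols = pd.MultiIndex.from_product([["P7", "Oz"], range(12)])
        idx = pd.MultiIndex.from_tuples([("s1", "a"), ("s2", "a")])
        ft = FeatureTable(
            values=pd.DataFrame(rng.uniform(0.1, 1, (2, 24)), index=idx, columns=cols),
            feature_kind="summed_intensity",
        )
        out = normalize_subject(ft)
        for lead in ("P7", "Oz"):
            assert np.allclose(out.values[lead].sum(axis=1), 1.0, atol=1e-12)

    def test_conductance_scale_invariance_and_ranking(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.5, 2.0, (1, 12))
        a = normalize_subject(_table(base, ["s"], ["x"]))
        b = normalize_subject(_table(37.5 * base, ["s"], ["x"]))
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())
        assert np.all(
            np.argsort(a.values.to_numpy()[0]) == np.argsort(base[0])
        )

    def test_wrong_kind_rejected(self):
        ft = _table([[1.0, 2.0]], ["s"], ["a"], kind="ac")
        with pytest.raises(ValueError):
            normalize_subject(ft)


class TestPairedTests:
    def test_identical_cohorts_give_p_one(self):
        v = np.tile(np.arange(1.0, 5.0)[:, None], (2, 3))
        ft = _table(
            v,
            ["s1", "s2", "s3", "s4"] * 2,
            ["a"] * 4 + ["b"] * 4,
            kind="ac",
        )
        res = paired_tests(ft, "a", "b")
        assert np.allclose(res.table["p_raw"], 1.0)
        assert np.allclose(res.table["t"], 0.0)

    def test_constant_nonzero_difference_degenerates_to_zero_p(self):
        a = np.ones((4, 2))
        b = np.zeros((4, 2))
        ft = _table(
            np.vstack([a, b]),
            ["s1", "s2", "s3", "s4"] * 2,
            ["x"] * 4 + ["y"] * 4,
            kind="ac",
        )
        res = paired_tests(ft, "x", "y")
        assert np.allclose(res.table["p_raw"], 0.0)
        assert res.table["degenerate"].all()

    def test_missing_pair_dropped_with_warning(self):
        ft = _table(
            [[1.0], [2.0], [3.1], [1.5], [2.5], [3.4], [9.0]],
            ["s1", "s2", "s3", "s1", "s2", "s3", "s4"],
            ["a", "a", "a", "b", "b", "b", "a"],
            kind="ac",
        )
        with pytest.warns(UserWarning, match="without both conditions"):
            res = paired_tests(ft, "a", "b")
        assert res.n_subjects == 3

    def test_rejection_rate_matches_power_oracle(self):
        # 4 of 24 cells carry a true shift; compare empirical rates
        # against an independent Monte-Carlo oracle of the same design
        rng = np.random.default_rng(0)
        n, cells, shift, alpha, reps = 30, 24, 0.8, 0.05, 300
        hits_null = hits_shift = 0
        oracle_null = oracle_shift = 0
        from scipy import stats as st

        for _ in range(reps):
            d = rng.standard_normal((n, cells))
            d[:, :4] += shift
            a = d  # condition a = b + d
            idx = [f"s{i}" for i in range(n)]
            ft = _table(
                np.vstack([a, np.zeros_like(d)]),
                idx * 2,
                ["x"] * n + ["y"] * n,
                kind="ac",
            )
            res = paired_tests(ft, "x", "y")
            p = res.table["p_raw"].to_numpy()
            hits_shift += int((p[:4] <= alpha).sum())
            hits_null += int((p[4:] <= alpha).sum())
            # oracle: direct t-test on freshly simulated differences
            d2 = rng.standard_normal((n, cells))
            d2[:, :4] += shift
            p2 = st.ttest_1samp(d2, 0.0, axis=0).pvalue
            oracle_shift += int((p2[:4] <= alpha).sum())
            oracle_null += int((p2[4:] <= alpha).sum())

        def near(x, y, trials):
            # binomial-error comparison of two empirical rates
            p = (x + y) / (2 * trials)
            se = np.sqrt(max(2 * p * (1 - p) / trials, 1e-12))
            return abs(x - y) / trials <= 4 * se + 0.01

        assert near(hits_shift, oracle_shift, reps * 4)
        assert near(hits_null, oracle_null, reps * 20)


class TestBootstrapMCC:
    def test_corrected_at_least_raw(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal((25, 40))
        d[:, 0] += 1.0
        from scipy import stats as st

        p_raw = st.ttest_1samp(d, 0.0, axis=0).pvalue
        p_corr = np.maximum(bootstrap_mcc(d, B=2000, seed=3), p_raw)
        assert np.all(p_corr >= p_raw)
        assert np.all((p_corr >= 0) & (p_corr <= 1))

    def test_single_cell_close_to_raw_bootstrap_p(self):
        rng = np.random.default_rng(4)
        d = rng.standard_normal(30) + 0.45
        p1 = bootstrap_mcc(d, B=4000, seed=0)
        from scipy import stats as st

        p_t = st.ttest_1samp(d, 0.0).pvalue
        # max over one cell is the plain bootstrap p; close to the t-test p
        assert p1.shape == (1,)
        assert p1[0] == pytest.approx(p_t, abs=0.05)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        d = rng.standard_normal((20, 10))
        assert np.array_equal(
            bootstrap_mcc(d, B=500, seed=42), bootstrap_mcc(d, B=500, seed=42)
        )


class TestKNN:
    def test_one_hot_features_are_perfect(self):
        y = np.repeat([0, 1, 2, 3], 20)
        X = np.eye(4)[y]
        res = knn_compare(X, X, y, k=5, folds=5, seed=0)
        assert res.accuracy_a == 1.0
        assert np.trace(res.confusion_a) == len(y)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1, 2, 3], 30)
        X = rng.standard_normal((len(y), 6))
        res = knn_compare(X, X, y, k=5, folds=5, seed=0)
        assert res.accuracy_a < 0.45  # chance is 0.25

    def test_confusion_row_sums_and_accuracy_identity(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1, 2], [30, 20, 10])
        X = y[:, None] + 0.8 * rng.standard_normal((len(y), 3))
        res = knn_compare(X, X, y, k=3, folds=3, seed=1)
        assert res.confusion_a.sum(axis=1).tolist() == [30, 20, 10]
        assert res.accuracy_a == pytest.approx(
            np.trace(res.confusion_a) / res.confusion_a.sum()
        )

    def test_dimensionality_mismatch_rejected(self):
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="dimensionality"):
            knn_compare(np.zeros((20, 3)), np.zeros((20, 4)), y)

    def test_small_class_warns(self):
        y = np.array([0] * 18 + [1] * 2)
        X = np.random.default_rng(0).standard_normal((20, 2))
        with pytest.warns(UserWarning, match="smallest class"):
            knn_compare(X, X, y, k=5, folds=2, seed=0)
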