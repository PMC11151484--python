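"""CV designs, fold preprocessing, metrics and importance rankers."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score

from gaitfatigue.classification_importance import (
    CVScheme,
    binarise_by_training_mean,
    binarise_fixed,
    classifier_grid,
    evaluate,
    grid_search_fit,
    lgbm_gini_importance,
    make_intersubject_folds,
    make_intrasubject_folds,
    mean_permutation_importance,
    permutation_importance_scores,
    preprocess_fold,
    run_classification,
    smote_oversample,
)
from gaitfatigue.synthetic_data import simulate_association_table

SMALL_GRIDS = {"svm": [0.1, 1, 10], "knn": [3, 5], "rf_trees": [50],
               "rf_features": ["sqrt"]}


class TestBinarise:
    def test_fixed_threshold(self):
        np.testing.assert_array_equal(
            binarise_fixed([0, 1, 2, 3, 4, 5, 6]), [0, 0, 0, 1, 1, 1, 1])

    def test_training_mean_rule(self):
        out = binarise_by_training_mean([2, 2, 3, 2.6], [2, 3])
        assert out is not None
        y_tr, y_te = out  # threshold 2.4: 2 -> low, 3 -> high
        np.testing.assert_array_equal(y_te, [0, 1])

    def test_single_class_split_skipped(self):
        assert binarise_by_training_mean([4, 4, 4], [4, 4]) is None


class TestFolds:
    def test_intersubject_partition(self, rng):
        sid = np.repeat([f"s{i}" for i in range(10)], 8)
        folds = list(make_intersubject_folds(sid, 5, rng))
        assert len(folds) == 5
        for tr, te in folds:
            assert set(sid[tr]).isdisjoint(set(sid[te]))
            assert len(set(sid[te])) == 2
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(len(sid)))

    def test_intrasubject_sizes_balanced(self, rng):
        folds = list(make_intrasubject_folds(23, 5, rng))
        sizes = sorted(len(te) for _, te in folds)
        assert max(sizes) - min(sizes) <= 1

    def test_single_window_subject_yields_no_folds(self, rng):
        assert list(make_intrasubject_folds(1, 5, rng)) == []


class TestPreprocess:
    def test_smote_reaches_parity(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0] * 30 + [1] * 10)
        Xr, yr = smote_oversample(X, y, rng)
        counts = np.bincount(yr)
        assert counts[0] == counts[1] == 30

    def test_smote_synthetic_points_interpolate(self, rng):
        X = np.column_stack([np.linspace(0, 1, 12), np.zeros(12)])
        y = np.array([0] * 9 + [1] * 3)
        Xr, yr = smote_oversample(X, y, rng)
        new = Xr[len(X):]
        minority = X[y == 1]
        assert new[:, 0].min() >= minority[:, 0].min() - 1e-12
        assert new[:, 0].max() <= minority[:, 0].max() + 1e-12

    def test_smote_impossible_with_one_minority_sample(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] * 9 + [1])
        assert smote_oversample(X, y, rng) is None

    def test_median_imputation_from_training_only(self, rng):
        X_tr = rng.normal(size=(20, 2))
        X_tr[:, 1] += 5.0
        X_te = rng.normal(size=(5, 2))
        X_te[0, 1] = np.nan
        y = np.array([0, 1] * 10)
        out = preprocess_fold(X_tr, y, X_te, rng, smote=False)
        _, _, X_te2, medians, mu, sd = out
        filled = X_te2[0, 1] * sd[1] + mu[1]
        assert filled == pytest.approx(np.median(X_tr[:, 1]))

    def test_scaling_uses_training_statistics(self, rng):
        X_tr = rng.normal(size=(30, 3))
        X_te = rng.normal(size=(10, 3)) + 100.0
        y = np.array([0, 1] * 15)
        X_tr2, _, X_te2, _, mu, sd = preprocess_fold(X_tr, y, X_te, rng, smote=False)
        np.testing.assert_allclose(X_tr2.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(X_tr2.std(axis=0), 1, atol=1e-9)
        assert X_te2.mean() > 50  # test offset survives: no test-fold leakage

    def test_no_leakage_from_poisoned_test_fold(self, rng):
        """Training-derived parameters are identical however extreme the
        test fold is."""
        X_tr = rng.normal(size=(24, 3))
        y = np.array([0, 1] * 12)
        X_te = rng.normal(size=(8, 3))
        poisoned = X_te.copy()
        poisoned[:] = 1e6
        seed_state = rng.bit_generator.state
        a = preprocess_fold(X_tr, y, X_te, np.random.default_rng(0))
        b = preprocess_fold(X_tr, y, poisoned, np.random.default_rng(0))
        np.testing.assert_array_equal(a[3], b[3])  # medians
        np.testing.assert_array_equal(a[4], b[4])  # means
        np.testing.assert_array_equal(a[5], b[5])  # sds
        np.testing.assert_array_equal(a[0], b[0])  # resampled training set


class TestGridsAndMetrics:
    def test_printed_grid_sizes(self):
        sizes = {}
        for fam in ("svm_rbf", "knn", "rf", "gnb"):
            _, grid = classifier_grid(fam, seed=0)
            n = 1
            for values in grid.values():
                n *= len(values)
            sizes[fam] = n if grid else 1
        assert sizes == {"svm_rbf": 49, "knn": 9, "rf": 18, "gnb": 1}

    def test_hand_worked_confusion_example(self):
        # TP=3, FP=1, FN=1, TN=5
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        m = evaluate(y_true, y_pred)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["balanced_accuracy"] == pytest.approx(0.7917, abs=1e-4)

    def test_perfect_predictions(self):
        m = evaluate([0, 1, 1], [0, 1, 1])
        assert m["precision"] == m["recall"] == m["balanced_accuracy"] == 1.0

    def test_all_positive_predictor_on_balanced_test(self):
        m = evaluate([0, 0, 1, 1], [1, 1, 1, 1])
        assert m["balanced_accuracy"] == pytest.approx(0.5)
        assert np.isnan(evaluate([1, 1], [0, 0])["precision"])

    def test_balanced_accuracy_matches_sklearn(self, rng):
        for _ in range(20):
            y_true = rng.integers(0, 2, size=30)
            y_pred = rng.integers(0, 2, size=30)
            if len(np.unique(y_true)) < 2:
                continue
            ours = evaluate(y_true, y_pred)["balanced_accuracy"]
            assert ours == pytest.approx(balanced_accuracy_score(y_true, y_pred))

    def test_separable_blobs_all_families(self, rng):
        n = 60
        X = np.vstack([rng.normal(-3, 0.4, size=(n, 2)),
                       rng.normal(+3, 0.4, size=(n, 2))])
        y = np.array([0] * n + [1] * n)
        for fam in ("svm_rbf", "knn", "rf", "gnb"):
            model, _ = grid_search_fit(X, y, fam, seed=0, inner_folds=3,
                                       grids=SMALL_GRIDS)
            m = evaluate(y, model.predict(X))
            assert m["balanced_accuracy"] >= 0.95


@pytest.fixture(scope="module")
def coupled():
    rng = np.random.default_rng(60)
    df = simulate_association_table(8, 18, 3.0, 0.4, rng=rng)
    df = df.rename(columns={"x": "feat"})
    df["noise"] = rng.standard_normal(len(df))
    df["pf_score"] = df["score"]
    return df


class TestRunClassification:
    def test_intersubject_no_subject_on_both_sides(self, coupled):
        res = run_classification(coupled, ["feat", "noise"], "pf_score",
                                 CVScheme("intersubject"), seed=0,
                                 grids=SMALL_GRIDS, inner_folds=3,
                                 families=("gnb",))
        assert len(res) > 0
        assert res["balanced_accuracy"].between(0, 1).all()

    def test_intrasubject_reports_per_subject(self, coupled):
        res = run_classification(coupled, ["feat", "noise"], "pf_score",
                                 CVScheme("intrasubject"), seed=0,
                                 grids=SMALL_GRIDS, inner_folds=3,
                                 families=("gnb",))
        assert res["subject_id"].notna().all()
        assert res["balanced_accuracy"].mean() > 0.6


class TestImportance:
    def _informative(self, seed, n=240, n_noise=4):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        y = (x + 0.35 * rng.standard_normal(n) > 0).astype(int)
        df = pd.DataFrame({"signal": x})
        for j in range(n_noise):
            df[f"noise{j}"] = rng.standard_normal(n)
        return df, y

    def test_constant_feature_permutation_importance_exactly_zero(self):
        df, y = self._informative(0)
        df["constant"] = 1.0
        from sklearn.naive_bayes import GaussianNB

        cols = list(df.columns)
        model = GaussianNB().fit(df[cols].to_numpy(), y)
        imp = permutation_importance_scores(
            model, df[cols].to_numpy(), y, np.random.default_rng(0))
        assert imp[cols.index("constant")] == 0.0

    def test_label_independent_feature_near_zero(self):
        df, y = self._informative(1)
        from sklearn.naive_bayes import GaussianNB

        cols = list(df.columns)
        model = GaussianNB().fit(df[cols].to_numpy(), y)
        imps = []
        for seed in range(20):
            imp = permutation_importance_scores(
                model, df[cols].to_numpy(), y, np.random.default_rng(seed))
            imps.append(imp[cols.index("noise0")])
        assert abs(np.mean(imps)) < 0.05

    def test_unused_feature_lgbm_gain_zero(self):
        df, y = self._informative(2)
        df["constant"] = 0.0
        cols = list(df.columns)
        gain = lgbm_gini_importance(df, cols, y, seed=0)
        assert gain["constant"] == 0.0
        assert gain.sum() == pytest.approx(1.0, abs=1e-9)

    def test_informative_feature_ranks_first_both_rankers(self):
        lgbm_wins = perm_wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            df, y = self._informative(100 + seed)
            cols = list(df.columns)
            gain = lgbm_gini_importance(df, cols, y, seed=seed)
            if gain.idxmax() == "signal":
                lgbm_wins += 1
            perm = mean_permutation_importance(df, cols, y, seed=seed,
                                               grids=SMALL_GRIDS,
                                               families=("gnb", "knn"))
            if perm.idxmax() == "signal":
                perm_wins += 1
        assert lgbm_wins >= 0.9 * n_seeds
        assert perm_wins >= 0.9 * n_seeds
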