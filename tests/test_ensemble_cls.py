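import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from eegstates.ensemble_cls import (
    CVScheme,
    LearnerSpec,
    RUSBoost,
    bagging_fit,
    build_learner,
    evaluate,
    imv_tfcv,
    metrics_from_confusion,
    optimize_ensemble,
    _split_indices,
)

from conftest import make_blob_matrix


class TestBagging:
    def test_single_learner_ensemble(self):
        fm = make_blob_matrix(n_per_class=20, separation=3.0)
        model = bagging_fit(fm, DecisionTreeClassifier(), L=1, seed=0)
        assert len(model.estimators_) == 1
        assert set(model.predict(fm.values)) <= set(fm.labels)

    def test_separable_data_perfect_training_accuracy(self):
        fm = make_blob_matrix(n_per_class=30, separation=8.0, n_classes=2)
        model = bagging_fit(fm, DecisionTreeClassifier(), L=50, seed=1)
        assert np.mean(model.predict(fm.values) == fm.labels) == 1.0

    def test_duplicated_columns_do_not_change_votes(self):
        fm = make_blob_matrix(n_per_class=25, separation=2.0)
        doubled = np.hstack([fm.values, fm.values])
        m1 = bagging_fit(fm, DecisionTreeClassifier(), L=25, seed=3)
        p1 = m1.predict(fm.values)
        from eegstates.feature_bank import FeatureMatrix

        meta2 = pd.concat([fm.column_meta] * 2, ignore_index=True)
        fm2 = FeatureMatrix(doubled, fm.labels, meta2)
        m2 = bagging_fit(fm2, DecisionTreeClassifier(), L=25, seed=3)
        p2 = m2.predict(doubled)
        assert np.mean(p1 == p2) > 0.95

    def test_single_class_rejected(self):
        fm = make_blob_matrix(n_per_class=10, n_classes=1)
        with pytest.raises(ValueError, match="two classes"):
            bagging_fit(fm, DecisionTreeClassifier(), L=5)

    def test_vote_fractions_are_probabilities(self):
        fm = make_blob_matrix(n_per_class=20)
        model = bagging_fit(fm, DecisionTreeClassifier(), L=10, seed=0)
        proba = model.predict_proba(fm.values)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert (proba >= 0).all()


class TestRUSBoost:
    def test_handles_imbalanced_classes(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((90, 4)), rng.standard_normal((10, 4)) + 3])
        y = np.array(["maj"] * 90 + ["min"] * 10)
        model = RUSBoost(L=30, random_state=0).fit(X, y)
        pred = model.predict(X)
        minority_recall = np.mean(pred[y == "min"] == "min")
        assert minority_recall >= 0.8


class TestMetrics:
    def test_hand_computed_binary_confusion(self):
        confusion = np.array([[9, 1], [2, 8]])
        table = metrics_from_confusion(confusion, ["pos", "neg"])
        row = table.loc["pos"]
        assert row["recall"] == pytest.approx(0.90)
        assert row["specificity"] == pytest.approx(0.80)
        assert row["precision"] == pytest.approx(9 / 11)
        assert row["f1"] == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))
        assert (confusion.trace() / confusion.sum()) == pytest.approx(0.85)

    def test_printed_variant_swaps_tp_and_tn(self):
        confusion = np.array([[9, 1], [2, 8]])
        table = metrics_from_confusion(confusion, ["pos", "neg"], paper_eq11=True)
        row = table.loc["pos"]
        assert row["recall"] == pytest.approx(0.80)  # Tn/(Fp+Tn)
        assert row["specificity"] == pytest.approx(0.90)  # Tp/(Fn+Tp)

    def test_perfect_predictor_all_ones(self):
        confusion = np.diag([10, 12, 8])
        table = metrics_from_confusion(confusion, list("abc"))
        assert (table[["recall", "specificity", "precision", "f1"]] == 1.0).all().all()

    def test_confusion_counts_sum_per_class(self):
        confusion = np.array([[5, 2, 1], [0, 7, 1], [2, 2, 4]])
        table = metrics_from_confusion(confusion, list("abc"))
        total = confusion.sum()
        for _, row in table.iterrows():
            assert row["tp"] + row["tn"] + row["fp"] + row["fn"] == total


class TestEvaluate:
    def test_random_guess_band_on_balanced_data(self):
        from sklearn.dummy import DummyClassifier

        fm = make_blob_matrix(n_per_class=680, n_features=3, separation=0.0)
        accs = [
            evaluate(
                DummyClassifier(strategy="uniform", random_state=s),
                fm,
                CVScheme("kfold_5", seed=s),
            ).accuracy
            for s in range(20)
        ]
        assert all(0.28 <= a <= 0.39 for a in accs)

    def test_stratified_folds_preserve_proportions(self):
        fm = make_blob_matrix(n_per_class=33)
        y = fm.labels
        for tr, te in _split_indices(y, CVScheme("kfold_10", seed=1)):
            for c in np.unique(y):
                frac = np.mean(y[te] == c)
                assert abs(frac * te.size - te.size / 3) <= 1.0

    def test_pooled_accuracy_equals_weighted_fold_mean(self):
        fm = make_blob_matrix(n_per_class=25, separation=1.0)
        model = build_learner(LearnerSpec("bagged_tree", L=10))
        rep = evaluate(model, fm, CVScheme("kfold_5", seed=2))
        sizes = []
        for _, te in _split_indices(fm.labels, CVScheme("kfold_5", seed=2)):
            sizes.append(te.size)
        weighted = np.average(rep.fold_accuracies, weights=sizes)
        assert rep.accuracy == pytest.approx(weighted)

    def test_bit_reproducible_with_fixed_seed(self):
        fm = make_blob_matrix(n_per_class=20, separation=1.5)
        model = build_learner(LearnerSpec("bagged_tree", L=20))
        r1 = evaluate(model, fm, CVScheme("kfold_5", seed=7))
        r2 = evaluate(model, fm, CVScheme("kfold_5", seed=7))
        assert r1.accuracy == r2.accuracy
        assert r1.fold_accuracies == r2.fold_accuracies
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_holdout_uses_one_fifth_for_testing(self):
        fm = make_blob_matrix(n_per_class=50)
        (tr, te), = _split_indices(fm.labels, CVScheme("holdout_80_20", seed=0))
        assert te.size == 30
        assert tr.size == 120

    def test_missing_class_in_training_fold_advises_stratification(self):
        fm = make_blob_matrix(n_per_class=20, n_classes=2)
        fm.labels[:] = "common"
        fm.labels[0] = "rare"  # single member: some training fold must miss it
        model = build_learner(LearnerSpec("bagged_tree", L=2))
        with pytest.raises(ValueError, match="stratified"):
            evaluate(model, fm, CVScheme("kfold_5", stratified=False, seed=0))

    def test_accuracy_increases_with_separation(self):
        accs = []
        for sep in (0.0, 1.0, 4.0):
            vals = [
                evaluate(
                    build_learner(LearnerSpec("bagged_tree", L=15), seed=s),
                    make_blob_matrix(n_per_class=30, separation=sep, seed=s),
                    CVScheme("kfold_5", seed=s),
                ).accuracy
                for s in range(5)
            ]
            accs.append(np.mean(vals))
        assert accs[0] < 0.55
        assert accs[0] < accs[1] < accs[2]
        assert accs[2] > 0.9


class TestOptimize:
    def test_history_length_equals_budget(self):
        fm = make_blob_matrix(n_per_class=15, separation=2.0)
        res = optimize_ensemble(fm, budget=5, cv=CVScheme("kfold_5", seed=0), seed=0)
        assert len(res.history) == 5
        assert res.best_score == res.history["cv_accuracy"].max()

    def test_budget_one_returns_that_candidate(self):
        fm = make_blob_matrix(n_per_class=15, separation=2.0)
        res = optimize_ensemble(fm, budget=1, cv=CVScheme("kfold_5", seed=1), seed=1)
        assert len(res.history) == 1
        assert res.history["method"].iloc[0] == res.best_spec.method

    def test_separable_data_reaches_high_accuracy(self):
        fm = make_blob_matrix(n_per_class=30, separation=4.0)
        res = optimize_ensemble(fm, budget=8, cv=CVScheme("kfold_10", seed=2), seed=2)
        assert res.best_score >= 0.9

    def test_invalid_budget(self):
        fm = make_blob_matrix(n_per_class=10)
        with pytest.raises(ValueError, match="budget"):
            optimize_ensemble(fm, budget=0, cv=CVScheme("kfold_5"), seed=0)


class TestIMV:
    def test_single_round_collapses_to_one_tfcv(self):
        fm = make_blob_matrix(n_per_class=20, separation=2.0)
        model = build_learner(LearnerSpec("bagged_tree", L=10))
        imv = imv_tfcv(fm, model, rounds=1, base_seed=0)
        assert len(imv.round_accuracies) == 1
        assert imv.best_round == 0
        assert imv.best_overall == imv.round_accuracies[0]

    def test_best_values_are_maxima(self):
        fm = make_blob_matrix(n_per_class=20, separation=1.0)
        model = build_learner(LearnerSpec("bagged_tree", L=10))
        imv = imv_tfcv(fm, model, rounds=3, base_seed=5)
        assert imv.best_overall >= np.mean(imv.round_accuracies)
        assert imv.best_overall == max(imv.round_accuracies)
        assert imv.best_foldwise >= imv.best_overall


class TestLearnerSpecs:
    @pytest.mark.parametrize("method", [
        "bagged_tree", "boosted_tree", "rus_boosted_tree",
        "subspace_knn", "subspace_discriminant",
    ])
    def test_all_five_families_fit_and_predict(self, method):
        fm = make_blob_matrix(n_per_class=20, separation=3.0, n_features=6)
        spec = LearnerSpec(method, L=10, subspace_dim=3, max_splits=8)
        model = build_learner(spec, seed=0)
        model.fit(fm.values, fm.labels)
        acc = np.mean(model.predict(fm.values) == fm.labels)
        assert acc > 0.8

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            LearnerSpec("stacking")
        with pytest.raises(ValueError, match="L must be"):
            LearnerSpec("bagged_tree", L=0)
        with pytest.raises(ValueError, match="learning rate"):
            LearnerSpec("boosted_tree", learning_rate=1.5)
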