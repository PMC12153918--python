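import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

import milkfa
from milkfa import (
    PLSDAClassifier,
    TunedRandomForestClassifier,
    confusion_accuracy,
    confusion_kappa,
    cross_validate,
    first_derivative,
    predict_membership,
)


def _two_class_data(n=200, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n // 2, 8)), rng.normal(sep, 1, (n // 2, 8))])
    y = np.repeat([1, 2], n // 2)
    return X, y


class TestFirstDerivative:
    def test_constant_spectrum_zeroes_out(self):
        assert (first_derivative(np.full((3, 10), 7.0)) == 0).all()

    def test_linear_ramp_gives_constant_slope(self):
        ramp = np.arange(10)[None, :] * 2.5
        assert np.allclose(first_derivative(ramp), 2.5)

    def test_baseline_offset_invariance(self):
        rng = np.random.default_rng(1)
        sp = rng.normal(size=(20, 50))
        offsets = rng.normal(size=(20, 1))
        assert np.allclose(first_derivative(sp + offsets), first_derivative(sp))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            first_derivative(np.ones((3, 1)))

    def test_dataframe_shape_and_names(self):
        df = pd.DataFrame(np.ones((2, 3)), columns=["sp001", "sp002", "sp003"])
        out = first_derivative(df)
        assert list(out.columns) == ["dsp002", "dsp003"]


class TestPLSDA:
    def test_separable_classes_high_cv_accuracy(self):
        X, y = _two_class_data()
        model = PLSDAClassifier(max_components=5, cv_folds=5).fit(X, y)
        assert model.cv_accuracy_ >= 0.95

    def test_shuffled_labels_score_at_chance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(600, 10))
        y = rng.integers(1, 4, size=600)
        cm, _ = cross_validate(X, y, PLSDAClassifier(n_components=3), folds=5, seed=0)
        assert confusion_accuracy(cm) == pytest.approx(1 / 3, abs=0.06)
        assert confusion_kappa(cm) == pytest.approx(0.0, abs=0.05)

    def test_probability_rows_stochastic(self):
        X, y = _two_class_data()
        model = PLSDAClassifier(n_components=2).fit(X, y)
        proba = model.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert (proba >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            PLSDAClassifier(n_components=1).fit(np.ones((10, 3)), np.ones(10))


class TestRandomForest:
    def test_near_separable_data_near_perfect(self, state_models):
        tight = milkfa.default_state_models(within_state_sd_fraction=0.1)
        cfg = milkfa.SimConfig(n_herds=25, horizon_days=150, seed=23)
        records, truth = milkfa.simulate_population(tight, cfg)
        fat_basis = milkfa.convert_to_fat_basis(records)
        X = fat_basis[list(milkfa.reference.FA_TRAITS)].to_numpy()
        rf = TunedRandomForestClassifier(
            n_estimators=100, max_features_grid=("sqrt",), random_state=0
        )
        cm, _ = cross_validate(X, truth["state_id"].to_numpy(), rf, folds=5, seed=0)
        assert confusion_accuracy(cm) >= 0.99

    def test_plsda_below_rf_on_default_states(self, fat_basis_population):
        """On the default 7-state population the linear PLS-DA scores
        below the random forest on identical folds (the non-linear
        cluster boundaries favour the forest)."""
        records, truth = fat_basis_population
        X = records[list(milkfa.reference.FA_TRAITS)].to_numpy()[:1500]
        y = truth["state_id"].to_numpy()[:1500]
        rf = TunedRandomForestClassifier(
            n_estimators=100, max_features_grid=("sqrt",), random_state=0
        )
        pls = PLSDAClassifier(n_components=10)
        cm_rf, _ = cross_validate(X, y, rf, folds=5, seed=1)
        cm_pls, _ = cross_validate(X, y, pls, folds=5, seed=1)
        assert confusion_accuracy(cm_pls) < confusion_accuracy(cm_rf)

    def test_vote_proportions_sum_to_one_and_match_hard_labels(self):
        X, y = _two_class_data(seed=5)
        rf = TunedRandomForestClassifier(
            n_estimators=30, max_features_grid=("sqrt",), random_state=0
        ).fit(X, y)
        proba, hard = predict_membership(rf, pd.DataFrame(X))
        votes = proba.to_numpy() * 30
        assert np.allclose(votes, np.round(votes))  # integer tree counts
        assert np.array_equal(hard, rf.classes_[proba.to_numpy().argmax(axis=1)])

    def test_unanimous_forest_gives_probability_one(self):
        X, y = _two_class_data(sep=50.0, seed=6)
        rf = TunedRandomForestClassifier(
            n_estimators=50, max_features_grid=("sqrt",), random_state=0
        ).fit(X, y)
        proba = rf.predict_proba(np.full((1, 8), 50.0))
        assert proba[0, 1] == pytest.approx(1.0)

    def test_max_features_grid_tuning_runs(self):
        X, y = _two_class_data(seed=7)
        rf = TunedRandomForestClassifier(
            n_estimators=20, max_features_grid=("sqrt", 0.5), cv_folds=3,
            random_state=0,
        ).fit(X, y)
        assert rf.max_features_ in ("sqrt", 0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            TunedRandomForestClassifier().fit(np.ones((10, 3)), np.ones(10))


class TestTieBreak:
    def test_argmax_tie_goes_to_lowest_class(self):
        from milkfa.classify import _argmax_lowest

        proba = np.array([[0.4, 0.4, 0.2]])
        assert _argmax_lowest(proba, np.array([1, 2, 3]))[0] == 1


class TestCrossValidate:
    def test_stratified_fold_sizes_balanced(self):
        X, y = _two_class_data(n=100)
        _, folds = cross_validate(
            X, y, PLSDAClassifier(n_components=1), folds=5, seed=0
        )
        assert folds["n"].max() - folds["n"].min() <= 2
        assert folds["n"].sum() == 100

    def test_pooled_total_is_n_records(self):
        X, y = _two_class_data(n=120)
        cm, _ = cross_validate(X, y, PLSDAClassifier(n_components=1), folds=6, seed=0)
        assert cm.to_numpy().sum() == 120

    def test_pooled_accuracy_within_fold_range(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 6))
        y = (X[:, 0] + rng.normal(0, 1.5, 300) > 0).astype(int) + 1
        cm, folds = cross_validate(X, y, PLSDAClassifier(n_components=2), folds=5, seed=2)
        acc = confusion_accuracy(cm)
        assert folds["accuracy"].min() - 1e-12 <= acc <= folds["accuracy"].max() + 1e-12

    def test_class_smaller_than_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        y = np.array([1] * 17 + [2] * 3)
        with pytest.raises(ValueError, match="fewer than"):
            cross_validate(X, y, PLSDAClassifier(n_components=1), folds=5, seed=0)


class TestConfusionMetrics:
    def test_diagonal_matrix_perfect(self):
        cm = np.diag([5, 3, 2])
        assert confusion_accuracy(cm) == 1.0
        assert confusion_kappa(cm) == 1.0

    def test_hand_counted_accuracy(self):
        assert confusion_accuracy([[3, 1], [1, 3]]) == 0.75

    def test_uniform_matrix_kappa_zero(self):
        assert confusion_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_kappa_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            y1 = rng.integers(0, 4, 200)
            y2 = np.where(rng.random(200) < 0.6, y1, rng.integers(0, 4, 200))
            cm = np.zeros((4, 4), dtype=int)
            for p, r in zip(y1, y2):
                cm[p, r] += 1
            assert confusion_kappa(cm) == pytest.approx(
                cohen_kappa_score(y1, y2), abs=1e-12
            )

    def test_invariant_under_simultaneous_permutation(self):
        rng = np.random.default_rng(4)
        cm = rng.integers(0, 50, (5, 5))
        perm = rng.permutation(5)
        permuted = cm[np.ix_(perm, perm)]
        assert confusion_accuracy(permuted) == pytest.approx(confusion_accuracy(cm))
        assert confusion_kappa(permuted) == pytest.approx(confusion_kappa(cm))

    def test_empty_and_degenerate_rejected(self):
        with pytest.raises(ValueError):
            confusion_accuracy(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="undefined"):
            confusion_kappa([[10, 0], [0, 0]])
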