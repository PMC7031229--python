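import numpy as np
import pytest

from ecgrhythm.models import (ALGORITHM_NAMES, ModelSpec, cross_validate,
                              default_grids, f1_report, grid_search,
                              make_estimator, make_strategy)


class TestF1Report:
    def test_perfect_predictions(self):
        y = np.array(["SB", "AFIB", "SR", "SR", "GSVT"])
        rep = f1_report(y, y)
        assert rep.weighted_f1 == 1.0
        assert rep.macro_f1 == 1.0
        assert np.all(rep.per_class["f1"] == 1.0)

    def test_weighted_average_hand_case(self):
        """Supports (3,1) with class F1s (1.0, 0.0) average to 0.75."""
        y_true = np.array([0, 0, 0, 1])
        y_pred = np.array([0, 0, 0, 0])
        rep = f1_report(y_true, y_pred)
        f1_0 = rep.per_class.loc[0, "f1"]
        # class 0: precision 3/4, recall 1 -> F1 = 6/7; class 1: F1 = 0
        assert f1_0 == pytest.approx(6 / 7, abs=1e-12)
        assert rep.per_class.loc[1, "f1"] == 0.0
        assert rep.weighted_f1 == pytest.approx(0.75 * f1_0, abs=1e-12)
        # the pure support-weighting arithmetic: F1s (1, 0) weighted 0.75
        assert (0.75 * 1.0 + 0.25 * 0.0) == 0.75

    def test_absent_class_carries_no_weight(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 1, 1])
        rep = f1_report(y_true, y_pred, labels=[0, 1, 2])
        assert rep.per_class.loc[2, "support"] == 0
        assert rep.per_class.loc[2, "f1"] == 0.0
        assert rep.weighted_f1 == 1.0

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import confusion_matrix, f1_score
        rng = np.random.default_rng(0)
        for _ in range(10):
            y_true = rng.integers(0, 4, 200)
            y_pred = rng.integers(0, 4, 200)
            rep = f1_report(y_true, y_pred)
            assert rep.weighted_f1 == pytest.approx(
                f1_score(y_true, y_pred, average="weighted"), abs=1e-12)
            assert rep.macro_f1 == pytest.approx(
                f1_score(y_true, y_pred, average="macro"), abs=1e-12)
            assert rep.micro_f1 == pytest.approx(
                f1_score(y_true, y_pred, average="micro"), abs=1e-12)
            np.testing.assert_array_equal(
                rep.confusion_matrix, confusion_matrix(y_true, y_pred))

    def test_confusion_conservation_laws(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 3, 120)
        y_pred = rng.integers(0, 3, 120)
        rep = f1_report(y_true, y_pred)
        assert rep.confusion_matrix.sum() == 120
        np.testing.assert_array_equal(
            rep.confusion_matrix.sum(axis=1),
            [np.sum(y_true == k) for k in rep.labels])
        np.testing.assert_allclose(
            rep.normalized_confusion.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            f1_report(np.array([]), np.array([]))


class TestCrossValidate:
    def test_constant_dummy_on_balanced_four_classes(self):
        """A constant predictor on balanced 4-class data scores exactly 0.1:
        the predicted class gets F1 = 2*(0.25*1)/1.25 = 0.4, others 0."""

        class Dummy:
            def fit(self, X, y):
                self.c = np.sort(np.unique(y))[0]
                return self

            def predict(self, X):
                return np.full(len(X), self.c)

            def get_params(self, deep=True):
                return {}

            def set_params(self, **p):
                return self

        X = np.random.default_rng(0).standard_normal((200, 3))
        y = np.repeat(np.arange(4), 50)
        res = cross_validate(X, y, estimator=Dummy(), n_splits=4, seed=0)
        assert res.mean_weighted_f1 == pytest.approx(0.1, abs=1e-12)

    def test_same_seed_reproduces_metrics(self, blobs_fixture):
        Xtr, _, ytr, _ = blobs_fixture
        spec = ModelSpec("paper_gbt", params={"n_estimators": 5})
        a = cross_validate(Xtr, ytr, spec=spec, n_splits=3, seed=5)
        b = cross_validate(Xtr, ytr, spec=spec, n_splits=3, seed=5)
        assert a.fold_weighted_f1 == b.fold_weighted_f1

    def test_kfold_mode_runs(self, blobs_fixture):
        Xtr, _, ytr, _ = blobs_fixture
        spec = ModelSpec("DT")
        res = cross_validate(Xtr, ytr, spec=spec, n_splits=4, mode="kfold",
                             seed=0)
        assert len(res.fold_reports) == 4

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(np.zeros((10, 2)), np.zeros(10),
                           spec=ModelSpec("DT"))


class TestGridSearch:
    def test_grid_of_size_one(self, blobs_fixture):
        Xtr, _, ytr, _ = blobs_fixture
        spec = ModelSpec("DT", grid={"max_depth": [3]})
        best, score, table = grid_search(Xtr, ytr, spec, seed=0, n_splits=3)
        assert best == {"max_depth": 3}
        assert len(table) == 1
        assert 0 <= score <= 1

    def test_depth_grid_prefers_capacity_on_interleaved_classes(
            self, blobs_fixture):
        """Stumps cannot separate 4 blobs; the deeper setting must win."""
        Xtr, _, ytr, _ = blobs_fixture
        spec = ModelSpec("DT", grid={"max_depth": [1, 10]})
        best, _, table = grid_search(Xtr, ytr, spec, seed=0, n_splits=3)
        assert best == {"max_depth": 10}
        assert len(table) == 2

    def test_enumeration_order_reproducible(self, blobs_fixture):
        Xtr, _, ytr, _ = blobs_fixture
        spec = ModelSpec("DT", grid={"max_depth": [2, 4],
                                     "criterion": ["gini", "entropy"]})
        _, _, t1 = grid_search(Xtr, ytr, spec, seed=1, n_splits=2)
        _, _, t2 = grid_search(Xtr, ytr, spec, seed=1, n_splits=2)
        assert t1.equals(t2)
        assert list(t1["param_max_depth"]) == [2, 2, 4, 4]

    def test_invalid_hyperparameter_rejected_before_fit(self, blobs_fixture):
        Xtr, _, ytr, _ = blobs_fixture
        spec = ModelSpec("DT", grid={"definitely_not_a_param": [1]})
        with pytest.raises(ValueError, match="invalid"):
            grid_search(Xtr, ytr, spec, seed=0)

    def test_empty_grid_rejected(self, blobs_fixture):
        Xtr, _, ytr, _ = blobs_fixture
        with pytest.raises(ValueError, match="empty"):
            grid_search(Xtr, ytr, ModelSpec("DT"), seed=0)


class TestRegistryAndStrategies:
    def test_all_algorithms_instantiate(self):
        for name in ALGORITHM_NAMES:
            est = make_estimator(ModelSpec(name), seed=0)
            assert hasattr(est, "fit") and hasattr(est, "predict")

    def test_shipped_grids_cover_the_study_algorithms(self):
        grids = default_grids()
        for name in ("DT", "KNN", "RF", "ERT", "GBT", "EGBT"):
            assert name in grids
        assert grids["GBT"]["subsample"] == [0.1, 0.5, 0.9]
        assert grids["EGBT"]["max_depth"] == [10, 15, 20, 50, 100]

    def test_one_vs_one_builds_k_choose_2_models(self, blobs_fixture):
        Xtr, _, ytr, _ = blobs_fixture
        est = make_estimator(ModelSpec("DT", strategy="one_vs_one"), seed=0)
        est.fit(Xtr, ytr)
        assert len(est.estimators_) == 6  # K(K-1)/2 with K=4

    def test_one_vs_rest_builds_k_models(self, blobs_fixture):
        Xtr, _, ytr, _ = blobs_fixture
        est = make_estimator(ModelSpec("DT", strategy="one_vs_rest"), seed=0)
        est.fit(Xtr, ytr)
        assert len(est.estimators_) == 4

    def test_strategy_none_is_passthrough(self):
        base = make_estimator(ModelSpec("DT"), seed=0)
        assert make_strategy(base, "none") is base

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("DT", strategy="stacking")

    def test_paper_gbt_works_under_one_vs_rest(self, blobs_fixture):
        Xtr, Xte, ytr, yte = blobs_fixture
        est = make_estimator(
            ModelSpec("paper_gbt", params={"n_estimators": 10},
                      strategy="one_vs_rest"), seed=0)
        est.fit(Xtr, ytr)
        assert np.mean(est.predict(Xte) == yte) > 0.8
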