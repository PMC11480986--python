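"""Split protocol, grid-search training, prediction rules and leakage guards."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.pipeline import Pipeline

from fragqsar import modeling as mo
from fragqsar import synthetic_data as sd
from fragqsar import validation as va
from fragqsar import pipeline as pl


def _ids(n):
    return [f"m{i}" for i in range(n)]


class TestMakeSplit:
    def test_sizes_and_fold_balance(self):
        rng = np.random.default_rng(0)
        plan = mo.make_split(_ids(100), rng.normal(size=100), seed=3)
        assert len(plan.holdout_indices) == 20
        assert len(plan.building_indices) == 80
        counts = np.bincount(plan.fold_of_building)[1:]
        assert counts.tolist() == [16] * 5
        assert set(plan.holdout_indices) | set(plan.building_indices) \
            == set(range(100))
        assert set(plan.holdout_indices) & set(plan.building_indices) == set()

    def test_regression_set_analog(self):
        rng = np.random.default_rng(1)
        plan = mo.make_split(_ids(475), rng.normal(size=475), seed=0)
        assert len(plan.holdout_indices) == 95
        assert len(plan.building_indices) == 380

    def test_deterministic_for_fixed_seed(self):
        y = np.random.default_rng(2).integers(0, 2, 60)
        a = mo.make_split(_ids(60), y, seed=11, task="binary")
        b = mo.make_split(_ids(60), y, seed=11, task="binary")
        np.testing.assert_array_equal(a.holdout_indices, b.holdout_indices)
        np.testing.assert_array_equal(a.fold_of_building, b.fold_of_building)
        c = mo.make_split(_ids(60), y, seed=12, task="binary")
        assert not np.array_equal(a.holdout_indices, c.holdout_indices)

    def test_small_class_errors(self):
        y = np.array([0] * 56 + [1] * 4)
        with pytest.raises(ValueError, match="stratum"):
            mo.make_split(_ids(60), y, k=5, task="binary")

    def test_tiny_dataset_errors(self):
        with pytest.raises(ValueError):
            mo.make_split(_ids(5), np.zeros(5))


def _linear_problem(n=80, p=12, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(rng.integers(0, 2, (n, p)).astype(np.float32))
    w = rng.uniform(0.5, 2.0, p)
    y = X @ w + rng.normal(0, sigma, n)
    return X, np.asarray(y).ravel()


class TestGridSearchTrain:
    def test_noiseless_linear_target_recovered(self):
        X, y = _linear_problem()
        plan = mo.make_split(_ids(len(y)), y, seed=0)
        spec = mo.ModelSpec("regression", "linear",
                            {"estimator__alpha": [1e-4]})
        model = mo.grid_search_train(X, y, spec, plan)
        assert model.best_cv_score >= 0.99

    def test_single_grid_point_equals_direct_fit(self):
        X, y = _linear_problem(sigma=0.3, seed=1)
        plan = mo.make_split(_ids(len(y)), y, seed=1)
        spec = mo.ModelSpec("regression", "linear", {"estimator__alpha": [2.0]})
        model = mo.grid_search_train(X, y, spec, plan)
        direct = mo.build_pipeline(spec).set_params(estimator__alpha=2.0)
        direct.fit(X[plan.building_indices], y[plan.building_indices])
        np.testing.assert_allclose(model.pipeline.predict(X),
                                   direct.predict(X), rtol=1e-10)
        assert model.best_params == {"estimator__alpha": 2.0}

    def test_constant_target_errors(self):
        X, _ = _linear_problem()
        plan = mo.make_split(_ids(X.shape[0]), np.arange(X.shape[0]), seed=0)
        with pytest.raises(ValueError, match="no variance"):
            mo.grid_search_train(X, np.ones(X.shape[0]),
                                 mo.ModelSpec("regression", "linear"), plan)

    def test_reproducible_selection(self):
        X, y = _linear_problem(sigma=0.5, seed=2)
        plan = mo.make_split(_ids(len(y)), y, seed=7)
        spec = mo.ModelSpec("regression", "linear")
        a = mo.grid_search_train(X, y, spec, plan)
        b = mo.grid_search_train(X, y, spec, plan)
        assert a.best_params == b.best_params
        assert a.cv_records == b.cv_records
        assert len(a.cv_records[0]["fold_scores"]) == 5


from sklearn.base import BaseEstimator, ClassifierMixin


class _FixedProba(ClassifierMixin, BaseEstimator):
    """Stub classifier returning preset probabilities."""

    def __init__(self, P=None):
        self.P = P
        self.classes_ = np.array([1, 2, 3])  # fitted-style attribute

    def fit(self, X, y=None):
        return self

    def predict_proba(self, X):
        return np.asarray(self.P)


def _stub_model(P, task="ternary"):
    est = _FixedProba(P)
    pipeline = Pipeline([("estimator", est)])
    spec = mo.ModelSpec(task, "linear")
    plan = mo.SplitPlan(["a"], np.array([], int), np.array([0]),
                        np.array([1]), 5, 0, False)
    return mo.TrainedModel(pipeline, spec, plan, [], {}, 0.0,
                           np.arange(3), ["a"], n_features_in=3)


class TestPredict:
    def test_ternary_argmax_and_tie_break(self):
        model = _stub_model([[0.2, 0.5, 0.3], [0.4, 0.4, 0.2]])
        preds = mo.predict(model, np.zeros((2, 3)))
        assert preds.values.tolist() == [2, 1]  # tie goes to the lower category
        assert np.allclose(preds.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_feature_count_mismatch(self):
        model = _stub_model([[1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="feature count"):
            mo.predict(model, np.zeros((1, 5)))

    def test_constant_regression_target_predicts_constant(self):
        rng = np.random.default_rng(3)
        X = sp.csr_matrix(rng.integers(0, 2, (40, 6)).astype(np.float32))
        y = 7.5 + rng.normal(0, 1e-6, 40)  # essentially constant target
        plan = mo.make_split(_ids(40), None, seed=0, stratify=False)
        spec = mo.ModelSpec("regression", "linear",
                            {"estimator__alpha": [1e6]})  # shrink to the mean
        model = mo.grid_search_train(X, y, spec, plan)
        preds = mo.predict(model, X)
        np.testing.assert_allclose(preds.values, 7.5, atol=1e-3)


class TestEvaluateHoldout:
    def test_perfect_predictions(self):
        X, y = _linear_problem(seed=4)
        plan = mo.make_split(_ids(len(y)), y, seed=4)
        spec = mo.ModelSpec("regression", "linear", {"estimator__alpha": [1e-6]})
        model = mo.grid_search_train(X, y, spec, plan)
        hold = plan.holdout_indices
        m = mo.evaluate_holdout(model, X[hold], y[hold],
                                [plan.ids[i] for i in hold])
        assert m.r2 >= 0.999

    def test_leakage_guard(self):
        X, y = _linear_problem(seed=5)
        plan = mo.make_split(_ids(len(y)), y, seed=5)
        spec = mo.ModelSpec("regression", "linear", {"estimator__alpha": [1.0]})
        model = mo.grid_search_train(X, y, spec, plan)
        with pytest.raises(mo.LeakageError):
            mo.evaluate_holdout(model, X[:5], y[:5], model.training_ids[:5])


class TestHoldoutCvAgreement:
    """On adequately sized synthetic data the holdout-CV gap stays small."""

    def test_gap_below_015_over_five_seeds(self):
        gaps, r2s = [], []
        for seed in range(5):
            data, _ = sd.generate_benchmark(
                {"n": 600, "fraction_exact": 1.0,
                 "fraction_censored_active": 0.0,
                 "fraction_censored_inactive": 0.0}, seed)
            config = pl.RunConfig(seed=seed)
            model, matrix, y, plan, _ = pl.train_task(data.dataset,
                                                      "regression", config)
            hold = plan.holdout_indices
            m = mo.evaluate_holdout(model, matrix.X[hold], y[hold])
            gaps.append(abs(m.r2 - model.best_cv_score))
            r2s.append(m.r2)
        assert all(g < 0.15 for g in gaps), gaps
        # holdout accuracy at noise sd 0.3 stays in the expected band
        assert all(0.7 <= r <= 1.0 for r in r2s), r2s


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, y = _linear_problem(sigma=0.2, seed=6)
        plan = mo.make_split(_ids(len(y)), y, seed=6)
        spec = mo.ModelSpec("regression", "linear")
        model = mo.grid_search_train(X, y, spec, plan)
        mo.save_model(model, tmp_path / "m")
        back = mo.load_model(tmp_path / "m")
        np.testing.assert_allclose(back.pipeline.predict(X),
                                   model.pipeline.predict(X))
        assert back.best_params == model.best_params
        assert back.training_ids == model.training_ids
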