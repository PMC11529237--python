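import numpy as np
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from tiab_screen.classifiers import (
    METHODS,
    ClassifierSpec,
    _build_estimator,
    _proba,
    default_grid,
    predict_inclusion_probability,
    tune_and_fit,
)
from tiab_screen.corpus_io import Label
from tiab_screen.features import build_dtm
from tiab_screen.text_processing import TokenBag


def _separable_dtm(n=60, seed=0):
    rng = np.random.default_rng(seed)
    bags, labels = [], []
    for i in range(n):
        include = i % 4 == 0
        counts = {"base": int(rng.integers(1, 5))}
        if include:
            counts["marker"] = int(rng.integers(2, 5))
        elif rng.random() < 0.1:
            counts["marker"] = 1
        bags.append(TokenBag(doc_id=f"d{i}", counts=counts))
        labels.append(Label.INCLUDE if include else Label.EXCLUDE)
    return build_dtm(bags), labels


class TestClassifierSpec:
    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            ClassifierSpec(method="nn")

    def test_logistic_regression_permits_empty_grid(self):
        spec = ClassifierSpec(method="logistic_regression", hyperparameter_grid={})
        assert spec.grid_points() == [{}]

    def test_other_methods_require_grid(self):
        with pytest.raises(ValueError, match="grid"):
            ClassifierSpec(method="svm", hyperparameter_grid={})

    def test_default_grids_exist(self):
        for method in METHODS:
            spec = ClassifierSpec(method=method)
            assert spec.grid_points()


class TestTuneAndFit:
    def test_grid_of_size_one_is_chosen(self):
        dtm, labels = _separable_dtm()
        spec = ClassifierSpec(
            method="random_forest",
            hyperparameter_grid={"n_estimators": [50], "max_features_factor": [1.0]},
            seed=0,
        )
        model = tune_and_fit(spec, dtm, labels)
        assert model.chosen_hyperparameters == {
            "n_estimators": 50, "max_features_factor": 1.0,
        }

    def test_two_point_grid_matches_oracle(self):
        # independently recompute both grid points' CV AUCs and check the
        # chosen point is the argmax (ties -> first point)
        dtm, labels = _separable_dtm(n=80, seed=1)
        grid = {"C": [0.01, 10.0]}
        spec = ClassifierSpec(
            method="svm",
            hyperparameter_grid={**grid, "gamma_factor": [1.0]},
            tuning_folds=4,
            seed=2,
        )
        model = tune_and_fit(spec, dtm, labels)

        from tiab_screen.features import labels_to_binary

        y = labels_to_binary(labels)
        X = dtm.toarray().astype(float)
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=2)
        folds = list(skf.split(X, y))
        oracle = []
        for c in grid["C"]:
            aucs = []
            for tr, va in folds:
                est = _build_estimator("svm", {"C": c, "gamma_factor": 1.0}, dtm.p, 2)
                est.fit(X[tr], y[tr])
                aucs.append(roc_auc_score(y[va], _proba("svm", est, X[va])))
            oracle.append(np.mean(aucs))
        expected_c = grid["C"][int(np.argmax(oracle))]
        assert model.chosen_hyperparameters["C"] == expected_c

    def test_single_class_rejected(self):
        dtm, labels = _separable_dtm()
        with pytest.raises(ValueError, match="class"):
            tune_and_fit(
                ClassifierSpec(method="logistic_regression"),
                dtm,
                [Label.EXCLUDE] * dtm.n,
            )

    def test_seed_stability(self):
        dtm, labels = _separable_dtm()
        spec = ClassifierSpec(
            method="random_forest",
            hyperparameter_grid={"n_estimators": [30], "max_features_factor": [0.5, 1.0]},
            seed=11,
        )
        m1 = tune_and_fit(spec, dtm, labels)
        m2 = tune_and_fit(spec, dtm, labels)
        assert m1.chosen_hyperparameters == m2.chosen_hyperparameters
        p1 = predict_inclusion_probability(m1, dtm)
        p2 = predict_inclusion_probability(m2, dtm)
        assert (p1 == p2).all()


class TestPredict:
    @pytest.mark.parametrize("method", METHODS)
    def test_probability_contract(self, method):
        dtm, labels = _separable_dtm()
        grid = {
            "svm": {"C": [1.0], "gamma_factor": [1.0]},
            "logistic_regression": {},
            "random_forest": {"n_estimators": [30], "max_features_factor": [1.0]},
            "gradient_boosted_trees": {"learning_rate": [0.1], "max_leaf_nodes": [15], "max_iter": [30]},
        }[method]
        spec = ClassifierSpec(method=method, hyperparameter_grid=grid, seed=0)
        model = tune_and_fit(spec, dtm, labels)
        probs = predict_inclusion_probability(model, dtm)
        assert probs.shape == (dtm.n,)
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_separable_corpus_orders_classes(self):
        dtm, labels = _separable_dtm(n=100, seed=3)
        spec = ClassifierSpec(
            method="random_forest",
            hyperparameter_grid={"n_estimators": [100], "max_features_factor": [1.0]},
            seed=3,
        )
        model = tune_and_fit(spec, dtm, labels)
        probs = predict_inclusion_probability(model, dtm)
        inc = [p for p, lab in zip(probs, labels) if lab is Label.INCLUDE]
        exc = [p for p, lab in zip(probs, labels) if lab is Label.EXCLUDE]
        assert np.mean(inc) > np.mean(exc)

    def test_vocabulary_mismatch_rejected(self):
        dtm, labels = _separable_dtm()
        spec = ClassifierSpec(
            method="logistic_regression", hyperparameter_grid={}, seed=0
        )
        model = tune_and_fit(spec, dtm, labels)
        other = build_dtm([TokenBag(doc_id="x", counts={"zzz": 1})])
        with pytest.raises(ValueError, match="vocabulary"):
            predict_inclusion_probability(model, other)

    def test_identical_rows_identical_probabilities(self):
        dtm, labels = _separable_dtm()
        spec = ClassifierSpec(
            method="gradient_boosted_trees",
            hyperparameter_grid={"learning_rate": [0.1], "max_leaf_nodes": [15], "max_iter": [20]},
            seed=0,
        )
        model = tune_and_fit(spec, dtm, labels)
        row = build_dtm(
            [TokenBag(doc_id=f"r{i}", counts={"base": 2, "marker": 3}) for i in range(3)],
            vocabulary=dtm.vocabulary,
        )
        probs = predict_inclusion_probability(model, row)
        assert probs[0] == probs[1] == probs[2]


def test_random_forest_probability_is_vote_share():
    dtm, labels = _separable_dtm(n=40, seed=5)
    spec = ClassifierSpec(
        method="random_forest",
        hyperparameter_grid={"n_estimators": [3], "max_features_factor": [1.0]},
        seed=5,
    )
    model = tune_and_fit(spec, dtm, labels)
    probs = predict_inclusion_probability(model, dtm)
    X = dtm.toarray().astype(float)
    votes = np.stack([t.predict(X) for t in model.fit_state.estimators_])
    expected = votes.mean(axis=0)
    assert np.allclose(probs, expected)
    # with 3 trees every probability is a multiple of 1/3
    assert set(np.round(probs * 3, 9) % 1.0) == {0.0}


def test_svm_probability_monotone_in_decision_value():
    dtm, labels = _separable_dtm(n=80, seed=7)
    spec = ClassifierSpec(
        method="svm", hyperparameter_grid={"C": [1.0], "gamma_factor": [1.0]}, seed=7
    )
    model = tune_and_fit(spec, dtm, labels)
    X = dtm.toarray().astype(float)
    decisions = model.fit_state.decision_function(X)
    probs = predict_inclusion_probability(model, dtm)
    order = np.argsort(decisions)
    # Platt scaling is monotone: probability ranks follow decision-value ranks
    assert (np.diff(probs[order]) >= -1e-12).all()


def test_default_grid_copies():
    g = default_grid("svm")
    g["C"].append(99)
    assert 99 not in default_grid("svm")["C"]
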