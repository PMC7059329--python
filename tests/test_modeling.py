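"""Classifier registry, tuning, consensus rules, and the model/results
objects."""

import numpy as np
import pandas as pd
import pytest

from bcrpqsar import modeling as mo
from bcrpqsar.modeling import (BCRPInhibitionModel, ClassifierSpec,
                               PredictionSet, consensus_label,
                               consensus_probability, train_classifier,
                               tune_hyperparameters)
from bcrpqsar.synthetic import SyntheticSpec, gen_feature_table

ALL_METHODS = list(mo.METHODS)


def _separable_frame(n=40, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x1 = np.r_[rng.normal(gap, 0.5, n), rng.normal(-gap, 0.5, n)]
    x2 = rng.normal(0, 1, 2 * n)
    y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    return pd.DataFrame({"f1": x1, "f2": x2}), y


# ---------------------------------------------------------------------------
# specs and training
# ---------------------------------------------------------------------------

def test_spec_validation():
    with pytest.raises(ValueError):
        ClassifierSpec("RandomGuess")
    with pytest.raises(ValueError):
        ClassifierSpec("SVM_RBF", {"n_neighbors": 3})
    ClassifierSpec("kNN_weighted", {"n_neighbors": 3})  # valid


@pytest.mark.parametrize("method", ALL_METHODS)
def test_every_method_separates_a_separable_problem(method):
    """On a linearly separable two-feature set every classifier reaches
    perfect training accuracy."""
    X, y = _separable_frame()
    handle = train_classifier(ClassifierSpec(method, seed=0), X, y)
    pred = handle.predict(X)
    assert (pred.predicted_label == y).all()
    # probability/label consistency
    assert ((pred.p_inhibitor >= 0.5) == pred.predicted_label.astype(bool)).all()


def test_knn_k1_memorizes_training_data():
    X, y = _separable_frame(gap=0.2)  # heavily overlapping
    handle = train_classifier(
        ClassifierSpec("kNN_weighted", {"n_neighbors": 1}), X, y)
    assert (handle.predict(X).predicted_label == y).all()


def test_single_class_labels_rejected():
    X, y = _separable_frame()
    with pytest.raises(ValueError):
        train_classifier(ClassifierSpec("NB"), X, np.ones_like(y))


def test_label_permutation_destroys_cv_signal():
    """Y-randomization: with labels shuffled independently of features,
    cross-validated MCC collapses to noise for every method."""
    fm = gen_feature_table(SyntheticSpec(
        n_inhibitors=200, n_noninhibitors=200, n_informative_continuous=3,
        n_noise_continuous=7, n_fingerprint_bits=10, effect_size=2.0, seed=21))
    rng = np.random.default_rng(0)
    y_perm = rng.permutation(fm.labels)
    X = fm.values.to_numpy(dtype=float)
    for method in ALL_METHODS:
        score = mo._cv_mcc(ClassifierSpec(method, seed=0), X, y_perm,
                           folds=5, seed=0)
        assert abs(score) < 0.15, method


# ---------------------------------------------------------------------------
# hyper-parameter search
# ---------------------------------------------------------------------------

def test_one_point_search_space_returns_that_point():
    X, y = _separable_frame(n=25)
    spec, log = tune_hyperparameters("kNN_weighted", X, y,
                                     grid={"n_neighbors": [5]}, n_random=0,
                                     cv_folds=3)
    assert spec.hyperparameters == {"n_neighbors": 5}
    assert len(log) == 1
    with pytest.raises(ValueError):
        tune_hyperparameters("kNN_weighted", X, y, grid={"n_neighbors": []})


def test_search_log_consistent_and_deterministic():
    fm = gen_feature_table(SyntheticSpec(
        n_inhibitors=60, n_noninhibitors=60, n_informative_continuous=2,
        n_noise_continuous=4, n_fingerprint_bits=0, effect_size=1.0, seed=2))
    X = fm.values
    spec1, log1 = tune_hyperparameters("kNN_weighted", X, fm.labels,
                                       n_random=5, cv_folds=3, seed=3)
    spec2, log2 = tune_hyperparameters("kNN_weighted", X, fm.labels,
                                       n_random=5, cv_folds=3, seed=3)
    pd.testing.assert_frame_equal(log1, log2)
    assert spec1 == spec2
    # the returned spec achieves the best objective value in its own log
    best_row = log1.loc[log1["cv_mcc"].idxmax()]
    assert best_row["hp:n_neighbors"] == spec1.hyperparameters["n_neighbors"]
    assert log1["stage"].value_counts()["random"] == 5


def test_knn_search_agrees_with_exhaustive_grid_oracle():
    """Exhaustively evaluating every k reproduces the two-stage search's
    grid stage; the final choice is never worse than the grid optimum."""
    fm = gen_feature_table(SyntheticSpec(
        n_inhibitors=80, n_noninhibitors=80, n_informative_continuous=2,
        n_noise_continuous=8, n_fingerprint_bits=0, effect_size=1.0, seed=13))
    grid = {"n_neighbors": [3, 5, 7, 9]}
    oracle = {k: mo._cv_mcc(ClassifierSpec("kNN_weighted", {"n_neighbors": k}),
                            fm.values.to_numpy(float), fm.labels, 3, 0)
              for k in grid["n_neighbors"]}
    spec, log = tune_hyperparameters("kNN_weighted", fm.values, fm.labels,
                                     grid=grid, n_random=4, cv_folds=3, seed=0)
    grid_rows = log[log["stage"] == "grid"].set_index("hp:n_neighbors")
    for k, v in oracle.items():
        assert grid_rows.loc[k, "cv_mcc"] == pytest.approx(v)
    assert log["cv_mcc"].max() >= max(oracle.values()) - 1e-12
    assert 3 <= spec.hyperparameters["n_neighbors"] <= 9


# ---------------------------------------------------------------------------
# consensus models
# ---------------------------------------------------------------------------

def _pset(ps):
    return PredictionSet(list(range(len(ps))), np.asarray(ps))


def test_consensus_label_majority_votes():
    out = consensus_label([_pset([0.9]), _pset([0.8]), _pset([0.2])])
    assert out.predicted_label[0] == 1
    out2 = consensus_label([_pset([0.1]), _pset([0.2]), _pset([0.9])])
    assert out2.predicted_label[0] == 0
    assert out2.p_inhibitor[0] == pytest.approx(1 / 3)


def test_consensus_label_identical_members_and_even_count():
    member = _pset([0.7, 0.2])
    out = consensus_label([member, member, member])
    assert (out.predicted_label == member.predicted_label).all()
    with pytest.raises(ValueError):
        consensus_label([member, member])


def test_consensus_probability_mean_and_threshold():
    out = consensus_probability([_pset([0.9]), _pset([0.8]), _pset([0.7])])
    assert out.p_inhibitor[0] == pytest.approx(0.8)
    assert out.predicted_label[0] == 1
    boundary = consensus_probability([_pset([0.4]), _pset([0.6])])
    assert boundary.p_inhibitor[0] == pytest.approx(0.5)
    assert boundary.predicted_label[0] == 1  # threshold is >=
    single = consensus_probability([_pset([0.3])])
    assert single.p_inhibitor[0] == pytest.approx(0.3)


def test_consensus_alignment_check():
    a = PredictionSet(["x", "y"], [0.1, 0.9])
    b = PredictionSet(["y", "x"], [0.1, 0.9])
    with pytest.raises(ValueError):
        consensus_probability([a, b])


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_results(separable_table):
    model = BCRPInhibitionModel(separable_table)
    return model.fit(methods=("NB", "RLR", "SVM_RBF", "XGBoost"),
                     consensus_members=("RLR", "SVM_RBF", "XGBoost"), seed=0)


def test_results_metric_tables(fitted_results):
    cv = fitted_results.metrics_cv()
    te = fitted_results.metrics_test()
    for tab in (cv, te):
        assert list(tab.columns) == ["GA", "BA", "MCC", "AUC"]
        assert {"NB", "RLR", "SVM_RBF", "XGBoost",
                "Consensus1", "Consensus2"} <= set(tab.index)
        assert tab["GA"].between(0, 1).all()
        assert tab["MCC"].between(-1, 1).all()
    # strongly separated data: well-performing models shine on the test set
    assert te.loc["SVM_RBF", "MCC"] > 0.8
    assert te.loc["XGBoost", "MCC"] > 0.8


def test_results_summary_and_misclassified(fitted_results):
    text = fitted_results.summary()
    assert "Test set" in text and "SVM_RBF" in text
    mis = fitted_results.misclassified("SVM_RBF")
    pred = fitted_results.test_predictions["SVM_RBF"]
    assert len(mis) == int((pred.predicted_label != fitted_results.y_test).sum())


def test_residual_profile_monotone(fitted_results):
    prof = fitted_results.residual_profile("SVM_RBF", "test")
    assert (np.diff(prof["fraction_above"]) <= 1e-12).all()


def test_fit_reproducible_under_seed(separable_table):
    model = BCRPInhibitionModel(separable_table)
    r1 = model.fit(methods=("RLR", "XGBoost"), consensus_members=(), seed=4)
    r2 = model.fit(methods=("RLR", "XGBoost"), consensus_members=(), seed=4)
    pd.testing.assert_frame_equal(r1.metrics_test(), r2.metrics_test())
    pd.testing.assert_frame_equal(r1.metrics_cv(), r2.metrics_cv())


def test_from_dataframe_infers_kinds():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"x": rng.normal(size=60),
                       "bit": rng.integers(0, 2, size=60),
                       "label": rng.integers(0, 2, size=60)})
    model = BCRPInhibitionModel.from_dataframe(df)
    assert model.features.kinds == {"x": "continuous", "bit": "binary_bit"}
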