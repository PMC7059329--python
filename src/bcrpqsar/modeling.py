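"""Classifier registry, hyper-parameter search, consensus, and the
model/results objects tying the pipeline together.

Seven classification methods sit behind one interface: naive Bayes (NB),
distance-weighted k-nearest neighbors (kNN_weighted), regularized logistic
regression (RLR), an RBF-kernel support vector machine (SVM_RBF),
stochastic gradient boosting (SGB), XGBoost, and a feed-forward neural
network (DNN: ReLU activation, adaptive-learning-rate optimizer, 300-epoch
cap). Hyper-parameters are tuned in two stages — a coarse grid, then a
seeded random search inside the region around the grid optimum — with mean
fivefold-CV Matthews correlation as the objective.

:class:`BCRPInhibitionModel` is the user-facing entry point: build it from
a feature matrix with labels, call :meth:`~BCRPInhibitionModel.fit`, and
read the returned :class:`QSARResults` (per-model cross-validation and
test metrics, consensus models, residual diagnostics, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import evaluation as ev
from .featurization import FeatureMatrix, fit_normalizer, normalize, stratified_split

__all__ = [
    "ClassifierSpec",
    "PredictionSet",
    "METHODS",
    "train_classifier",
    "tune_hyperparameters",
    "consensus_label",
    "consensus_probability",
    "BCRPInhibitionModel",
    "QSARResults",
]

PROBABILITY_THRESHOLD = 0.5  # ties at exactly 0.5 classify as inhibitor


def _make_nb(hp, seed):
    return GaussianNB(**hp)


def _make_knn(hp, seed):
    return KNeighborsClassifier(weights="distance", **hp)


def _make_rlr(hp, seed):
    return LogisticRegression(max_iter=2000, random_state=seed, **hp)


def _make_svm(hp, seed):
    return SVC(kernel="rbf", probability=True, random_state=seed, **hp)


def _make_sgb(hp, seed):
    return GradientBoostingClassifier(subsample=0.5, random_state=seed, **hp)


def _make_xgb(hp, seed):
    return XGBClassifier(eval_metric="logloss", n_jobs=1, verbosity=0,
                         random_state=seed, **hp)


def _make_dnn(hp, seed):
    # fixed settings: ReLU, adaptive-rate optimizer (adam), 300-epoch cap
    return MLPClassifier(activation="relu", solver="adam", max_iter=300,
                         random_state=seed, **hp)


# method -> (constructor, allowed hyperparameter names, coarse default grid)
METHODS: dict[str, tuple] = {
    "NB": (_make_nb, {"var_smoothing"},
           {"var_smoothing": [1e-9, 1e-7, 1e-5]}),
    "kNN_weighted": (_make_knn, {"n_neighbors"},
                     {"n_neighbors": [3, 5, 7, 9, 15]}),
    "RLR": (_make_rlr, {"C"},
            {"C": [0.01, 0.1, 1.0, 10.0]}),
    "SVM_RBF": (_make_svm, {"C", "gamma"},
                {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]}),
    "SGB": (_make_sgb, {"n_estimators", "learning_rate", "max_depth"},
            {"n_estimators": [100, 300], "learning_rate": [0.05, 0.1],
             "max_depth": [2, 3]}),
    "XGBoost": (_make_xgb, {"n_estimators", "learning_rate", "max_depth"},
                {"n_estimators": [100, 300], "learning_rate": [0.05, 0.1],
                 "max_depth": [3, 6]}),
    "DNN": (_make_dnn, {"hidden_layer_sizes", "alpha"},
            {"hidden_layer_sizes": [(64,), (64, 32)], "alpha": [1e-4, 1e-3]}),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Method name plus validated hyper-parameters and a seed."""

    method: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method: {self.method!r}; "
                             f"known: {sorted(METHODS)}")
        allowed = METHODS[self.method][1]
        bad = set(self.hyperparameters) - allowed
        if bad:
            raise ValueError(f"invalid hyperparameters for {self.method}: {sorted(bad)}")

    def build(self):
        return METHODS[self.method][0](dict(self.hyperparameters), self.seed)


@dataclass
class PredictionSet:
    """Probabilities and thresholded labels for a set of compounds."""

    compound_ids: list
    p_inhibitor: np.ndarray

    def __post_init__(self):
        self.p_inhibitor = np.asarray(self.p_inhibitor, dtype=float)
        if np.any((self.p_inhibitor < 0) | (self.p_inhibitor > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def predicted_label(self) -> np.ndarray:
        return (self.p_inhibitor >= PROBABILITY_THRESHOLD).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"compound_id": self.compound_ids,
                             "p_inhibitor": self.p_inhibitor,
                             "label": self.predicted_label})


class TrainedClassifier:
    """Fitted estimator bound to an ordered feature-name list."""

    def __init__(self, spec: ClassifierSpec, estimator, feature_names):
        self.spec = spec
        self.estimator = estimator
        self.feature_names = list(feature_names)

    def predict_proba(self, values: pd.DataFrame) -> np.ndarray:
        X = values[self.feature_names].to_numpy(dtype=float)
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]

    def predict(self, values: pd.DataFrame) -> PredictionSet:
        return PredictionSet(list(values.index), self.predict_proba(values))


def train_classifier(spec: ClassifierSpec, values: pd.DataFrame,
                     labels) -> TrainedClassifier:
    """Fit one classifier; the handle predicts inhibitor probabilities."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = spec.build()
    est.fit(values.to_numpy(dtype=float), y)
    return TrainedClassifier(spec, est, values.columns)


def _cv_mcc(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
            folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    vals = []
    for tr, te in skf.split(X, y):
        est = spec.build()
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        vals.append(ev.mcc(*ev.confusion(y[te], pred)))
    return float(np.mean(vals))


def _neighborhood(grid_values: list, best):
    """Window of the grid around the best value (adjacent grid points)."""
    i = grid_values.index(best)
    lo = max(i - 1, 0)
    hi = min(i + 1, len(grid_values) - 1)
    return grid_values[lo:hi + 1]


def tune_hyperparameters(method: str, values: pd.DataFrame, labels,
                         grid: dict | None = None, n_random: int = 10,
                         cv_folds: int = 5, seed: int = 0) -> tuple[ClassifierSpec, pd.DataFrame]:
    """Two-stage hyper-parameter search maximizing fivefold-CV MCC.

    Stage one evaluates the coarse grid exhaustively; stage two draws
    ``n_random`` seeded random points inside the region bracketed by the
    grid points adjacent to the stage-one optimum (numeric parameters are
    sampled uniformly inside the bracket, discrete ones from the bracket
    set). Returns the best spec and the full search log.
    """
    if grid is None:
        grid = METHODS[method][2]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty search space")
    y = np.asarray(labels, dtype=int)
    X = values.to_numpy(dtype=float)

    names = list(grid)
    combos = [{}]
    for name in names:
        combos = [dict(c, **{name: v}) for c in combos for v in grid[name]]

    log = []
    best_hp, best_score = None, -np.inf
    for hp in combos:
        score = _cv_mcc(ClassifierSpec(method, hp, seed), X, y, cv_folds, seed)
        log.append({"stage": "grid", **{f"hp:{k}": v for k, v in hp.items()},
                    "cv_mcc": score})
        if score > best_score:
            best_hp, best_score = hp, score

    rng = np.random.default_rng(seed)
    grid_best = dict(best_hp)  # the random stage explores around the grid optimum
    for _ in range(n_random):
        hp = {}
        for name in names:
            window = _neighborhood(grid[name], grid_best[name])
            numeric = all(isinstance(v, (int, float)) and not isinstance(v, bool)
                          for v in window)
            if numeric and len(window) > 1:
                lo, hi = min(window), max(window)
                v = rng.uniform(lo, hi)
                if all(isinstance(w, int) for w in window):
                    v = int(round(v))
                hp[name] = v
            else:
                hp[name] = window[int(rng.integers(len(window)))]
        score = _cv_mcc(ClassifierSpec(method, hp, seed), X, y, cv_folds, seed)
        log.append({"stage": "random", **{f"hp:{k}": v for k, v in hp.items()},
                    "cv_mcc": score})
        if score > best_score:
            best_hp, best_score = hp, score

    return ClassifierSpec(method, best_hp, seed), pd.DataFrame(log)


def _check_aligned(sets: list[PredictionSet]):
    if not sets:
        raise ValueError("no member prediction sets")
    ids = sets[0].compound_ids
    for s in sets[1:]:
        if list(s.compound_ids) != list(ids):
            raise ValueError("member prediction sets are not aligned")


def consensus_label(prediction_sets: list[PredictionSet]) -> PredictionSet:
    """Majority vote of member labels; probability = vote fraction.

    Requires an odd member count so no vote can tie. All members weigh
    equally.
    """
    _check_aligned(prediction_sets)
    if len(prediction_sets) % 2 == 0:
        raise ValueError("consensus_label needs an odd number of members")
    votes = np.stack([s.predicted_label for s in prediction_sets])
    return PredictionSet(prediction_sets[0].compound_ids, votes.mean(axis=0))


def consensus_probability(prediction_sets: list[PredictionSet]) -> PredictionSet:
    """Unweighted mean of member probabilities; label by the 0.5 threshold."""
    _check_aligned(prediction_sets)
    p = np.stack([s.p_inhibitor for s in prediction_sets]).mean(axis=0)
    return PredictionSet(prediction_sets[0].compound_ids, p)


def _cv_probabilities(spec: ClassifierSpec, values: pd.DataFrame,
                      y: np.ndarray, assignment: ev.FoldAssignment) -> np.ndarray:
    """Out-of-fold inhibitor probabilities under one fold assignment."""
    X = values.to_numpy(dtype=float)
    p = np.full(len(y), np.nan)
    for j in range(1, assignment.k + 1):
        te = assignment.fold_indices(j)
        tr = np.setdiff1d(np.arange(len(y)), te)
        est = spec.build()
        est.fit(X[tr], y[tr])
        proba = est.predict_proba(X[te])
        pos = list(est.classes_).index(1)
        p[te] = proba[:, pos]
    return p


DEFAULT_METHODS = ("NB", "kNN_weighted", "RLR", "SVM_RBF", "SGB", "XGBoost", "DNN")
DEFAULT_CONSENSUS_MEMBERS = ("SVM_RBF", "DNN", "XGBoost")


class BCRPInhibitionModel:
    """Binary inhibition classification model over a feature matrix.

    Parameters
    ----------
    features : FeatureMatrix
        Feature table with aligned 0/1 labels (1 = inhibitor).
    fingerprints : array-like, optional
        Bit matrix for Tanimoto cluster cross-validation; when omitted the
        matrix's own binary-bit columns are used.
    """

    def __init__(self, features: FeatureMatrix, fingerprints=None):
        if features.labels is None:
            raise ValueError("feature matrix must carry labels")
        self.features = features
        self.fingerprints = fingerprints

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       **kwargs) -> "BCRPInhibitionModel":
        """Build from a plain DataFrame; feature kinds are inferred
        (columns holding only {0,1} values become fingerprint bits)."""
        labels = df[label_col].to_numpy(dtype=int)
        values = df.drop(columns=[label_col])
        kinds = {c: ("binary_bit" if values[c].isin((0, 1)).all() else "continuous")
                 for c in values.columns}
        return cls(FeatureMatrix(values, kinds, labels), **kwargs)

    def fit(self, methods=DEFAULT_METHODS, hyperparameters: dict | None = None,
            consensus_members=DEFAULT_CONSENSUS_MEMBERS,
            test_fraction: float = 0.2, cv_folds: int = 5,
            cluster_cv: bool = False, cluster_threshold: float = 0.7,
            seed: int = 0) -> "QSARResults":
        """Split, normalize, train every method, and evaluate.

        ``hyperparameters`` maps method name to a hyper-parameter dict;
        unlisted methods use library defaults. With ``cluster_cv`` the
        training set is additionally evaluated under Tanimoto
        complete-linkage cluster folds.
        """
        hyperparameters = hyperparameters or {}
        fm = self.features
        y = fm.labels
        train_idx, test_idx = stratified_split(y, test_fraction, seed)
        stats = fit_normalizer(fm, train_idx)
        normed = normalize(fm, stats)
        train = normed.values.iloc[train_idx]
        test = normed.values.iloc[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]

        specs = {m: ClassifierSpec(m, hyperparameters.get(m, {}), seed)
                 for m in methods}
        fitted, cv_pred, test_pred = {}, {}, {}
        random_folds = ev.random_kfold(y_tr, k=cv_folds, seed=seed)[0]
        for m, spec in specs.items():
            fitted[m] = train_classifier(spec, train, y_tr)
            cv_pred[m] = PredictionSet(list(train.index),
                                       _cv_probabilities(spec, train, y_tr, random_folds))
            test_pred[m] = fitted[m].predict(test)

        if consensus_members and set(consensus_members) <= set(methods):
            members_cv = [cv_pred[m] for m in consensus_members]
            members_te = [test_pred[m] for m in consensus_members]
            cv_pred["Consensus1"] = consensus_label(members_cv)
            test_pred["Consensus1"] = consensus_label(members_te)
            cv_pred["Consensus2"] = consensus_probability(members_cv)
            test_pred["Consensus2"] = consensus_probability(members_te)

        cluster_pred = {}
        cluster_assignment = None
        if cluster_cv:
            fp = self.fingerprints
            if fp is None:
                bits = fm.binary_names()
                if not bits:
                    raise ValueError("cluster CV requires fingerprint bits")
                fp = fm.values[bits].to_numpy(dtype=int)
            fp_tr = np.asarray(fp)[train_idx]
            cluster_assignment = ev.cluster_folds(fp_tr, k=cv_folds,
                                                  distance_threshold=cluster_threshold,
                                                  seed=seed)
            for m, spec in specs.items():
                cluster_pred[m] = PredictionSet(
                    list(train.index),
                    _cv_probabilities(spec, train, y_tr, cluster_assignment))

        return QSARResults(
            model=self, fitted=fitted, normalizer=stats,
            train_idx=train_idx, test_idx=test_idx,
            y_train=y_tr, y_test=y_te,
            cv_predictions=cv_pred, test_predictions=test_pred,
            cluster_predictions=cluster_pred,
            cluster_assignment=cluster_assignment, seed=seed,
        )


@dataclass
class QSARResults:
    """Fit artifacts: fitted classifiers, fold predictions, and metrics."""

    model: BCRPInhibitionModel
    fitted: dict
    normalizer: object
    train_idx: np.ndarray
    test_idx: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray
    cv_predictions: dict
    test_predictions: dict
    cluster_predictions: dict
    cluster_assignment: object
    seed: int

    def _metric_rows(self, predictions: dict, y: np.ndarray) -> pd.DataFrame:
        rows = {}
        for name, pred in predictions.items():
            probs = pred.p_inhibitor
            use_auc = name != "Consensus1"  # vote fractions are not calibrated
            m = ev.compute_metrics(y, pred.predicted_label,
                                   probs if use_auc else None)
            rows[name] = {"GA": m.GA, "BA": m.BA, "MCC": m.MCC,
                          "AUC": m.AUC if use_auc else np.nan}
        return pd.DataFrame(rows).T[["GA", "BA", "MCC", "AUC"]]

    def metrics_cv(self) -> pd.DataFrame:
        """Random fivefold cross-validation metrics on the training set."""
        return self._metric_rows(self.cv_predictions, self.y_train)

    def metrics_test(self) -> pd.DataFrame:
        return self._metric_rows(self.test_predictions, self.y_test)

    def metrics_cluster_cv(self) -> pd.DataFrame:
        if not self.cluster_predictions:
            raise ValueError("fit was run without cluster_cv=True")
        return self._metric_rows(self.cluster_predictions, self.y_train)

    def residual_profile(self, method: str, which: str = "test",
                         grid=None) -> pd.DataFrame:
        """Cross-entropy residual exceedance curve for one model."""
        if which == "test":
            pred, y = self.test_predictions[method], self.y_test
        else:
            pred, y = self.cv_predictions[method], self.y_train
        residuals = ev.cross_entropy_residual(y, pred.p_inhibitor)
        if grid is None:
            grid = np.linspace(0.0, max(1.0, float(residuals.max())), 51)
        return ev.residual_distribution(residuals, grid)

    def misclassified(self, method: str) -> list:
        """Compound ids the model got wrong on the test set."""
        pred = self.test_predictions[method]
        wrong = pred.predicted_label != self.y_test
        return [cid for cid, w in zip(pred.compound_ids, wrong) if w]

    def summary(self) -> str:
        lines = ["BCRP inhibition classification results",
                 "=" * 46,
                 f"compounds: {len(self.y_train)} train "
                 f"({int(self.y_train.sum())} inhibitors), "
                 f"{len(self.y_test)} test ({int(self.y_test.sum())} inhibitors)",
                 f"features: {self.model.features.values.shape[1]}  seed: {self.seed}",
                 "",
                 "Training set (random fivefold cross-validation)",
                 self.metrics_cv().round(3).to_string(),
                 "",
                 "Test set",
                 self.metrics_test().round(3).to_string()]
        if self.cluster_predictions:
            lines += ["", "Training set (cluster fivefold cross-validation)",
                      self.metrics_cluster_cv().round(3).to_string()]
        return "\n".join(lines)
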