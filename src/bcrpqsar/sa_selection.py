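"""Simulated-annealing wrapper feature selection scored by random forest.

The search runs one annealing chain per cross-validation resample
(stratified k-fold with repeats). Within a chain, the current feature
subset is perturbed by toggling a small random number of features; the
candidate is accepted outright when the internal random-forest accuracy
does not drop, and otherwise with probability exp(-delta / T_i), where
delta is the accuracy drop and T_i = T0 * alpha^i follows a geometric
cooling schedule. Internal accuracy is the forest's out-of-bag accuracy on
the resample's internal 4/5; external accuracy is measured on the held-out
1/5 and is what the best iteration is chosen by.

Limiting behaviors used as sanity checks: T -> infinity gives a random
walk, T -> 0 gives greedy hill climbing with non-decreasing internal
accuracy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = ["SAConfig", "SATrace", "sa_search", "select_best_iteration"]


@dataclass(frozen=True)
class SAConfig:
    """Annealing schedule, forest settings and resampling plan."""

    max_iterations: int = 1000
    t0: float = 0.10
    alpha: float = 0.99
    max_toggle: int = 3
    rf_trees: int = 100
    cv_folds: int = 5
    cv_repeats: int = 5
    init_include_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0 (use math.inf for a random walk)")

    def temperature(self, iteration: int) -> float:
        if math.isinf(self.t0):
            return math.inf
        return self.t0 * self.alpha ** iteration


@dataclass
class SATrace:
    """Per-(resample, iteration) record of the annealing search."""

    records: pd.DataFrame  # resample, iteration, internal_acc, external_acc
    subsets: dict  # (resample, iteration) -> frozenset of feature names
    config: SAConfig
    feature_names: list[str]

    def mean_external(self) -> pd.Series:
        """Mean external accuracy across resamples, indexed by iteration."""
        return self.records.groupby("iteration")["external_acc"].mean()

    def mean_internal(self) -> pd.Series:
        return self.records.groupby("iteration")["internal_acc"].mean()


def _accept(delta: float, temperature: float, rng) -> bool:
    # delta = accuracy drop of the candidate (<= 0 means no worse)
    if delta <= 0:
        return True
    if temperature <= 0:
        return False
    if math.isinf(temperature):
        return True
    return rng.random() < math.exp(-delta / temperature)


class _SubsetScorer:
    """RF evaluation of feature subsets with per-chain memoization."""

    def __init__(self, X, y, X_ext, y_ext, names, trees, seed):
        self.X, self.y = X, y
        self.X_ext, self.y_ext = X_ext, y_ext
        self.names = names
        self.trees = trees
        self.seed = seed
        self._cache: dict[frozenset, tuple[float, float]] = {}

    def score(self, subset: frozenset) -> tuple[float, float]:
        hit = self._cache.get(subset)
        if hit is not None:
            return hit
        cols = [i for i, n in enumerate(self.names) if n in subset]
        rf = RandomForestClassifier(n_estimators=self.trees, oob_score=True,
                                    random_state=self.seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(self.X[:, cols], self.y)
            internal = float(rf.oob_score_)
        if self.X_ext is None:
            external = float("nan")
        else:
            external = float(np.mean(rf.predict(self.X_ext[:, cols]) == self.y_ext))
        self._cache[subset] = (internal, external)
        return internal, external


def _run_chain(scorer: _SubsetScorer, names, config: SAConfig, rng,
               iterations: int):
    """One annealing chain; yields (iteration, subset, internal, external)."""
    n = len(names)
    include = rng.random(n) < config.init_include_prob
    if not include.any():
        include[rng.integers(n)] = True
    current = frozenset(np.asarray(names)[include])
    cur_int, cur_ext = scorer.score(current)
    out = []
    for it in range(1, iterations + 1):
        k = int(rng.integers(1, config.max_toggle + 1))
        toggle = rng.choice(n, size=min(k, n), replace=False)
        candidate = set(current)
        for t in toggle:
            name = names[t]
            if name in candidate:
                candidate.discard(name)
            else:
                candidate.add(name)
        if candidate:
            candidate = frozenset(candidate)
            cand_int, cand_ext = scorer.score(candidate)
            if _accept(cur_int - cand_int, config.temperature(it), rng):
                current, cur_int, cur_ext = candidate, cand_int, cand_ext
        out.append((it, current, cur_int, cur_ext))
    return out


def sa_search(train_values: pd.DataFrame, labels, config: SAConfig) -> SATrace:
    """Run the resampled simulated-annealing subset search.

    Parameters
    ----------
    train_values : DataFrame
        Filtered and normalized training feature table (rows = compounds).
    labels : array-like of 0/1
    config : SAConfig
    """
    names = list(train_values.columns)
    if not names:
        raise ValueError("empty feature space")
    y = np.asarray(labels, dtype=int)
    if not np.isin(y, (0, 1)).all() or len(np.unique(y)) < 2:
        raise ValueError("labels must be binary with both classes present")
    X = train_values.to_numpy(dtype=float)

    rskf = RepeatedStratifiedKFold(n_splits=config.cv_folds,
                                   n_repeats=config.cv_repeats,
                                   random_state=config.seed)
    rows, subsets = [], {}
    for resample, (int_idx, ext_idx) in enumerate(rskf.split(X, y)):
        rng = np.random.default_rng([config.seed, resample])
        scorer = _SubsetScorer(X[int_idx], y[int_idx], X[ext_idx], y[ext_idx],
                               names, config.rf_trees, config.seed)
        for it, subset, internal, external in _run_chain(
                scorer, names, config, rng, config.max_iterations):
            rows.append({"resample": resample, "iteration": it,
                         "internal_acc": internal, "external_acc": external})
            subsets[(resample, it)] = subset
    records = pd.DataFrame(rows)
    return SATrace(records=records, subsets=subsets, config=config,
                   feature_names=names)


def select_best_iteration(trace: SATrace, train_values: pd.DataFrame,
                          labels) -> tuple[int, frozenset]:
    """Best iteration by mean external accuracy; final subset consolidation.

    The best iteration is the argmax of the mean external accuracy over
    resamples (earliest iteration on ties). The final subset is re-derived
    by running a fresh annealing chain on the full training set up to that
    iteration under the stored seed, scoring with out-of-bag accuracy.
    """
    if trace.records.empty:
        raise ValueError("empty trace")
    mean_ext = trace.mean_external()
    best_iter = int(mean_ext.idxmax())  # idxmax returns first occurrence
    y = np.asarray(labels, dtype=int)
    names = list(train_values.columns)
    X = train_values.to_numpy(dtype=float)
    rng = np.random.default_rng([trace.config.seed, 999_983])
    scorer = _SubsetScorer(X, y, None, None, names, trace.config.rf_trees,
                           trace.config.seed)
    chain = _run_chain(scorer, names, trace.config, rng, best_iter)
    final_subset = chain[-1][1]
    return best_iter, frozenset(final_subset)
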