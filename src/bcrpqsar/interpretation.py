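"""Perturbation-based, model-agnostic feature importance.

One feature at a time is perturbed by permuting its column across
compounds (all other columns fixed), which preserves the feature's
marginal distribution while breaking its association with the labels. The
importance of the feature is the increase in mean binary cross-entropy
loss relative to the unperturbed model, averaged over repetitions with
distinct permutations (10 by default, for repeatability). A feature the
model never uses has importance near zero; a constant feature has
importance exactly zero because permuting it is the identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import cross_entropy_residual

__all__ = ["permutation_importance", "top_features"]


def _mean_loss(model, values: pd.DataFrame, y: np.ndarray) -> float:
    p = model.predict_proba(values)
    return float(np.mean(cross_entropy_residual(y, p)))


def permutation_importance(model, values: pd.DataFrame, labels,
                           n_repeats: int = 10, seed: int = 0,
                           features=None) -> pd.DataFrame:
    """Permutation importance of every feature under cross-entropy loss.

    Parameters
    ----------
    model : object with ``predict_proba(values) -> p_inhibitor``
    values : DataFrame of the evaluation set (typically the test set)
    labels : aligned 0/1 vector
    n_repeats : permutations averaged per feature
    features : subset of feature names to score (default: all columns)

    Returns
    -------
    DataFrame (feature, importance_mean, importance_sd, rank, baseline_loss)
    sorted by importance descending.
    """
    y = np.asarray(labels, dtype=int)
    if features is None:
        features = list(values.columns)
    missing = [f for f in features if f not in values.columns]
    if missing:
        raise ValueError(f"features absent from the matrix: {missing[:5]}")
    rng = np.random.default_rng(seed)
    baseline = _mean_loss(model, values, y)
    n = len(values)
    rows = []
    for f in features:
        if values[f].nunique() <= 1:
            rows.append({"feature": f, "importance_mean": 0.0,
                         "importance_sd": 0.0})
            continue
        losses = []
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            perturbed = values.copy()
            perturbed[f] = values[f].to_numpy()[perm]
            losses.append(_mean_loss(model, perturbed, y))
        losses = np.asarray(losses)
        rows.append({"feature": f,
                     "importance_mean": float(losses.mean() - baseline),
                     "importance_sd": float(losses.std(ddof=0))})
    df = pd.DataFrame(rows)
    df["baseline_loss"] = baseline
    df = df.sort_values("importance_mean", ascending=False,
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def top_features(importance: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """The n most important features (bar-plot layout order)."""
    return importance.head(n).reset_index(drop=True)
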