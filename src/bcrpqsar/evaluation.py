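"""Validation machinery for binary QSAR classifiers.

Implements the confusion-matrix statistics used throughout the pipeline
(global accuracy, balanced accuracy, Matthews correlation coefficient),
rank-based AUC, per-compound binary cross-entropy residuals and their
exceedance curves, stratified random k-fold assignment, and Tanimoto
complete-linkage cluster cross-validation folds that keep whole chemical
clusters inside one fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMetrics",
    "FoldAssignment",
    "confusion",
    "global_accuracy",
    "balanced_accuracy",
    "mcc",
    "auc",
    "compute_metrics",
    "cross_entropy_residual",
    "residual_distribution",
    "random_kfold",
    "tanimoto",
    "tanimoto_distance_matrix",
    "cluster_folds",
]

_EPS = 1e-15


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts plus the derived statistics for one prediction set."""

    TP: int
    TN: int
    FP: int
    FN: int
    GA: float
    BA: float
    MCC: float
    AUC: float | None = None

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def as_dict(self) -> dict:
        d = {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
             "GA": self.GA, "BA": self.BA, "MCC": self.MCC}
        if self.AUC is not None:
            d["AUC"] = self.AUC
        return d


@dataclass
class FoldAssignment:
    """Maps each compound to a fold under one of the two CV schemes."""

    fold: np.ndarray  # fold index per compound, 1..k
    k: int
    scheme: str  # "random_stratified" or "cluster"
    cluster_id: np.ndarray | None = None

    def fold_indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.fold == j)

    @property
    def fold_sizes(self) -> list[int]:
        return [int(np.sum(self.fold == j)) for j in range(1, self.k + 1)]


def _as_binary(a, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return a.astype(int)


def confusion(true_labels, predicted_labels) -> tuple[int, int, int, int]:
    """Count (TP, TN, FP, FN); the positive class is the inhibitor (label 1)."""
    y = _as_binary(true_labels, "true_labels")
    p = _as_binary(predicted_labels, "predicted_labels")
    if y.shape != p.shape:
        raise ValueError("true and predicted label vectors differ in length")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return tp, tn, fp, fn


def global_accuracy(TP: int, TN: int, FP: int, FN: int) -> float:
    """GA = (TP + TN) / (TP + TN + FP + FN)."""
    total = TP + TN + FP + FN
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return (TP + TN) / total


def balanced_accuracy(TP: int, TN: int, FP: int, FN: int) -> float:
    """BA = 0.5 * (sensitivity + specificity)."""
    if TP + FN == 0 or TN + FP == 0:
        raise ValueError("balanced accuracy undefined: one class is empty")
    return 0.5 * (TP / (TP + FN) + TN / (TN + FP))


def mcc(TP: int, TN: int, FP: int, FN: int) -> float:
    """Matthews correlation coefficient.

    Any zero factor in the denominator yields 0 (the standard continuity
    convention for a degenerate confusion matrix).
    """
    denom = (TP + FN) * (TP + FP) * (FN + TN) * (TN + FP)
    if denom == 0:
        return 0.0
    return (TP * TN - FN * FP) / math.sqrt(denom)


def auc(true_labels, probabilities) -> float:
    """Area under the ROC curve, rank-based with midrank tie handling."""
    y = _as_binary(true_labels, "true_labels")
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def compute_metrics(true_labels, predicted_labels, probabilities=None) -> ConfusionMetrics:
    """Full metric panel for one prediction set (AUC only if probabilities given)."""
    tp, tn, fp, fn = confusion(true_labels, predicted_labels)
    a = auc(true_labels, probabilities) if probabilities is not None else None
    return ConfusionMetrics(
        TP=tp, TN=tn, FP=fp, FN=fn,
        GA=global_accuracy(tp, tn, fp, fn),
        BA=balanced_accuracy(tp, tn, fp, fn),
        MCC=mcc(tp, tn, fp, fn),
        AUC=a,
    )


def cross_entropy_residual(y, p, eps: float = _EPS) -> np.ndarray:
    """Per-compound binary cross entropy -[y ln p + (1-y) ln(1-p)].

    Natural logarithm; probabilities are clipped to [eps, 1-eps] before the
    logarithm so residuals stay finite at p in {0, 1}.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pc = np.clip(p, eps, 1 - eps)
    return -(y * np.log(pc) + (1 - y) * np.log(1 - pc))


def residual_distribution(residuals, grid) -> pd.DataFrame:
    """Exceedance curve: fraction of compounds with residual > threshold.

    Equals one minus the empirical CDF evaluated on the threshold grid, so
    the curve is monotone non-increasing.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residual set")
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals must be finite")
    g = np.asarray(grid, dtype=float)
    frac = np.array([np.mean(r > t) for t in g])
    return pd.DataFrame({"threshold": g, "fraction_above": frac})


def random_kfold(labels, k: int = 5, seed: int = 0, repeats: int = 1) -> list[FoldAssignment]:
    """Stratified random k-fold assignments (one FoldAssignment per repeat)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = _as_binary(labels, "labels")
    if len(y) < k:
        raise ValueError("fewer compounds than folds")
    out = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        fold = np.zeros(len(y), dtype=int)
        for j, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y), start=1):
            fold[test_idx] = j
        out.append(FoldAssignment(fold=fold, k=k, scheme="random_stratified"))
    return out


def tanimoto(bits_a, bits_b) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| on equal-length bit vectors.

    Two all-zero vectors are defined as identical (similarity 1).
    """
    a = np.asarray(bits_a).astype(bool)
    b = np.asarray(bits_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("bit vectors differ in length")
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return int(np.sum(a & b)) / union


def tanimoto_distance_matrix(fingerprints) -> np.ndarray:
    """Pairwise 1 - Tanimoto distances for a (n_compounds, n_bits) bit array."""
    fp = np.asarray(fingerprints).astype(bool)
    inter = fp.astype(np.int32) @ fp.astype(np.int32).T
    counts = fp.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(sim, 1.0)
    return 1.0 - sim


def cluster_folds(fingerprints, k: int = 5, distance_threshold: float = 0.7,
                  seed: int = 0) -> FoldAssignment:
    """Cluster cross-validation folds from complete-linkage Tanimoto clusters.

    Compounds are clustered by agglomerative complete linkage on
    1 - Tanimoto distance; the dendrogram is cut at ``distance_threshold``
    (so the maximum intra-cluster pairwise distance never exceeds the cut),
    and whole clusters are dealt greedily, in seeded random order, to the
    currently smallest fold.
    """
    fp = np.asarray(fingerprints)
    n = fp.shape[0]
    if n < k:
        raise ValueError("fewer compounds than folds")
    dist = tanimoto_distance_matrix(fp)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="complete")
    cluster_id = fcluster(z, t=distance_threshold, criterion="distance")
    uniq = np.unique(cluster_id)
    if len(uniq) < k:
        raise ValueError(f"only {len(uniq)} clusters at cut {distance_threshold}; need >= {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    fold_of_cluster: dict[int, int] = {}
    sizes = np.zeros(k, dtype=int)
    for c in order:
        j = int(np.argmin(sizes))
        fold_of_cluster[int(c)] = j + 1
        sizes[j] += int(np.sum(cluster_id == c))
    fold = np.array([fold_of_cluster[int(c)] for c in cluster_id])
    return FoldAssignment(fold=fold, k=k, scheme="cluster", cluster_id=cluster_id)
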