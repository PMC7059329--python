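"""Applicability domain via non-parametric probability density estimation.

The training feature space is projected onto the principal components
retaining a requested fraction of variance, and a Gaussian kernel density
estimate (Scott bandwidth) is fitted to the projected training compounds.
A query compound is inside the domain when its estimated density reaches
the threshold, which defaults to the minimum density observed over the
training compounds — so the training set itself is always fully covered.
Unlike range or leverage approaches this can flag internal empty regions
of feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

__all__ = ["ADModel", "fit_ad", "coverage"]


@dataclass
class ADModel:
    """Fitted density model over a reduced training feature space."""

    pca: PCA
    kde: gaussian_kde
    threshold: float
    n_components: int
    variance_explained: float
    feature_names: list[str]

    def density(self, values: pd.DataFrame) -> np.ndarray:
        if list(values.columns) != self.feature_names:
            raise ValueError("feature mismatch with the fitted domain model")
        z = self.pca.transform(values.to_numpy(dtype=float))
        return self.kde(z.T)

    def inside(self, values: pd.DataFrame) -> np.ndarray:
        return self.density(values) >= self.threshold


def fit_ad(train_values: pd.DataFrame, variance: float = 0.95,
           threshold_percentile: float = 0.0) -> ADModel:
    """Fit the applicability domain on normalized training features.

    Parameters
    ----------
    train_values : DataFrame
        Normalized training feature table.
    variance : float
        Fraction of variance the principal-component projection retains.
    threshold_percentile : float
        Percentile of training densities used as the inside/outside
        threshold; 0 keeps every training compound inside.
    """
    X = train_values.to_numpy(dtype=float)
    n = X.shape[0]
    max_comp = min(n - 1, X.shape[1])
    pca = PCA(n_components=max_comp).fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance) + 1)
    k = min(k, max_comp)
    if n <= k or n < 10:
        raise ValueError("too few training compounds for a density estimate")
    pca = PCA(n_components=k).fit(X)
    z = pca.transform(X)
    kde = gaussian_kde(z.T, bw_method="scott")
    dens = kde(z.T)
    threshold = float(np.percentile(dens, threshold_percentile)
                      if threshold_percentile > 0 else dens.min())
    return ADModel(pca=pca, kde=kde, threshold=threshold, n_components=k,
                   variance_explained=float(cum[k - 1]),
                   feature_names=list(train_values.columns))


def coverage(ad: ADModel, values: pd.DataFrame, labels=None) -> dict:
    """Per-class inside/outside counts and the coverage percentage."""
    inside = ad.inside(values)
    out = {
        "n": int(len(values)),
        "inside": int(inside.sum()),
        "outside": int((~inside).sum()),
        "coverage_pct": 100.0 * float(inside.mean()) if len(values) else float("nan"),
    }
    if labels is not None:
        y = np.asarray(labels, dtype=int)
        out["inside_inhibitor"] = int(inside[y == 1].sum())
        out["inside_noninhibitor"] = int(inside[y == 0].sum())
        out["outside_inhibitor"] = int((~inside)[y == 1].sum())
        out["outside_noninhibitor"] = int((~inside)[y == 0].sum())
    return out
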