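"""Molecular features, pre-filters, splitting, and property comparison.

Descriptors are computed with RDKit (namespaced ``desc:``) and substructure
bits are MACCS keys (namespaced ``fp:``), so the downstream pipeline is
agnostic to the feature set. Pre-filters follow the standard QSAR recipe:
drop features with missing values, near-zero-variance features, and one
member of every highly correlated pair (|r| > 0.90). Splitting is
stratified 4:1 with per-class floor rounding, and normalization is
z-scoring of continuous features with statistics from the training rows
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import MACCSkeys
from scipy.stats import mannwhitneyu

__all__ = [
    "FeatureMatrix",
    "compute_features",
    "binary_fingerprints",
    "near_zero_variance_filter",
    "correlation_filter",
    "stratified_split",
    "NormalizationStats",
    "fit_normalizer",
    "normalize",
    "simple_descriptors",
    "compare_property_distributions",
]

CONTINUOUS = "continuous"
BINARY_BIT = "binary_bit"


@dataclass
class FeatureMatrix:
    """Compounds x named features with per-feature kind tags.

    ``values`` is a DataFrame whose index holds compound ids; ``kinds``
    maps every column to "continuous" or "binary_bit"; ``labels`` is an
    optional aligned 0/1 vector.
    """

    values: pd.DataFrame
    kinds: dict[str, str]
    labels: np.ndarray | None = None
    informative: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.kinds)
        if missing:
            raise ValueError(f"features without kind tag: {sorted(missing)[:5]}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.values):
                raise ValueError("labels not aligned with rows")
        for name, kind in self.kinds.items():
            if kind == BINARY_BIT and name in self.values.columns:
                col = self.values[name]
                if not col.isin((0, 1)).all():
                    raise ValueError(f"binary feature {name} has non 0/1 values")

    @property
    def compound_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def continuous_names(self) -> list[str]:
        return [c for c in self.values.columns if self.kinds[c] == CONTINUOUS]

    def binary_names(self) -> list[str]:
        return [c for c in self.values.columns if self.kinds[c] == BINARY_BIT]

    def subset_features(self, names) -> "FeatureMatrix":
        names = [n for n in self.values.columns if n in set(names)]
        return FeatureMatrix(self.values[names].copy(),
                             {n: self.kinds[n] for n in names},
                             None if self.labels is None else self.labels.copy(),
                             [n for n in self.informative if n in set(names)])

    def subset_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(self.values.iloc[idx].copy(), dict(self.kinds),
                             None if self.labels is None else self.labels[idx],
                             list(self.informative))


# descriptor name -> callable; a compact, reproducible open-source set
_DESCRIPTORS = {
    "MolWt": Descriptors.MolWt,
    "MolLogP": Crippen.MolLogP,
    "MolMR": Crippen.MolMR,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "NumHAcceptors": Lipinski.NumHAcceptors,
    "NumHDonors": Lipinski.NumHDonors,
    "NumRotatableBonds": Lipinski.NumRotatableBonds,
    "NumAromaticRings": Lipinski.NumAromaticRings,
    "NumAliphaticRings": Lipinski.NumAliphaticRings,
    "NumSaturatedRings": Lipinski.NumSaturatedRings,
    "RingCount": Lipinski.RingCount,
    "HeavyAtomCount": Lipinski.HeavyAtomCount,
    "NHOHCount": Lipinski.NHOHCount,
    "NOCount": Lipinski.NOCount,
    "FractionCSP3": Lipinski.FractionCSP3,
    "NumHeteroatoms": Lipinski.NumHeteroatoms,
    "LabuteASA": rdMolDescriptors.CalcLabuteASA,
    "BalabanJ": GraphDescriptors.BalabanJ,
    "BertzCT": GraphDescriptors.BertzCT,
    "Chi0v": GraphDescriptors.Chi0v,
    "Chi1v": GraphDescriptors.Chi1v,
    "Chi2v": GraphDescriptors.Chi2v,
    "Kappa1": GraphDescriptors.Kappa1,
    "Kappa2": GraphDescriptors.Kappa2,
    "Kappa3": GraphDescriptors.Kappa3,
    "HallKierAlpha": GraphDescriptors.HallKierAlpha,
    "MaxPartialCharge": Descriptors.MaxPartialCharge,
    "MinPartialCharge": Descriptors.MinPartialCharge,
    "NumAromaticAtoms": lambda m: sum(a.GetIsAromatic() for a in m.GetAtoms()),
    "NumAromaticBonds": lambda m: sum(b.GetIsAromatic() for b in m.GetBonds()),
    "qed": Descriptors.qed,
}


def _mols(compounds):
    out = []
    for c in compounds:
        m = c if isinstance(c, Chem.Mol) else Chem.MolFromSmiles(c)
        out.append(m)
    return out


def binary_fingerprints(compounds) -> np.ndarray:
    """MACCS key bit matrix (n_compounds, 167) for Tanimoto work."""
    rows = []
    for m in _mols(compounds):
        if m is None:
            raise ValueError("unparseable structure in fingerprint input")
        fp = MACCSkeys.GenMACCSKeys(m)
        rows.append(np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype="S1") == b"1")
    return np.asarray(rows, dtype=int)


def compute_features(compounds, ids=None, labels=None) -> tuple[FeatureMatrix, list]:
    """Compute descriptor + fingerprint features for a compound library.

    Returns the feature matrix and the list of compound indices that were
    dropped because a descriptor failed. Columns with any missing value are
    removed (the missing-value filter).
    """
    mols = _mols(compounds)
    if ids is None:
        ids = list(range(len(mols)))
    keep_rows, dropped = [], []
    desc_rows, fp_rows = [], []
    for i, m in enumerate(mols):
        if m is None:
            dropped.append(ids[i])
            continue
        row = {}
        ok = True
        for name, fn in _DESCRIPTORS.items():
            try:
                v = fn(m)
            except Exception:
                ok = False
                break
            row[f"desc:{name}"] = v
        if not ok:
            dropped.append(ids[i])
            continue
        fp = MACCSkeys.GenMACCSKeys(m)
        fp_rows.append([int(b) for b in fp.ToBitString()])
        desc_rows.append(row)
        keep_rows.append(i)
    desc = pd.DataFrame(desc_rows, index=[ids[i] for i in keep_rows])
    fp = pd.DataFrame(np.asarray(fp_rows, dtype=int),
                      index=desc.index,
                      columns=[f"fp:MACCS_{j}" for j in range(len(fp_rows[0]))] if fp_rows else [])
    values = pd.concat([desc, fp], axis=1)
    # missing-value filter: drop any column with a non-finite entry
    finite = values.columns[np.isfinite(values.to_numpy(dtype=float)).all(axis=0)]
    values = values[list(finite)]
    kinds = {c: (CONTINUOUS if c.startswith("desc:") else BINARY_BIT)
             for c in values.columns}
    lab = None
    if labels is not None:
        lab = np.asarray([labels[i] for i in keep_rows], dtype=int)
    return FeatureMatrix(values, kinds, lab), dropped


def near_zero_variance_filter(matrix: FeatureMatrix, freq_cut: float = 95 / 5,
                              unique_cut: float = 10.0) -> list[str]:
    """Names of features surviving the near-zero-variance filter.

    A feature is removed when it has a single unique value, or when the
    ratio of the most common to the second most common value exceeds
    ``freq_cut`` while the percentage of unique values is below
    ``unique_cut``.
    """
    retained = []
    n = len(matrix.values)
    for c in matrix.values.columns:
        col = matrix.values[c]
        counts = col.value_counts()
        if len(counts) == 1:
            continue
        freq_ratio = counts.iloc[0] / counts.iloc[1]
        pct_unique = 100.0 * len(counts) / n
        if freq_ratio > freq_cut and pct_unique < unique_cut:
            continue
        retained.append(c)
    return retained


def correlation_filter(matrix: FeatureMatrix, threshold: float = 0.90) -> list[str]:
    """Greedy elimination of highly correlated features.

    While any pair with |Pearson r| above ``threshold`` remains, the member
    of the worst pair with the larger mean absolute correlation against all
    remaining features is removed; ties break deterministically toward the
    earlier column.
    """
    cols = list(matrix.values.columns)
    arr = matrix.values.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"zero-variance features present (run NZV first): {bad[:5]}")
    corr = np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    corr = np.abs(corr)
    alive = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(alive, alive)]
        m = sub.max()
        if m <= threshold:
            break
        i, j = np.unravel_index(int(sub.argmax()), sub.shape)
        mean_i = sub[i].sum() / (len(alive) - 1)
        mean_j = sub[j].sum() / (len(alive) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = min(i, j)
        alive.pop(drop)
    return [cols[i] for i in alive]


def stratified_split(labels, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split with per-class floor rounding.

    The test set receives floor(class_size * test_fraction) compounds of
    each class, sampled uniformly; the remainder stays in training. With
    1098/1701 compounds at 1/5 this reproduces the 879/1361 train and
    219/340 test partition.
    """
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if len(members) < 5:
            raise ValueError(f"class {cls} has fewer than 5 members")
        n_test = int(np.floor(len(members) * test_fraction))
        test_idx.extend(rng.choice(members, size=n_test, replace=False))
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    return train_idx, test_idx


@dataclass(frozen=True)
class NormalizationStats:
    mean: pd.Series
    std: pd.Series


def fit_normalizer(matrix: FeatureMatrix, train_idx=None) -> NormalizationStats:
    """Mean/sd of every continuous feature, from training rows only."""
    rows = matrix.values if train_idx is None else matrix.values.iloc[np.asarray(train_idx)]
    cont = matrix.continuous_names()
    mean = rows[cont].mean()
    std = rows[cont].std(ddof=0)
    if (std == 0).any():
        bad = list(std.index[std == 0])
        raise ValueError(f"zero-variance continuous features: {bad[:5]}")
    return NormalizationStats(mean=mean, std=std)


def normalize(matrix: FeatureMatrix, stats: NormalizationStats) -> FeatureMatrix:
    """Z-score continuous features with reference statistics; bits untouched."""
    values = matrix.values.copy()
    cont = list(stats.mean.index)
    values[cont] = (values[cont] - stats.mean) / stats.std
    return FeatureMatrix(values, dict(matrix.kinds),
                         None if matrix.labels is None else matrix.labels.copy(),
                         list(matrix.informative))


def _aromatic_proportion(mol) -> float:
    heavy = mol.GetNumHeavyAtoms()
    if heavy == 0:
        return 0.0
    return sum(a.GetIsAromatic() for a in mol.GetAtoms()) / heavy


def _esol_logs(mol) -> float:
    # Delaney ESOL estimate of aqueous solubility (log mol/L)
    return (0.16 - 0.63 * Crippen.MolLogP(mol) - 0.0062 * Descriptors.MolWt(mol)
            + 0.066 * Lipinski.NumRotatableBonds(mol) - 0.74 * _aromatic_proportion(mol))


def _kier_flex(mol) -> float:
    heavy = mol.GetNumHeavyAtoms()
    if heavy == 0:
        return 0.0
    return GraphDescriptors.Kappa1(mol) * GraphDescriptors.Kappa2(mol) / heavy


_SIMPLE = {
    "logP": Crippen.MolLogP,
    "logS": _esol_logs,
    "h_acceptors": Lipinski.NumHAcceptors,
    "h_donors": Lipinski.NumHDonors,
    "rotatable_bonds": Lipinski.NumRotatableBonds,
    "flexibility": _kier_flex,
    "aromatic_atoms": lambda m: sum(a.GetIsAromatic() for a in m.GetAtoms()),
    "aromatic_bonds": lambda m: sum(b.GetIsAromatic() for b in m.GetBonds()),
}


def simple_descriptors(compounds) -> pd.DataFrame:
    """The eight interpretable physicochemical descriptors used for the
    class-comparison analysis (lipophilicity, solubility, H-bonding,
    flexibility, aromaticity)."""
    mols = _mols(compounds)
    rows = []
    for m in mols:
        if m is None:
            raise ValueError("unparseable structure")
        rows.append({k: fn(m) for k, fn in _SIMPLE.items()})
    return pd.DataFrame(rows)


def compare_property_distributions(compounds, labels) -> pd.DataFrame:
    """Per-class means and Mann–Whitney U p-values for the eight simple
    descriptors (two-sided; non-parametric, so no normality assumption)."""
    desc = simple_descriptors(compounds)
    y = np.asarray(labels, dtype=int)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("each class needs at least 2 compounds")
    rows = []
    for c in desc.columns:
        a = desc[c][y == 1]
        b = desc[c][y == 0]
        p = mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append({"descriptor": c,
                     "mean_inhibitor": float(a.mean()),
                     "mean_noninhibitor": float(b.mean()),
                     "p_value": float(p)})
    return pd.DataFrame(rows)
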