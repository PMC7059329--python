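"""Synthetic inputs for every pipeline stage.

Three generators emulate the study's data shapes without any download:

* :func:`gen_feature_table` — numeric feature tables with a known
  informative subset: class-conditional unit-variance normals whose means
  differ by ``effect_size`` (so the effect size is a Cohen's d), plus pure
  noise features and Bernoulli fingerprint bits with class-dependent rates;
* :func:`gen_compound_library` — labeled SMILES libraries with planted
  ring-system fragments included at class-dependent rates, with exact
  ground-truth membership returned alongside;
* :func:`gen_activity_records` — an activity-record fixture table covering
  every curation rule branch, with the expected disposition of each record
  riding alongside (never inside) the records.

Identical spec + seed reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .featurization import BINARY_BIT, CONTINUOUS, FeatureMatrix

__all__ = ["SyntheticSpec", "gen_feature_table", "gen_compound_library",
           "gen_activity_records"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the curated dataset's class balance (1098 inhibitors,
    1701 non-inhibitors) at a reduced desk scale, with a clearly separable
    informative subset.
    """

    n_inhibitors: int = 400
    n_noninhibitors: int = 400
    n_informative_continuous: int = 5
    n_noise_continuous: int = 45
    n_fingerprint_bits: int = 32
    effect_size: float = 3.0
    bit_rate_inhibitor: float = 0.5
    bit_rate_noninhibitor: float = 0.5
    planted_fragments: tuple = ()  # (scaffold_smiles, inhib_rate, noninhib_rate)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_inhibitors", "n_noninhibitors", "n_informative_continuous",
                     "n_noise_continuous", "n_fingerprint_bits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not math.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        for name in ("bit_rate_inhibitor", "bit_rate_noninhibitor"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for frag in self.planted_fragments:
            smi, r1, r0 = frag
            if not 0.0 <= r1 <= 1.0 or not 0.0 <= r0 <= 1.0:
                raise ValueError(f"fragment rates must be in [0, 1]: {frag}")


def gen_feature_table(spec: SyntheticSpec) -> FeatureMatrix:
    """Numeric feature table with labels and ground-truth informative names.

    Informative continuous features: N(+d/2, 1) for inhibitors and
    N(-d/2, 1) for non-inhibitors with d = ``effect_size``; noise features
    N(0, 1) in both classes; fingerprint bits Bernoulli with the
    class-dependent rates. The names of informative features are recorded
    in ``FeatureMatrix.informative``.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n0 = spec.n_inhibitors, spec.n_noninhibitors
    n = n1 + n0
    labels = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    d = spec.effect_size
    cols = {}
    informative = []
    for j in range(spec.n_informative_continuous):
        name = f"desc:informative_{j:02d}"
        shift = np.where(labels == 1, d / 2.0, -d / 2.0)
        cols[name] = rng.normal(0.0, 1.0, size=n) + shift
        if d != 0.0:
            informative.append(name)
    for j in range(spec.n_noise_continuous):
        cols[f"desc:noise_{j:02d}"] = rng.normal(0.0, 1.0, size=n)
    for j in range(spec.n_fingerprint_bits):
        rates = np.where(labels == 1, spec.bit_rate_inhibitor,
                         spec.bit_rate_noninhibitor)
        cols[f"fp:bit_{j:03d}"] = (rng.random(n) < rates).astype(int)
        if spec.bit_rate_inhibitor != spec.bit_rate_noninhibitor:
            informative.append(f"fp:bit_{j:03d}")
    values = pd.DataFrame(cols, index=[f"cmp_{i:05d}" for i in range(n)])
    kinds = {c: (CONTINUOUS if c.startswith("desc:") else BINARY_BIT)
             for c in values.columns}
    return FeatureMatrix(values, kinds, labels, informative)


_SUBSTITUENTS = ("C", "Cl", "OC")  # methyl, chloro, methoxy
_BACKGROUND = ("c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCNCC1", "c1ccc2ccccc2c1")


def _attachable_atoms(mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def _attach(mol: Chem.Mol, group_smiles: str, at_idx: int, rng) -> Chem.Mol:
    group = Chem.MolFromSmiles(group_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, group))
    g_idx = mol.GetNumAtoms()  # first atom of the group
    combo.AddBond(at_idx, g_idx, Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _link(a: Chem.Mol, b: Chem.Mol, rng) -> Chem.Mol:
    """Join two ring systems with a short acyclic -CC- linker."""
    ai = int(rng.choice(_attachable_atoms(a)))
    linked = _attach(a, "CC", ai, rng)
    bi = int(rng.choice(_attachable_atoms(b)))
    combo = Chem.RWMol(Chem.CombineMols(linked, b))
    tail = linked.GetNumAtoms() - 1  # last linker carbon
    combo.AddBond(tail, linked.GetNumAtoms() + bi, Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def gen_compound_library(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Labeled SMILES library with planted fragments at class-dependent rates.

    Each compound is one or more ring-system scaffolds, joined by short
    acyclic linkers when a compound carries several planted scaffolds, then
    decorated with 0–2 substituents from a small vocabulary (methyl,
    chloro, methoxy). Planted scaffolds are included independently per
    compound with the class rate from the spec; compounds receiving none
    are built from a background scaffold vocabulary.

    Returns
    -------
    (library, membership)
        ``library``: DataFrame (id, smiles, label). ``membership``: boolean
        DataFrame, one column per planted scaffold (canonical SMILES),
        giving exact ground-truth fragment membership.
    """
    scaffolds = []
    for smi, r1, r0 in spec.planted_fragments:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid scaffold SMILES: {smi!r}")
        scaffolds.append((Chem.MolToSmiles(mol), r1, r0))
    planted_canon = {s for s, _, _ in scaffolds}
    background = [b for b in _BACKGROUND
                  if Chem.MolToSmiles(Chem.MolFromSmiles(b)) not in planted_canon]

    rng = np.random.default_rng(spec.seed)
    n1, n0 = spec.n_inhibitors, spec.n_noninhibitors
    labels = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    rows, member_rows = [], []
    for i, y in enumerate(labels):
        present = [s for s, r1, r0 in scaffolds
                   if rng.random() < (r1 if y == 1 else r0)]
        if present:
            mol = Chem.MolFromSmiles(present[0])
            for extra in present[1:]:
                mol = _link(mol, Chem.MolFromSmiles(extra), rng)
        else:
            mol = Chem.MolFromSmiles(background[int(rng.integers(len(background)))])
        for _ in range(int(rng.integers(0, 3))):
            sites = _attachable_atoms(mol)
            if not sites:
                break
            sub = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
            mol = _attach(mol, sub, int(rng.choice(sites)), rng)
        rows.append({"id": f"syn_{i:05d}", "smiles": Chem.MolToSmiles(mol),
                     "label": int(y)})
        member_rows.append({s: (s in present) for s, _, _ in scaffolds})
    library = pd.DataFrame(rows, columns=["id", "smiles", "label"])
    membership = pd.DataFrame(member_rows,
                              columns=[s for s, _, _ in scaffolds], dtype=bool)
    membership.index = library["id"]
    return library, membership


def gen_activity_records(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Activity-record fixture table covering every curation rule branch.

    Returns the record table (compound_id, smiles, index_type, value,
    concentration, outcome, source_id) and an expectations table
    (compound_id, expected_disposition, expected_label) kept separate so
    curation never sees ground truth.
    """
    # distinct, trivially valid backbone structures
    chain = lambda k: "C" * k  # noqa: E731
    rec, exp = [], []

    def add(cid, smiles, index_type, value=None, conc=None, outcome=None,
            disposition="removed", label=None, source="fixture"):
        rec.append({"compound_id": cid, "smiles": smiles, "index_type": index_type,
                    "value": value, "concentration": conc, "outcome": outcome,
                    "source_id": source})
        exp.append({"compound_id": cid, "expected_disposition": disposition,
                    "expected_label": label})

    add("ic50_low", chain(3), "IC50", 8.0, disposition="inhibitor", label=1)
    add("ec50_low", chain(4), "EC50", 5.0, disposition="inhibitor", label=1)
    add("ic50_high", chain(5), "IC50", 60.0, disposition="non_inhibitor", label=0)
    add("ic50_window", chain(6), "IC50", 30.0)
    add("ic50_boundary_low", chain(7), "IC50", 10.0)
    add("ic50_boundary_high", chain(8), "IC50", 50.0)
    add("pct_high", chain(9), "percent_inhibition", 80.0, conc=10.0,
        disposition="inhibitor", label=1)
    add("pct_low", chain(10), "percent_inhibition", 20.0, conc=10.0,
        disposition="non_inhibitor", label=0)
    add("pct_window", chain(11), "percent_inhibition", 35.0, conc=10.0)
    add("pct_wrong_conc", chain(12), "percent_inhibition", 90.0, conc=5.0)
    add("qual_active", chain(13), "qualitative", outcome="Active",
        disposition="inhibitor", label=1)
    add("qual_inactive", chain(14), "qualitative", outcome="Inactive",
        disposition="non_inhibitor", label=0)
    add("qual_inconclusive", chain(15), "qualitative", outcome="Inconclusive")
    add("qual_unspecified", chain(16), "qualitative", outcome="Unspecified")

    # concordant replicates: mean(4, 6) = 5 -> inhibitor
    for v, src in ((4.0, "s1"), (6.0, "s2")):
        rec.append({"compound_id": "replicate_concordant", "smiles": chain(17),
                    "index_type": "IC50", "value": v, "concentration": None,
                    "outcome": None, "source_id": src})
    exp.append({"compound_id": "replicate_concordant",
                "expected_disposition": "inhibitor", "expected_label": 1})
    # discrepant replicates: ratio 20 > 10 -> removed
    for v, src in ((2.0, "s1"), (40.0, "s2")):
        rec.append({"compound_id": "replicate_discrepant", "smiles": chain(18),
                    "index_type": "IC50", "value": v, "concentration": None,
                    "outcome": None, "source_id": src})
    exp.append({"compound_id": "replicate_discrepant",
                "expected_disposition": "removed", "expected_label": None})

    # duplicated structure with conflicting labels: all copies removed
    add("dup_conflict_a", "c1ccc2ncncc2c1", "IC50", 5.0)
    exp[-1].update(expected_disposition="removed", expected_label=None)
    add("dup_conflict_b", "c1ccc2ncncc2c1", "IC50", 100.0)
    exp[-1].update(expected_disposition="removed", expected_label=None)
    # duplicated structure with concordant labels: collapses to one entry;
    # both ids expect label 1, exactly one survives (structure-level check)
    add("dup_concordant_a", "c1ccncc1", "IC50", 3.0,
        disposition="inhibitor", label=1)
    add("dup_concordant_b", "c1ccncc1", "IC50", 4.0,
        disposition="inhibitor", label=1)

    # structure-standardization branches
    add("salt_form", "[Cl-].CCCC[NH3+]", "IC50", 2.0,
        disposition="inhibitor", label=1)
    add("metal_organic", "CC[Sn](CC)CC", "IC50", 2.0)
    add("mixture", "c1ccccc1.C1CCCCC1", "IC50", 2.0)
    add("unparseable", "C1CC", "IC50", 2.0)

    records = pd.DataFrame(rec)
    expected = pd.DataFrame(exp)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    records = records.iloc[order].reset_index(drop=True)
    return records, expected
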