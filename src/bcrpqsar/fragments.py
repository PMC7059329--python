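"""Fragment decomposition and class-enrichment statistics.

Each compound is decomposed into three kinds of ring-derived fragments:

* ring assemblies — maximal contiguous ring systems (connected components
  of the ring-bond subgraph, with exocyclic double-bonded atoms retained);
* bridge assemblies — ring assemblies in which two rings share two or more
  bonds;
* Bemis–Murcko assemblies — the ring-plus-linker scaffold of compounds
  containing at least two ring systems.

Fragment importance is scored by information gain (base-2 entropy reduction
from conditioning the inhibitor / non-inhibitor split on fragment presence)
and by per-class frequency enrichment: a fragment with class frequency > 1
is over-represented in that class relative to the whole dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

__all__ = [
    "FragmentRecord",
    "decompose",
    "class_frequency",
    "information_gain",
    "entropy",
    "fragment_table",
    "rank_fragments",
    "misclassification_enrichment",
]

RING_ASSEMBLY = "ring_assembly"
BRIDGE_ASSEMBLY = "bridge_assembly"
BEMIS_MURCKO = "bemis_murcko_assembly"


@dataclass(frozen=True)
class FragmentRecord:
    fragment_smiles: str
    fragment_kind: str
    count_inhibitor: int
    count_noninhibitor: int
    F1: float
    F2: float
    IG: float


def _mol_from(compound):
    if isinstance(compound, Chem.Mol):
        return compound
    mol = Chem.MolFromSmiles(compound)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {compound!r}")
    return mol


def _ring_components(mol) -> list[set[int]]:
    """Connected components of the ring-bond subgraph, as atom-index sets."""
    ring_bonds = [b for b in mol.GetBonds() if b.IsInRing()]
    adj: dict[int, set[int]] = {}
    for b in ring_bonds:
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    seen: set[int] = set()
    comps = []
    for a in adj:
        if a in seen:
            continue
        stack, comp = [a], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def _submol_smiles(mol, atoms: set[int]) -> str:
    """Canonical SMILES of the substructure induced by ``atoms`` plus any
    exocyclic double-bonded partner atoms (e.g. ring carbonyl oxygens)."""
    keep = set(atoms)
    for b in mol.GetBonds():
        if b.GetBondType() == Chem.BondType.DOUBLE and not b.IsInRing():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in atoms and j not in atoms:
                keep.add(j)
            elif j in atoms and i not in atoms:
                keep.add(i)
    bond_ids = [
        b.GetIdx() for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in keep and b.GetEndAtomIdx() in keep
    ]
    sub = Chem.PathToSubmol(mol, bond_ids)
    smi = Chem.MolToSmiles(sub)
    # re-canonicalize through a fresh parse for stability
    m2 = Chem.MolFromSmiles(smi)
    return Chem.MolToSmiles(m2) if m2 is not None else smi


def _is_bridge(mol, comp: set[int]) -> bool:
    """True when two SSSR rings inside this component share >= 2 bonds."""
    bond_rings = mol.GetRingInfo().BondRings()
    rings_here = [
        frozenset(br) for br in bond_rings
        if all(mol.GetBondWithIdx(b).GetBeginAtomIdx() in comp for b in br)
    ]
    for i in range(len(rings_here)):
        for j in range(i + 1, len(rings_here)):
            if len(rings_here[i] & rings_here[j]) >= 2:
                return True
    return False


def decompose(compound) -> set[tuple[str, str]]:
    """Decompose one compound into (fragment_smiles, fragment_kind) pairs.

    Acyclic compounds yield the empty set. Presence is binary: a fragment
    occurring twice in one molecule is reported once.
    """
    mol = _mol_from(compound)
    comps = _ring_components(mol)
    out: set[tuple[str, str]] = set()
    for comp in comps:
        smi = _submol_smiles(mol, comp)
        if not smi:
            continue
        out.add((smi, RING_ASSEMBLY))
        if _is_bridge(mol, comp):
            out.add((smi, BRIDGE_ASSEMBLY))
    if len(comps) >= 2:
        scaffold = MurckoScaffold.GetScaffoldForMol(mol)
        if scaffold is not None and scaffold.GetNumAtoms() > 0:
            smi = Chem.MolToSmiles(scaffold)
            if smi:
                out.add((smi, BEMIS_MURCKO))
    return out


def entropy(counts) -> float:
    """Shannon entropy in bits of a discrete distribution given by counts."""
    n = sum(counts)
    if n == 0:
        raise ValueError("entropy of an empty partition")
    return -sum(c / n * math.log2(c / n) for c in counts if c > 0)


def class_frequency(count_in_class: int, class_size: int,
                    fragment_total_count: int, dataset_total: int) -> float:
    """Enrichment frequency of a fragment within one class.

    frequency = (N_fragment_class * N_total) / (N_fragment_total * N_class);
    a value above 1 means the fragment is enriched in that class.
    """
    if fragment_total_count == 0:
        raise ValueError("fragment occurs nowhere in the dataset")
    if not (0 <= count_in_class <= fragment_total_count <= dataset_total):
        raise ValueError("inconsistent fragment counts")
    if class_size <= 0 or class_size > dataset_total:
        raise ValueError("invalid class size")
    return count_in_class * dataset_total / (fragment_total_count * class_size)


def information_gain(count_inhibitor: int, count_noninhibitor: int,
                     n_inhibitors: int, n_noninhibitors: int) -> float:
    """Information gain (bits) of conditioning the class split on presence.

    IG = Ent(D) - sum_v (N_v / N) Ent(D_v) over the present / absent
    partitions, with 0·log2(0) taken as 0.
    """
    if count_inhibitor > n_inhibitors or count_noninhibitor > n_noninhibitors:
        raise ValueError("fragment count exceeds class size")
    n = n_inhibitors + n_noninhibitors
    if n == 0:
        raise ValueError("empty dataset")
    present = count_inhibitor + count_noninhibitor
    absent_i = n_inhibitors - count_inhibitor
    absent_n = n_noninhibitors - count_noninhibitor
    ig = entropy([n_inhibitors, n_noninhibitors])
    if present > 0:
        ig -= present / n * entropy([count_inhibitor, count_noninhibitor])
    if present < n:
        ig -= (n - present) / n * entropy([absent_i, absent_n])
    # clamp tiny negative float error
    return max(ig, 0.0)


def fragment_table(compounds, labels) -> pd.DataFrame:
    """Per-fragment class counts, frequencies and information gain.

    Counts are numbers of compounds containing the fragment (presence, not
    multiplicity); records with identical (fragment, kind) are merged.
    """
    labels = list(labels)
    n1 = sum(1 for y in labels if y == 1)
    n0 = len(labels) - n1
    counts: dict[tuple[str, str], list[int]] = {}
    for compound, y in zip(compounds, labels, strict=True):
        for frag in decompose(compound):
            c = counts.setdefault(frag, [0, 0])
            c[1 if y == 1 else 0] += 1
    rows = []
    total = n1 + n0
    for (smi, kind), (c0, c1) in sorted(counts.items()):
        ftot = c0 + c1
        rows.append({
            "fragment_smiles": smi,
            "fragment_kind": kind,
            "count_inhibitor": c1,
            "count_noninhibitor": c0,
            "F1": class_frequency(c1, n1, ftot, total) if n1 else float("nan"),
            "F2": class_frequency(c0, n0, ftot, total) if n0 else float("nan"),
            "IG": information_gain(c1, c0, n1, n0),
        })
    df = pd.DataFrame(rows, columns=["fragment_smiles", "fragment_kind",
                                     "count_inhibitor", "count_noninhibitor",
                                     "F1", "F2", "IG"])
    return df.sort_values("IG", ascending=False, kind="stable").reset_index(drop=True)


def rank_fragments(table: pd.DataFrame, top_n: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into inhibitor-enriched (F1 > F2) and non-inhibitor-enriched
    (F2 > F1) lists, each sorted by information gain descending and truncated
    to ``top_n``. Ties F1 == F2 belong to neither list."""
    pos = table[table["F1"] > table["F2"]]
    neg = table[table["F2"] > table["F1"]]
    pos = pos.sort_values("IG", ascending=False, kind="stable").head(top_n)
    neg = neg.sort_values("IG", ascending=False, kind="stable").head(top_n)
    return pos.reset_index(drop=True), neg.reset_index(drop=True)


def _presence_counts(compounds) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for c in compounds:
        for frag in decompose(c):
            counts[frag] = counts.get(frag, 0) + 1
    return counts


def misclassification_enrichment(train_set, test_set, misclassified_set,
                                 min_misclassified: int = 2) -> pd.DataFrame:
    """Occurrence ratios of fragments over-represented among misclassified
    test compounds.

    Fragments appearing in at least ``min_misclassified`` misclassified
    compounds are kept; the occurrence ratio in each set is
    100 * (compounds containing the fragment) / (set size).
    """
    train_set, test_set = list(train_set), list(test_set)
    mis = list(misclassified_set)
    if not mis:
        return pd.DataFrame(columns=["fragment_smiles", "fragment_kind",
                                     "count_train", "count_test", "count_misclassified",
                                     "or_train", "or_test", "or_misclassified"])
    c_train = _presence_counts(train_set)
    c_test = _presence_counts(test_set)
    c_mis = _presence_counts(mis)
    rows = []
    for frag, cm in sorted(c_mis.items()):
        if cm < min_misclassified:
            continue
        smi, kind = frag
        rows.append({
            "fragment_smiles": smi,
            "fragment_kind": kind,
            "count_train": c_train.get(frag, 0),
            "count_test": c_test.get(frag, 0),
            "count_misclassified": cm,
            "or_train": 100.0 * c_train.get(frag, 0) / len(train_set),
            "or_test": 100.0 * c_test.get(frag, 0) / len(test_set),
            "or_misclassified": 100.0 * cm / len(mis),
        })
    return pd.DataFrame(rows).reset_index(drop=True)
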