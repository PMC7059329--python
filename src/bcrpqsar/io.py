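"""File adapters: SMILES CSV, SDF, and typed table round-trips."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from rdkit import Chem

__all__ = ["read_smiles_csv", "write_smiles_csv", "read_sdf",
           "read_activity_csv", "write_json", "read_json"]


def read_smiles_csv(path, smiles_col: str = "smiles") -> tuple[pd.DataFrame, int]:
    """Load a compound CSV, canonicalizing structures.

    Malformed SMILES rows are skipped; returns the clean frame and the
    number of skipped rows. An empty input raises.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"no compounds in {path}")
    keep, skipped = [], 0
    for i, smi in enumerate(df[smiles_col]):
        mol = Chem.MolFromSmiles(str(smi))
        if mol is None:
            skipped += 1
            continue
        keep.append((i, Chem.MolToSmiles(mol)))
    out = df.iloc[[i for i, _ in keep]].copy()
    out[smiles_col] = [s for _, s in keep]
    return out.reset_index(drop=True), skipped


def write_smiles_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_sdf(path) -> pd.DataFrame:
    """Load structures from an SDF; returns (id, smiles) with bad records skipped."""
    rows = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_{i}"
        rows.append({"id": name or f"sdf_{i}", "smiles": Chem.MolToSmiles(mol)})
    if not rows:
        raise ValueError(f"no compounds in {path}")
    return pd.DataFrame(rows)


def read_activity_csv(path) -> pd.DataFrame:
    """Load an activity-record table, checking the required columns."""
    df = pd.read_csv(path)
    required = {"compound_id", "smiles", "index_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity CSV missing columns: {sorted(missing)}")
    for col in ("value", "concentration", "outcome", "source_id"):
        if col not in df.columns:
            df[col] = None
    return df


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
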