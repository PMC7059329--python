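"""Curation of heterogeneous activity records into binary inhibition labels.

The decision rules convert IC50/EC50 values (μM), %inhibition at 10 μM, and
qualitative assay outcomes into inhibitor (1) / non-inhibitor (0) classes:

* IC50 or EC50 < 10 μM → inhibitor; > 50 μM → non-inhibitor; values in the
  [10, 50] window are excluded as assay-condition sensitive.
* %inhibition is used only when measured at 10 μM: > 50% → inhibitor,
  < 25% → non-inhibitor, the [25, 50] window excluded.
* Qualitative outcomes: Active → inhibitor, Inactive → non-inhibitor,
  Inconclusive / Unspecified → removed.

Replicated IC50/EC50 measurements are arithmetically averaged before
thresholding; a compound whose replicates disagree by more than a factor of
10 (max/min) is excluded. Structures are standardized by counter-ion
stripping; mixtures and metal-organics are rejected. Structure-identical
compounds with conflicting labels are removed entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "ActivityRecord",
    "LabeledCompound",
    "StandardizationError",
    "standardize_structure",
    "assign_label",
    "aggregate_replicates",
    "deduplicate",
    "curate",
]

EXCLUDED = "excluded"

# elements admitted in an "organic" component; anything else is a metal
# or metalloid and triggers rejection
_ORGANIC_ELEMENTS = {
    "H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I",
}

# common counter-ions stripped before the mixture test (canonical SMILES)
_COUNTER_IONS = {
    "[Na+]", "[K+]", "[Li+]", "[Ca+2]", "[Mg+2]", "[Cl-]", "[Br-]", "[I-]",
    "[F-]", "O", "[NH4+]", "[OH-]", "[H+]",
    "O=S(=O)([O-])[O-]", "O=S(=O)([O-])O", "O=[N+]([O-])[O-]",
    "O=C([O-])O", "O=C([O-])[O-]", "O=P([O-])([O-])[O-]",
    "CC(=O)[O-]", "CC(=O)O", "O=C(O)C(=O)O", "O=C([O-])C(=O)[O-]",
    "CS(=O)(=O)O", "CS(=O)(=O)[O-]", "O=C(O)/C=C/C(=O)O", "OCC(O)C(O)C(O)C(O)CO",
}


class Disposition(str, Enum):
    INHIBITOR = "inhibitor"
    NON_INHIBITOR = "non_inhibitor"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class ActivityRecord:
    """One experimental measurement of one compound."""

    compound_id: str
    smiles: str
    index_type: str  # IC50 | EC50 | percent_inhibition | qualitative
    value: float | None = None
    concentration: float | None = None  # μM, for percent_inhibition
    outcome: str | None = None  # Active | Inactive | Inconclusive | Unspecified
    source_id: str = ""

    def __post_init__(self):
        if self.index_type in ("IC50", "EC50") and self.value is not None and self.value <= 0:
            raise ValueError("IC50/EC50 values must be positive")
        if self.index_type == "percent_inhibition" and self.concentration is None:
            raise ValueError("percent_inhibition records must carry a concentration")


@dataclass(frozen=True)
class LabeledCompound:
    compound_id: str
    canonical_smiles: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


class StandardizationError(ValueError):
    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


def _has_metal(mol) -> bool:
    return any(a.GetSymbol() not in _ORGANIC_ELEMENTS for a in mol.GetAtoms())


def standardize_structure(smiles: str) -> str:
    """Canonicalize one structure; strip salts; reject mixtures and metals.

    Counter-ions from a fixed list are removed first. If exactly one organic
    component remains, it is returned canonicalized; several remaining
    components constitute a true mixture and are rejected; a metal anywhere
    in the retained structure is rejected.

    Raises :class:`StandardizationError` with ``reason`` in
    {"parse", "metal", "mixture", "empty"}.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError("parse", smiles)
    frags = Chem.GetMolFrags(mol, asMols=True)
    organic = []
    for f in frags:
        smi = Chem.MolToSmiles(f)
        if smi in _COUNTER_IONS:
            continue
        organic.append(f)
    if not organic:
        raise StandardizationError("empty", smiles)
    if len(organic) > 1:
        # all-identical components collapse (e.g. dimeric salt entries)
        smis = {Chem.MolToSmiles(f) for f in organic}
        if len(smis) > 1:
            raise StandardizationError("mixture", smiles)
        organic = organic[:1]
    kept = organic[0]
    if _has_metal(kept):
        raise StandardizationError("metal", smiles)
    return Chem.MolToSmiles(kept)


def assign_label(record: ActivityRecord) -> int | str:
    """Label one record: 1 (inhibitor), 0 (non-inhibitor), or "excluded".

    Thresholds are strict inequalities; boundary values fall into the
    excluded windows.
    """
    it = record.index_type
    if it in ("IC50", "EC50"):
        v = record.value
        if v is None:
            raise ValueError("IC50/EC50 record without a value")
        if v < 10.0:
            return 1
        if v > 50.0:
            return 0
        return EXCLUDED
    if it == "percent_inhibition":
        if record.concentration != 10.0:
            return EXCLUDED
        v = record.value
        if v is None:
            raise ValueError("percent_inhibition record without a value")
        if v > 50.0:
            return 1
        if v < 25.0:
            return 0
        return EXCLUDED
    if it == "qualitative":
        outcome = (record.outcome or "").strip()
        if outcome == "Active":
            return 1
        if outcome == "Inactive":
            return 0
        return EXCLUDED
    raise ValueError(f"unknown index_type: {it!r}")


def aggregate_replicates(records: list[ActivityRecord],
                         max_ratio: float = 10.0) -> ActivityRecord | str:
    """Average replicate IC50/EC50 measurements of one compound.

    Single records pass through unchanged. Replicates are averaged
    arithmetically on the μM scale; if max/min exceeds ``max_ratio`` the
    discrepancy is considered significant and the compound is excluded.
    """
    if not records:
        raise ValueError("no records to aggregate")
    if len(records) == 1:
        return records[0]
    types = {r.index_type for r in records}
    if len(types) > 1:
        raise ValueError(f"mixed index types in replicate set: {types}")
    it = types.pop()
    if it not in ("IC50", "EC50"):
        raise ValueError("replicate averaging applies to IC50/EC50 records only")
    values = [r.value for r in records]
    if min(values) > 0 and max(values) / min(values) > max_ratio:
        return EXCLUDED
    first = records[0]
    return ActivityRecord(
        compound_id=first.compound_id, smiles=first.smiles, index_type=it,
        value=float(np.mean(values)), source_id=first.source_id,
    )


def deduplicate(compounds: list[LabeledCompound]) -> list[LabeledCompound]:
    """Collapse structure-identical entries; drop all copies on label conflict."""
    by_smiles: dict[str, list[LabeledCompound]] = {}
    order: list[str] = []
    for c in compounds:
        if c.canonical_smiles not in by_smiles:
            order.append(c.canonical_smiles)
        by_smiles.setdefault(c.canonical_smiles, []).append(c)
    out = []
    for smi in order:
        labels = {c.label for c in by_smiles[smi]}
        if len(labels) == 1:
            out.append(by_smiles[smi][0])
    return out


def _records_from_frame(df: pd.DataFrame) -> list[ActivityRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(ActivityRecord(
            compound_id=str(row.compound_id),
            smiles=row.smiles,
            index_type=row.index_type,
            value=None if pd.isna(getattr(row, "value", None)) else float(row.value),
            concentration=(None if pd.isna(getattr(row, "concentration", None))
                           else float(row.concentration)),
            outcome=(None if pd.isna(getattr(row, "outcome", None))
                     else str(row.outcome)),
            source_id=str(getattr(row, "source_id", "")),
        ))
    return records


def curate(records, max_ratio: float = 10.0,
           quantitative_precedence: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full curation pipeline on an activity-record table.

    Parameters
    ----------
    records : DataFrame or list of ActivityRecord
        Columns: compound_id, smiles, index_type, value, concentration,
        outcome, source_id.
    max_ratio : float
        Replicate max/min discrepancy threshold for exclusion.
    quantitative_precedence : bool
        When a compound carries both quantitative (IC50/EC50, %inhibition)
        and qualitative evidence, the quantitative rule decides.

    Returns
    -------
    (dataset, rejects)
        ``dataset``: DataFrame (compound_id, canonical_smiles, label) with
        no duplicated structure. ``rejects``: DataFrame (compound_id,
        reason) for everything removed, with the curation-rule branch named.
    """
    if isinstance(records, pd.DataFrame):
        records = _records_from_frame(records)

    rejects: list[dict] = []
    by_compound: dict[str, list[ActivityRecord]] = {}
    for r in records:
        by_compound.setdefault(r.compound_id, []).append(r)

    labeled: list[LabeledCompound] = []
    for cid, recs in by_compound.items():
        try:
            canonical = standardize_structure(recs[0].smiles)
        except StandardizationError as e:
            rejects.append({"compound_id": cid, "reason": f"structure:{e.reason}"})
            continue

        quantitative = [r for r in recs if r.index_type in ("IC50", "EC50")]
        percent = [r for r in recs if r.index_type == "percent_inhibition"]
        qualitative = [r for r in recs if r.index_type == "qualitative"]

        label: int | str = EXCLUDED
        if quantitative:
            agg = aggregate_replicates(quantitative, max_ratio=max_ratio)
            if agg == EXCLUDED:
                rejects.append({"compound_id": cid, "reason": "replicate_discrepancy"})
                continue
            label = assign_label(agg)
        elif percent:
            label = assign_label(percent[0])
        if label == EXCLUDED and qualitative:
            has_quantitative = bool(quantitative or percent)
            if not (has_quantitative and quantitative_precedence):
                for q in qualitative:
                    label = assign_label(q)
                    if label != EXCLUDED:
                        break
        if label == EXCLUDED:
            rejects.append({"compound_id": cid, "reason": "label_excluded"})
            continue
        labeled.append(LabeledCompound(cid, canonical, int(label)))

    deduped = deduplicate(labeled)
    kept_ids = {c.compound_id for c in deduped}
    conflict_smiles = set()
    seen: dict[str, int] = {}
    for c in labeled:
        if c.canonical_smiles in seen and seen[c.canonical_smiles] != c.label:
            conflict_smiles.add(c.canonical_smiles)
        seen[c.canonical_smiles] = c.label
    for c in labeled:
        if c.compound_id not in kept_ids:
            reason = ("duplicate_conflict" if c.canonical_smiles in conflict_smiles
                      else "duplicate_collapsed")
            rejects.append({"compound_id": c.compound_id, "reason": reason})

    dataset = pd.DataFrame(
        [{"compound_id": c.compound_id, "canonical_smiles": c.canonical_smiles,
          "label": c.label} for c in deduped],
        columns=["compound_id", "canonical_smiles", "label"],
    )
    rejects_df = pd.DataFrame(rejects, columns=["compound_id", "reason"])
    return dataset, rejects_df
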