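"""Reading and writing the interaction-record TSV dialect.

Dataset files are UTF-8 TSV with header ``smiles	sequence	label``
plus optional ``drug_id`` / ``protein_id`` columns; labels are 0/1.
"""

from __future__ import annotations

import json

import pandas as pd

from .model import InteractionRecord

REQUIRED_COLUMNS = ("smiles", "sequence", "label")


def records_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "smiles": [r.smiles for r in records],
        "sequence": [r.sequence for r in records],
        "label": [r.label for r in records],
        "drug_id": [r.drug_id for r in records],
        "protein_id": [r.protein_id for r in records],
    })


def write_interactions(records: list[InteractionRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_interactions(path: str) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"smiles": str, "sequence": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    if not df["label"].isin((0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    has_ids = "drug_id" in df.columns and "protein_id" in df.columns
    return [
        InteractionRecord(
            smiles=row.smiles, sequence=row.sequence, label=int(row.label),
            drug_id=str(row.drug_id) if has_ids else "",
            protein_id=str(row.protein_id) if has_ids else "")
        for row in df.itertuples()
    ]


def write_manifest(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
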