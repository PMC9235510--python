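"""Readers for the tabular molecule formats the pipeline consumes."""

from __future__ import annotations

import warnings

import pandas as pd
from rdkit import Chem

from .chem import InvalidMoleculeError, Molecule, parse_smiles


def read_molecules_csv(path, strict: bool = False, sep: str | None = None) -> list[Molecule]:
    """Read a CSV/TSV with header columns (id, smiles, ...).

    Invalid SMILES are skipped with a warning by default; ``strict=True``
    raises on the first invalid row instead.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols:
        raise ValueError(f"{path}: no 'smiles' column")
    id_col = cols.get("id")
    out: list[Molecule] = []
    for i, row in enumerate(df.itertuples(index=False)):
        smiles = getattr(row, cols["smiles"])
        mol_id = getattr(row, id_col) if id_col else f"row{i}"
        try:
            out.append(parse_smiles(smiles, id=str(mol_id)))
        except InvalidMoleculeError:
            if strict:
                raise
            warnings.warn(f"skipping invalid SMILES for id {mol_id!r}: {smiles!r}")
    return out


def read_molecules_sdf(path, strict: bool = False) -> list[Molecule]:
    """Read an SDF file, mapping the title line to the molecule id."""
    out: list[Molecule] = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            if strict:
                raise InvalidMoleculeError(f"record {i} in {path}")
            warnings.warn(f"skipping unparsable SDF record {i} in {path}")
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i}"
        out.append(parse_smiles(Chem.MolToSmiles(mol), id=mol_id))
    return out


def read_binary_labels_csv(path, label_column: str) -> pd.DataFrame:
    """Read (id, smiles, <label_column>) rows with 0/1 labels."""
    df = pd.read_csv(path, dtype={"id": str})
    if label_column not in df.columns:
        raise ValueError(f"{path}: no {label_column!r} column")
    if not set(df[label_column].unique()).issubset({0, 1}):
        raise ValueError(f"{path}: {label_column!r} must be binary 0/1")
    return df
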