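"""Dataset I/O for molecular property regression benchmarks.

Reads CSV files of (SMILES, scalar target) pairs in the column dialects
used by the MoleculeNet benchmark sets (ESOL, FreeSolv, Lipophilicity,
BACE) or any user-supplied CSV with a SMILES column and a numeric target
column.

The raw SMILES string is the node-ordering authority for the whole
pipeline (graph node i is the i-th atom token of the string), so the
loader never canonicalizes, re-writes, or otherwise touches the SMILES
text: records carry it byte-identical to the file cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from rdkit import Chem

logger = logging.getLogger("molgat")

__all__ = [
    "MoleculeRecord",
    "DatasetDialect",
    "DIALECTS",
    "load_dataset",
    "save_dataset",
    "drop_failed_geometry",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """One dataset row: raw SMILES, scalar target, provenance.

    Target units are whatever the source dataset uses (log mol/L for
    ESOL, kcal/mol for FreeSolv, logD for Lipophilicity, pIC50 for BACE).
    """

    smiles: str
    target: float
    source_row: int = 0
    dataset_name: str = "generic"


@dataclass(frozen=True)
class DatasetDialect:
    """Column naming convention of a benchmark CSV."""

    name: str
    smiles_column: str
    target_column: str


#: Built-in column dialects for the MoleculeNet CSV distributions.
DIALECTS: dict[str, DatasetDialect] = {
    "esol": DatasetDialect(
        "esol", "smiles", "measured log solubility in mols per litre"
    ),
    "freesolv": DatasetDialect("freesolv", "smiles", "expt"),
    "lipophilicity": DatasetDialect("lipophilicity", "smiles", "exp"),
    "bace": DatasetDialect("bace", "mol", "pIC50"),
    "generic": DatasetDialect("generic", "smiles", "target"),
}


def load_dataset(
    path: str | Path, dialect: DatasetDialect | str = "generic"
) -> tuple[list[MoleculeRecord], int]:
    """Load a CSV of (SMILES, target) pairs.

    Rows whose SMILES fails to parse (to a molecule with at least one
    heavy atom) or whose target is missing or non-numeric are dropped
    with a warning; the second return value counts them.  Surviving
    records keep file order and raw SMILES text.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    KeyError
        If a configured column is missing from the header.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    # keep_default_na=False so SMILES like "NaN"-ish strings survive as text
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (dialect.smiles_column, dialect.target_column):
        if col not in df.columns:
            raise KeyError(
                f"column {col!r} not in header of {path} "
                f"(columns: {list(df.columns)})"
            )
    smiles_col = df[dialect.smiles_column].tolist()
    target_col = df[dialect.target_column].tolist()
    records: list[MoleculeRecord] = []
    dropped = 0
    for i, (smiles, raw_target) in enumerate(zip(smiles_col, target_col)):
        try:
            target = float(raw_target)
        except (TypeError, ValueError):
            target = math.nan
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None or mol.GetNumAtoms() == 0 or not math.isfinite(target):
            dropped += 1
            logger.warning("dropping row %d of %s: smiles=%r target=%r",
                           i, path.name, smiles, raw_target)
            continue
        records.append(
            MoleculeRecord(smiles, target, source_row=i, dataset_name=dialect.name)
        )
    if dropped:
        logger.warning("%s: dropped %d of %d rows", path.name, dropped, len(df))
    return records, dropped


def save_dataset(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write records as a generic-dialect CSV with columns smiles,target."""
    df = pd.DataFrame(
        {"smiles": [r.smiles for r in records],
         "target": [r.target for r in records]}
    )
    df.to_csv(path, index=False)


def drop_failed_geometry(
    records: list[MoleculeRecord], failures: list[int]
) -> list[MoleculeRecord]:
    """Remove records whose 3D featurization failed, preserving order.

    ``failures`` are positions into ``records`` (as produced by the
    featurizer when conformer embedding or charge assignment fails).
    Each removal is logged with its SMILES so the benchmark filtering is
    auditable.
    """
    bad = set(failures)
    for i in bad:
        if not 0 <= i < len(records):
            raise IndexError(f"failure index {i} out of range for {len(records)} records")
        logger.warning("removing molecule with failed geometry: %s",
                       records[i].smiles)
    return [r for i, r in enumerate(records) if i not in bad]
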