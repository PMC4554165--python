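"""Readers/writers for the package's plain-text interchange formats.

Formats
-------
Expression TSV
    UTF-8, tab-separated; header row ``mirna_id<TAB><array ids...>``,
    one row per miRNA, decimal point, no thousands separators. Used for
    both raw intensities and normalized log2 matrices.
Sample sheet CSV
    Header ``array_id,patient_id,condition``; condition is the literal
    string ``scar`` or ``normal``. Defines the paired design.
Ground-truth JSON
    ``{"de": [{"id": ..., "log2_effect": ...}, ...], "seed": ...}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import DesignError, InputError

CONDITIONS = ("scar", "normal")


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a miRNAs x arrays matrix as TSV with an ``mirna_id`` column."""
    matrix.to_csv(path, sep="\t", index_label="mirna_id")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV into a DataFrame indexed by miRNA id."""
    matrix = pd.read_csv(path, sep="\t", index_col="mirna_id")
    validate_matrix(matrix)
    return matrix


def validate_matrix(matrix: pd.DataFrame) -> None:
    """Check the id discipline shared by raw and normalized matrices."""
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate miRNA ids: {dupes[:5]}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise InputError(f"duplicate array ids: {dupes[:5]}")
    non_numeric = [c for c in matrix.columns
                   if not pd.api.types.is_numeric_dtype(matrix[c])]
    if non_numeric:
        raise InputError(f"non-numeric columns: {non_numeric[:5]}")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV and validate its column contract."""
    sheet = pd.read_csv(path, dtype=str)
    required = {"array_id", "patient_id", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise InputError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(sheet["condition"]) - set(CONDITIONS)
    if bad:
        raise InputError(f"unknown condition values: {sorted(bad)}")
    return sheet


def paired_arrays(sheet: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Resolve the paired design: one row per patient with scar/normal arrays.

    Parameters
    ----------
    sheet
        Sample sheet with ``array_id``, ``patient_id``, ``condition``.
    columns
        If given, the matrix columns the sheet must cover exactly.

    Returns
    -------
    DataFrame indexed by ``patient_id`` with columns ``scar`` and
    ``normal`` holding array ids, sorted by patient id.

    Raises
    ------
    DesignError
        If any patient lacks exactly one scar and one normal array, or
        the arrays do not match ``columns``.
    """
    if sheet["array_id"].duplicated().any():
        raise DesignError("duplicate array_id entries in sample sheet")
    if columns is not None:
        sheet_arrays = set(sheet["array_id"])
        matrix_arrays = set(map(str, columns))
        if sheet_arrays != matrix_arrays:
            only_sheet = sorted(sheet_arrays - matrix_arrays)
            only_matrix = sorted(matrix_arrays - sheet_arrays)
            raise DesignError(
                "sample sheet and matrix arrays differ: "
                f"sheet-only={only_sheet[:5]}, matrix-only={only_matrix[:5]}")
    wide = sheet.pivot_table(index="patient_id", columns="condition",
                             values="array_id", aggfunc=list)
    unpaired = []
    for patient, row in wide.iterrows():
        for cond in CONDITIONS:
            arrays = row.get(cond)
            if not isinstance(arrays, list) or len(arrays) != 1:
                unpaired.append(str(patient))
                break
    if unpaired:
        raise DesignError(f"incomplete pairing for patients: {unpaired}")
    pairs = pd.DataFrame({cond: [row[cond][0] for _, row in wide.iterrows()]
                          for cond in CONDITIONS},
                         index=wide.index)
    return pairs.sort_index()


def write_ground_truth(truth, path: str | Path) -> None:
    payload = {
        "de": [{"id": mid, "log2_effect": float(truth.effect_per_id[mid])}
               for mid in sorted(truth.de_ids)],
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_ground_truth(path: str | Path):
    from .simulate import GroundTruth  # avoid import cycle

    payload = json.loads(Path(path).read_text())
    effects = {rec["id"]: float(rec["log2_effect"]) for rec in payload["de"]}
    return GroundTruth(de_ids=frozenset(effects), effect_per_id=effects,
                       seed=payload.get("seed"))
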