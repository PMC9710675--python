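"""Long-format data model and I/O shared by every analysis stage.

The canonical in-memory container is a :class:`pandas.DataFrame` in long
format with one row per measured feature intensity and the fixed column
set :data:`CANONICAL_COLUMNS`.  All downstream math operates on the log2
scale; the single authoritative intensity column is ``intensity_log2``.
Raw (linear) intensities are recovered as ``2**intensity_log2`` where a
metric is only meaningful on the linear scale.

Search-engine exports (Spectronaut, MaxQuant, Skyline, DIA-NN, Proteome
Discoverer ...) are consumed through a :class:`ColumnMap` that assigns
export columns to the canonical roles.  Dialect presets cover the common
Spectronaut and MaxQuant long exports; anything else goes through the
``generic`` dialect with an explicit mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Fixed column order of the canonical long-format table (on disk and in memory).
CANONICAL_COLUMNS = [
    "sample",
    "condition",
    "replicate",
    "protein",
    "peptide",
    "precursor",
    "intensity_log2",
    "dose",
]

#: Roles a column map may assign.  sample/condition/protein/intensity are mandatory.
ROLES = ("sample", "condition", "replicate", "protein", "peptide", "precursor", "intensity", "dose")
REQUIRED_ROLES = ("sample", "condition", "protein", "intensity")

LEVELS = ("protein", "peptide", "precursor")


class ColumnMapError(ValueError):
    """A column map is incomplete or does not match the file header."""


@dataclass
class ColumnMap:
    """Assignment of source-file columns to canonical roles.

    Parameters
    ----------
    roles:
        Mapping from role name (see :data:`ROLES`) to the column name in
        the source file.
    intensity_is_log:
        If True the mapped intensity column already holds log2 values.
    source_dialect:
        Informational tag; one of ``spectronaut``, ``maxquant``,
        ``skyline``, ``generic``.
    """

    roles: Mapping[str, str]
    intensity_is_log: bool = False
    source_dialect: str = "generic"

    def __post_init__(self) -> None:
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise ColumnMapError(f"unknown roles in column map: {sorted(unknown)}")
        missing = [r for r in REQUIRED_ROLES if r not in self.roles]
        if missing:
            raise ColumnMapError(
                "column map must cover roles " + ", ".join(REQUIRED_ROLES) + f"; missing: {missing}"
            )


#: Presets for common long-format exports.  MaxQuant evidence tables carry the
#: experiment name in "Experiment"; users habitually encode the condition there.
DIALECTS: dict[str, ColumnMap] = {
    "spectronaut": ColumnMap(
        roles={
            "sample": "R.FileName",
            "condition": "R.Condition",
            "replicate": "R.Replicate",
            "protein": "PG.ProteinGroups",
            "peptide": "PEP.StrippedSequence",
            "precursor": "EG.PrecursorId",
            "intensity": "FG.Quantity",
        },
        intensity_is_log=False,
        source_dialect="spectronaut",
    ),
    "maxquant": ColumnMap(
        roles={
            "sample": "Raw file",
            "condition": "Experiment",
            "protein": "Leading razor protein",
            "peptide": "Sequence",
            "intensity": "Intensity",
        },
        intensity_is_log=False,
        source_dialect="maxquant",
    ),
    "canonical": ColumnMap(
        roles={
            "sample": "sample",
            "condition": "condition",
            "replicate": "replicate",
            "protein": "protein",
            "peptide": "peptide",
            "precursor": "precursor",
            "intensity": "intensity_log2",
            "dose": "dose",
        },
        intensity_is_log=True,
        source_dialect="generic",
    ),
}


def make_precursor(peptide: str, charge: int | str) -> str:
    """Dialect-independent precursor key: peptide + "_" + charge."""
    return f"{peptide}_{charge}"


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_quant_table(
    path: str | Path,
    column_map: ColumnMap | None = None,
    dialect: str | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited export into the canonical long-format table.

    Non-numeric or non-positive intensities become missing (zero in
    search-engine exports denotes non-detection, not abundance zero).
    If the map lacks a replicate role, replicates are enumerated per
    condition in order of first appearance of each sample.

    Raises
    ------
    ColumnMapError
        If a mapped column is absent from the file header (the message
        names the role and column) or no usable map/dialect is given.
    ValueError
        If the file is empty.
    """
    path = Path(path)
    if column_map is None:
        if dialect is None or dialect not in DIALECTS:
            raise ColumnMapError(
                "no column map given; pass column_map= or dialect= one of "
                + ", ".join(sorted(DIALECTS))
            )
        column_map = DIALECTS[dialect]

    try:
        raw = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty input file: {path}") from exc
    if raw.empty:
        raise ValueError(f"input file has a header but no rows: {path}")

    for role, col in column_map.roles.items():
        if col not in raw.columns:
            raise ColumnMapError(f"mapped column for role '{role}' not in file: '{col}'")

    out = pd.DataFrame(index=raw.index)
    for role in ("sample", "condition", "protein", "peptide", "precursor"):
        col = column_map.roles.get(role)
        out[role] = raw[col] if col is not None else pd.Series(pd.NA, index=raw.index, dtype="object")

    intensity = pd.to_numeric(raw[column_map.roles["intensity"]], errors="coerce")
    if column_map.intensity_is_log:
        out["intensity_log2"] = intensity.astype(float)
    else:
        intensity = intensity.where(intensity > 0)
        out["intensity_log2"] = np.log2(intensity.astype(float))

    dose_col = column_map.roles.get("dose")
    out["dose"] = pd.to_numeric(raw[dose_col], errors="coerce") if dose_col else np.nan

    rep_col = column_map.roles.get("replicate")
    if rep_col is not None:
        out["replicate"] = pd.to_numeric(raw[rep_col], errors="coerce").astype("Int64")
    else:
        out["replicate"] = _enumerate_replicates(out)

    return out[CANONICAL_COLUMNS]


def _enumerate_replicates(table: pd.DataFrame) -> pd.Series:
    """Number samples 1..n within each condition, in order of appearance."""
    rep_of: dict[str, int] = {}
    seen_per_cond: dict[str, int] = {}
    for sample, cond in table[["sample", "condition"]].drop_duplicates().itertuples(index=False):
        seen_per_cond[cond] = seen_per_cond.get(cond, 0) + 1
        rep_of[sample] = seen_per_cond[cond]
    return table["sample"].map(rep_of).astype("Int64")


def write_quant_table(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write the canonical long format with fixed column order; missing as NA."""
    table = table.reindex(columns=CANONICAL_COLUMNS)
    table.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_canonical(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read back a table written by :func:`write_quant_table`."""
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=True, dtype=str)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ColumnMapError(f"canonical table lacks columns: {missing}")
    df["intensity_log2"] = pd.to_numeric(df["intensity_log2"], errors="coerce")
    df["dose"] = pd.to_numeric(df["dose"], errors="coerce")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    return df[CANONICAL_COLUMNS]


def validate_quant_table(table: pd.DataFrame) -> None:
    """Check the structural invariants of a canonical table."""
    missing = [c for c in CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks canonical columns: {missing}")
    if table["protein"].isna().any():
        raise ValueError("every record must have protein populated")
    bad = table["precursor"].notna() & table["peptide"].isna()
    if bad.any():
        raise ValueError("precursor implies peptide; offending rows: " + str(list(table.index[bad][:5])))


def to_matrix(table: pd.DataFrame, level: str = "protein") -> pd.DataFrame:
    """Pivot the long table to a features x samples matrix of log2 intensities.

    Parameters
    ----------
    level:
        Quantification level: ``protein``, ``peptide`` or ``precursor``.
        The corresponding ID column must be populated for all records.

    Returns
    -------
    DataFrame with one row per feature, one column per sample, NaN for
    unobserved cells.

    Raises
    ------
    ValueError
        If the level column has missing IDs, or the same (feature, sample)
        pair occurs twice (the message lists the first offending pair).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if table[level].isna().any():
        raise ValueError(f"level '{level}' requested but its ID column has missing values")

    dup = table.duplicated(subset=[level, "sample"], keep=False)
    if dup.any():
        first = table.loc[dup, [level, "sample"]].iloc[0]
        raise ValueError(
            f"duplicate observation for ({level}={first[level]!r}, sample={first['sample']!r}); "
            "aggregate or pick a finer level"
        )

    matrix = table.pivot(index=level, columns="sample", values="intensity_log2")
    matrix.index.name = level
    matrix.columns.name = "sample"
    return matrix


def matrix_to_triples(matrix: pd.DataFrame) -> set[tuple[str, str, float]]:
    """Flatten a matrix back to the set of observed (feature, sample, value) triples."""
    stacked = matrix.stack()
    return {(f, s, v) for (f, s), v in stacked.items()}


def sample_conditions(table: pd.DataFrame) -> pd.Series:
    """Map sample -> condition (errors if a sample has two conditions)."""
    pairs = table[["sample", "condition"]].drop_duplicates()
    if pairs["sample"].duplicated().any():
        bad = pairs[pairs["sample"].duplicated(keep=False)]["sample"].iloc[0]
        raise ValueError(f"sample {bad!r} is assigned to more than one condition")
    return pairs.set_index("sample")["condition"]
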