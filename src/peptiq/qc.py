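"""Quality-control metrics as plot-ready tables.

All metrics describe the data as measured: no imputation, no filtering.
CVs are computed on the linear intensity scale (sd/mean of raw
intensities), because a CV of log-transformed values has no scale
meaning; raw values are recovered as 2**log2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import to_matrix


def qc_cv(table: pd.DataFrame, level: str = "protein") -> pd.DataFrame:
    """Per-(feature, condition) coefficient of variation in percent.

    CV = sd(raw) / mean(raw) * 100 with sample (n-1) sd, over the
    non-missing replicate observations; cells with fewer than two
    observations are omitted.
    """
    df = table[[level, "condition", "intensity_log2"]].dropna(subset=[level, "intensity_log2"]).copy()
    df["raw"] = np.exp2(df["intensity_log2"])
    g = df.groupby([level, "condition"], sort=True)["raw"]
    out = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    out = out[out["n"] >= 2].copy()
    out["cv_percent"] = out["sd"] / out["mean"] * 100.0
    return out[[level, "condition", "n", "cv_percent"]].reset_index(drop=True)


def qc_completeness(table: pd.DataFrame, level: str = "protein") -> tuple[pd.DataFrame, float]:
    """Fraction of non-missing cells of the feature x sample grid.

    Returns (per-sample table, overall fraction).  The grid is the one
    induced by :func:`peptiq.io.to_matrix` at the requested level.
    """
    matrix = to_matrix(table, level)
    if matrix.size == 0:
        return pd.DataFrame(columns=["sample", "n_observed", "n_total", "completeness"]), float("nan")
    per_sample = pd.DataFrame({
        "sample": matrix.columns,
        "n_observed": matrix.notna().sum(axis=0).to_numpy(),
        "n_total": len(matrix.index),
    })
    per_sample["completeness"] = per_sample["n_observed"] / per_sample["n_total"]
    overall = float(matrix.notna().to_numpy().mean())
    return per_sample.reset_index(drop=True), overall


def qc_ids_per_sample(table: pd.DataFrame) -> pd.DataFrame:
    """Distinct protein/peptide/precursor IDs with an intensity, per sample."""
    obs = table.dropna(subset=["intensity_log2"])
    rows = []
    for sample, grp in obs.groupby("sample", sort=True):
        row = {"sample": sample}
        for lvl in ("protein", "peptide", "precursor"):
            ids = grp[lvl].dropna()
            row[f"n_{lvl}s"] = int(ids.nunique())
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample", "n_proteins", "n_peptides", "n_precursors"])


def qc_sample_correlation(matrix: pd.DataFrame, min_complete: int = 3) -> pd.DataFrame:
    """Pearson correlation between samples on pairwise-complete features.

    Pairs sharing fewer than ``min_complete`` complete features get a
    missing entry; the diagonal is 1 wherever a sample has any data.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples for a correlation matrix")
    return matrix.corr(method="pearson", min_periods=min_complete)


def qc_report(table: pd.DataFrame, level: str = "protein") -> dict[str, pd.DataFrame | float]:
    """Bundle of all QC metrics plus per-sample median/quartile intensities."""
    matrix = to_matrix(table, level)
    per_sample, overall = qc_completeness(table, level)
    quart = pd.DataFrame({
        "sample": matrix.columns,
        "q25_log2": matrix.quantile(0.25, axis=0).to_numpy(),
        "median_log2": matrix.median(axis=0).to_numpy(),
        "q75_log2": matrix.quantile(0.75, axis=0).to_numpy(),
    })
    return {
        "ids_per_sample": qc_ids_per_sample(table),
        "intensity_quartiles": quart.reset_index(drop=True),
        "cv": qc_cv(table, level),
        "completeness_per_sample": per_sample,
        "completeness_overall": overall,
        "sample_correlation": qc_sample_correlation(matrix) if matrix.shape[1] >= 2 else None,
    }
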