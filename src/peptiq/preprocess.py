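"""Normalization, observation filtering and MNAR imputation.

Median normalization corrects unequal sample loading by shifting every
sample's log2 intensities so all per-sample medians coincide.  The common
target is the median of the per-sample medians — symmetric in the
samples, no designated reference run.

Imputation draws missing cells from a down-shifted Normal per sample
(mean(sample) - shift_sd * sd(sample), width width_sd * sd(sample)), the
standard surrogate for left-censored, missing-not-at-random dropout.  It
is strictly opt-in and must never run before QC, which has to see the
data as measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class NormalizationResult:
    table: pd.DataFrame          # corrected canonical table
    shifts: pd.Series            # per-sample additive shift applied (log2)
    reference_median: float      # common target median (log2)


def median_normalize(table: pd.DataFrame) -> NormalizationResult:
    """Shift each sample so its median log2 intensity hits the common reference.

    corrected = log2 - median(sample) + median over samples of the
    per-sample medians.  Missing values stay missing; within-sample
    differences are preserved exactly (a per-sample constant is added).

    Raises
    ------
    ValueError
        If a sample has no non-missing intensity (named in the message).
    """
    medians = table.groupby("sample")["intensity_log2"].median()
    empty = medians[medians.isna()]
    if not empty.empty:
        raise ValueError(f"sample {empty.index[0]!r} has no non-missing intensities")
    reference = float(medians.median())
    shifts = reference - medians
    out = table.copy()
    out["intensity_log2"] = out["intensity_log2"] + out["sample"].map(shifts).astype(float)
    return NormalizationResult(table=out, shifts=shifts, reference_median=reference)


def filter_min_observations(
    table: pd.DataFrame,
    level: str = "protein",
    min_per_condition: int = 2,
    mode: str = "any",
) -> pd.DataFrame:
    """Keep features with >= min_per_condition observed replicates per condition.

    mode="any": at least one condition must pass; mode="all": every
    condition present in the table must pass.
    """
    if min_per_condition < 1:
        raise ValueError("min_per_condition must be >= 1")
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    obs = table.dropna(subset=[level, "intensity_log2"])
    counts = obs.groupby([level, "condition"]).size().unstack("condition", fill_value=0)
    counts = counts.reindex(columns=table["condition"].unique(), fill_value=0)
    passing = counts >= min_per_condition
    keep = passing.any(axis=1) if mode == "any" else passing.all(axis=1)
    kept_ids = set(keep.index[keep])
    return table[table[level].isin(kept_ids)].reset_index(drop=True)


@dataclass
class ImputationResult:
    matrix: pd.DataFrame
    imputed: pd.DataFrame  # boolean mask of cells that were filled


def impute_mnar(
    matrix: pd.DataFrame,
    shift_sd: float = 1.8,
    width_sd: float = 0.3,
    seed: int = 0,
) -> ImputationResult:
    """Fill missing cells from a per-sample down-shifted Normal.

    Each missing cell in sample s draws from
    Normal(mean_s - shift_sd * sd_s, (width_sd * sd_s)^2) where mean_s /
    sd_s are the observed moments of that sample.  Deterministic under
    ``seed``.  Samples with fewer than two observed values keep their
    missing cells (logged as a warning).

    Raises
    ------
    ValueError
        If the whole matrix has fewer than 10 observed values — too few
        to estimate moments.
    """
    observed = matrix.notna()
    if int(observed.to_numpy().sum()) < 10:
        raise ValueError("need >= 10 observed values to estimate imputation moments")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    flags = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
    for col in matrix.columns:
        vals = matrix[col]
        miss = vals.isna()
        if not miss.any():
            continue
        obs = vals.dropna()
        if len(obs) < 2:
            logger.warning("sample %r has < 2 observed values; leaving its missing cells", col)
            continue
        mu = float(obs.mean())
        sd = float(obs.std(ddof=1))
        draws = rng.normal(mu - shift_sd * sd, width_sd * sd, size=int(miss.sum()))
        out.loc[miss, col] = draws
        flags.loc[miss, col] = True
    return ImputationResult(matrix=out, imputed=flags)
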