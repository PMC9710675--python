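"""Protein abundance profiles from peptide/precursor intensities.

The main estimator reconstructs a per-protein abundance profile across
samples from the medians of pairwise feature log-ratios, in the spirit of
MaxLFQ: for every sample pair (j, k) sharing at least ``min_shared``
features, the ratio r_jk is the median over shared features of
(x_ij - x_ik); the profile p then minimises

    sum over pairs (p_j - p_k - r_jk)^2 .

The system is translation-invariant, so the profile of each connected
sample component is anchored to the mean of all observed log2 intensities
of its samples — this keeps profiles on the intensity scale without
preferring any sample.  Components of size one (and samples disconnected
from all others) fall back to the median of their own observed features;
components are never mixed, because pairwise ratios carry no information
between them.

``summarize_simple`` provides the naive per-sample baselines (sum of raw
intensities, or median of log2 values) for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import to_matrix


@dataclass
class ProteinProfile:
    protein: str
    abundance: pd.Series        # per-sample log2 abundance, NaN where no data
    n_features: int             # features with >= 1 observation
    n_sample_pairs: int         # sample pairs sharing >= min_shared features


def _components(n: int, edges: list[tuple[int, int]], active: np.ndarray) -> list[list[int]]:
    """Connected components over active nodes with the given edges."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for j, k in edges:
        adj[j].append(k)
        adj[k].append(j)
    seen = [False] * n
    comps = []
    for start in range(n):
        if not active[start] or seen[start]:
            continue
        comp, stack = [], [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def maxlfq(values: np.ndarray, min_shared: int = 1) -> np.ndarray:
    """Pairwise-median-ratio least-squares profile of one protein.

    Parameters
    ----------
    values:
        features x samples array of log2 intensities, NaN for missing.
    min_shared:
        Minimum number of shared features for a sample pair to
        contribute a ratio (default 1; canonical MaxLFQ uses 2).

    Returns
    -------
    Per-sample log2 abundances; samples without any observation are NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("need a non-empty 2-D features x samples array")
    n_samples = x.shape[1]
    obs = ~np.isnan(x)
    active = obs.any(axis=0)

    edges: list[tuple[int, int]] = []
    ratios: dict[tuple[int, int], float] = {}
    for j in range(n_samples):
        if not active[j]:
            continue
        for k in range(j + 1, n_samples):
            if not active[k]:
                continue
            shared = obs[:, j] & obs[:, k]
            if int(shared.sum()) >= min_shared:
                ratios[(j, k)] = float(np.median(x[shared, j] - x[shared, k]))
                edges.append((j, k))

    profile = np.full(n_samples, np.nan)
    for comp in _components(n_samples, edges, active):
        if len(comp) == 1:
            j = comp[0]
            profile[j] = float(np.median(x[obs[:, j], j]))
            continue
        pos = {j: i for i, j in enumerate(comp)}
        m = len(comp)
        # normal equations of the pair system: graph Laplacian L p = b
        lap = np.zeros((m, m))
        b = np.zeros(m)
        for (j, k), r in ratios.items():
            if j not in pos:
                continue
            a, c = pos[j], pos[k]
            lap[a, a] += 1.0
            lap[c, c] += 1.0
            lap[a, c] -= 1.0
            lap[c, a] -= 1.0
            b[a] += r
            b[c] -= r
        # L is singular (ones-vector nullspace); lstsq gives the minimum-norm
        # solution, which we then anchor to the observed-data mean.
        p, *_ = np.linalg.lstsq(lap, b, rcond=None)
        target = float(np.nanmean(x[:, comp]))
        profile[comp] = p - p.mean() + target
    return profile


def maxlfq_profile(matrix: pd.DataFrame, protein: str = "", min_shared: int = 1) -> ProteinProfile:
    """MaxLFQ-style profile for one protein's feature x sample matrix."""
    if matrix.size == 0:
        raise ValueError("empty intensity matrix")
    x = matrix.to_numpy(dtype=float)
    prof = maxlfq(x, min_shared=min_shared)
    obs = ~np.isnan(x)
    n_pairs = 0
    for j in range(x.shape[1]):
        for k in range(j + 1, x.shape[1]):
            if int((obs[:, j] & obs[:, k]).sum()) >= min_shared:
                n_pairs += 1
    return ProteinProfile(
        protein=protein,
        abundance=pd.Series(prof, index=matrix.columns),
        n_features=int(obs.any(axis=1).sum()),
        n_sample_pairs=n_pairs,
    )


def summarize_simple(matrix: pd.DataFrame, method: str = "median_log2", protein: str = "") -> ProteinProfile:
    """Baseline per-sample summaries: sum of raw intensities or median log2."""
    if matrix.size == 0:
        raise ValueError("empty intensity matrix")
    if method == "sum_raw":
        raw = np.exp2(matrix)
        sums = raw.sum(axis=0, skipna=True)
        sums[raw.notna().sum(axis=0) == 0] = np.nan
        prof = np.log2(sums.astype(float))
    elif method == "median_log2":
        prof = matrix.median(axis=0, skipna=True)
    else:
        raise ValueError("method must be 'sum_raw' or 'median_log2'")
    obs = matrix.notna().to_numpy()
    return ProteinProfile(protein=protein, abundance=pd.Series(prof, index=matrix.columns),
                          n_features=int(obs.any(axis=1).sum()), n_sample_pairs=0)


def quantify_proteins(
    table: pd.DataFrame,
    level: str = "precursor",
    method: str = "maxlfq",
    min_shared: int = 1,
) -> pd.DataFrame:
    """Protein x sample log2 abundance matrix from a long table.

    ``level`` selects the feature level fed into the profile estimator.
    """
    samples = pd.unique(table["sample"])
    rows = {}
    for protein, grp in table.groupby("protein", sort=True):
        matrix = to_matrix(grp, level).reindex(columns=samples)
        if method == "maxlfq":
            prof = maxlfq_profile(matrix, protein=protein, min_shared=min_shared)
        elif method in ("sum", "sum_raw"):
            prof = summarize_simple(matrix, method="sum_raw", protein=protein)
        elif method in ("median", "median_log2"):
            prof = summarize_simple(matrix, method="median_log2", protein=protein)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows[protein] = prof.abundance
    out = pd.DataFrame(rows).T
    out.index.name = "protein"
    out.columns.name = "sample"
    return out
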