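import numpy as np
import pandas as pd
import pytest

from peptiq.io import CANONICAL_COLUMNS


def make_table(records: list[dict]) -> pd.DataFrame:
    """Build a canonical table from sparse record dicts."""
    df = pd.DataFrame(records)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA if col in ("peptide", "precursor") else np.nan
    df["replicate"] = pd.array(df["replicate"], dtype="Int64") if "replicate" in df else 1
    return df[CANONICAL_COLUMNS]


@pytest.fixture
def two_condition_table() -> pd.DataFrame:
    """2 proteins x 2 conditions x 3 replicates, complete, peptide level."""
    rows = []
    base = {"P1": 20.0, "P2": 18.0}
    for prot, mean in base.items():
        for cond, shift in (("C1", 0.0), ("C2", 1.0 if prot == "P1" else 0.0)):
            for rep in (1, 2, 3):
                rows.append({
                    "sample": f"{cond}_R{rep}", "condition": cond, "replicate": rep,
                    "protein": prot, "peptide": f"PEP{prot}", "precursor": f"PEP{prot}_2",
                    "intensity_log2": mean + shift + 0.1 * rep,
                })
    return make_table(rows)


def maxlfq_oracle(x: np.ndarray, min_shared: int = 1) -> np.ndarray:
    """Dense least-squares solve of the pairwise-median-ratio system.

    Builds the full overdetermined system (one equation p_j - p_k = r_jk
    per qualifying pair) for each connected sample component, solves it
    with numpy lstsq, and shifts the solution so the component mean
    matches the mean of its observed intensities.  Independent of the
    normal-equations path used by the implementation.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[1]
    obs = ~np.isnan(x)
    active = obs.any(axis=0)
    edges, ratios = [], []
    for j in range(n):
        for k in range(j + 1, n):
            shared = obs[:, j] & obs[:, k]
            if active[j] and active[k] and shared.sum() >= min_shared:
                edges.append((j, k))
                ratios.append(np.median(x[shared, j] - x[shared, k]))
    # union-find components
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for j, k in edges:
        parent[find(j)] = find(k)
    profile = np.full(n, np.nan)
    comps: dict[int, list[int]] = {}
    for j in range(n):
        if active[j]:
            comps.setdefault(find(j), []).append(j)
    for comp in comps.values():
        if len(comp) == 1:
            j = comp[0]
            profile[j] = np.median(x[obs[:, j], j])
            continue
        pos = {j: i for i, j in enumerate(comp)}
        rows_a, rhs = [], []
        for (j, k), r in zip(edges, ratios):
            if j in pos:
                row = np.zeros(len(comp))
                row[pos[j]], row[pos[k]] = 1.0, -1.0
                rows_a.append(row)
                rhs.append(r)
        a = np.vstack(rows_a)
        p, *_ = np.linalg.lstsq(a, np.asarray(rhs), rcond=None)
        target = np.nanmean(x[:, comp])
        profile[comp] = p - p.mean() + target
    return profile
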