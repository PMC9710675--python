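"""Over-representation analysis of hit lists by exact hypergeometric tests.

Given a set of hit proteins, a background set and term-to-protein
annotations, each term is tested for over-representation with the
one-sided upper-tail hypergeometric probability

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the background size, K the background members of the term,
n the number of hits and k the hits inside the term.  The background
defaults to the proteins actually present in the dataset, not the whole
proteome: enrichment must be judged relative to what was detectable.

Odds ratios come from the 2x2 table with a 0.5 continuity correction
when any cell is zero.  Terms with K < 2 or K > N/2 are reported but
flagged low-information.  A single-set variant
(:func:`treatment_enrichment`) tests e.g. a drug-target list without
multiplicity adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import adjust_bh


@dataclass
class TermMapping:
    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"term {self.term_id} has no members")


def read_gmt(path: str | Path) -> list[TermMapping]:
    """Read GMT-style TSV: term_id <tab> term_name <tab> member1 <tab> ..."""
    terms = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {ln}: GMT rows need term_id, term_name and >= 1 member")
            term_id, term_name, *members = parts
            if term_id in seen:
                raise ValueError(f"line {ln}: duplicate term_id {term_id!r}")
            seen.add(term_id)
            terms.append(TermMapping(term_id, term_name, frozenset(m for m in members if m)))
    return terms


def read_term_table(path: str | Path) -> list[TermMapping]:
    """Read two-column long format (term_id <tab> protein_id), header optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("term table needs two columns: term_id, protein_id")
    term_col, prot_col = df.columns[:2]
    terms = []
    for term_id, grp in df.groupby(term_col, sort=True):
        terms.append(TermMapping(str(term_id), str(term_id), frozenset(grp[prot_col].dropna())))
    return terms


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    a = k                   # hit, in term
    b = n - k               # hit, not in term
    c = K - k               # non-hit, in term
    d = N - K - n + k       # non-hit, not in term
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def enrich(
    hits: set[str],
    background: set[str],
    terms: list[TermMapping],
    depletion: bool = False,
) -> pd.DataFrame:
    """Test every term for over-representation of hits within the background.

    Terms with no background member are skipped.  Returns one row per
    tested term with counts, odds ratio, exact p and BH-adjusted p,
    sorted by ascending adjusted p.

    Raises
    ------
    ValueError
        If hits are not a subset of the background (offenders listed).
    """
    hits, background = set(hits), set(background)
    if not background:
        raise ValueError("background must be non-empty")
    stray = hits - background
    if stray:
        raise ValueError(f"hits outside background: {sorted(stray)[:10]}")
    N, n = len(background), len(hits)
    rows = []
    for term in terms:
        members = term.members & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & hits)
        if depletion:
            p = float(sps.hypergeom.cdf(k, N, K, n))
        else:
            p = hypergeom_tail(k, N, K, n)
        rows.append({
            "term_id": term.term_id, "term_name": term.term_name,
            "n_hits_in_term": k, "n_hits": n,
            "n_background_in_term": K, "n_background": N,
            "odds_ratio": _odds_ratio(k, K, n, N),
            "p_value": min(p, 1.0),
            "low_information": K < 2 or K > 0.5 * N,
        })
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "n_hits_in_term", "n_hits",
                                      "n_background_in_term", "n_background", "odds_ratio",
                                      "p_value", "low_information"])
    out["adj_p_value"] = adjust_bh(out["p_value"]) if len(out) else np.nan
    return out.sort_values(["adj_p_value", "p_value", "term_id"]).reset_index(drop=True)


def treatment_enrichment(
    hits: set[str],
    background: set[str],
    target_set: set[str],
    term_id: str = "treatment_targets",
) -> pd.DataFrame:
    """Single-set over-representation of a treatment-target list.

    Same machinery as :func:`enrich` with one term and no multiplicity
    adjustment (adj_p = p).  A target set disjoint from the background is
    skipped with a reason rather than an error.
    """
    term = TermMapping(term_id, term_id, frozenset(target_set))
    out = enrich(hits, background, [term])
    if out.empty:
        return pd.DataFrame([{"term_id": term_id, "term_name": term_id,
                              "reason": "no target in background"}])
    out = out.copy()
    out["adj_p_value"] = out["p_value"]
    return out
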