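"""Peptide-to-protein sequence mapping and per-residue differential profiles.

This is the peptide-centric (LiP-MS style) end of the pipeline: peptides
are located in their protein sequence, classified by proteolytic
specificity (trypsin cuts after K/R), coverage is computed as a union of
residue intervals, and per-feature differential statistics are projected
onto residues as a "barcode" — the data behind plots of differentially
abundant peptides along the protein sequence.

Coordinates are 1-based inclusive, matching UniProt residue numbering.
Peptide strings are matched after stripping modification annotations in
[brackets] or (parentheses), since search-engine exports embed PTM
strings in the sequence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

N_TERMINUS = "[N-term]"
C_TERMINUS = "[C-term]"

_MOD_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)")
_UNIPROT_HEADER_RE = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id}")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PeptidePosition:
    protein_id: str
    peptide_seq: str            # stripped sequence actually matched
    start: int | None = None    # 1-based inclusive
    end: int | None = None
    preceding_aa: str | None = None   # residue letter or N_TERMINUS
    following_aa: str | None = None   # residue letter or C_TERMINUS
    found: bool = False
    multi_mapped: bool = False


def strip_modifications(peptide: str) -> str:
    """Remove [UniMod]/(phospho)-style annotations and uppercase."""
    return _MOD_RE.sub("", peptide).upper().strip()


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records; UniProt sp|ACC|NAME headers yield the accession.

    Raises on duplicate accessions — a quantitative table joined against
    an ambiguous database would silently mix proteins.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _UNIPROT_HEADER_RE.match(rec.id)
        pid = m.group(1) if m else rec.id
        if pid in seen:
            raise ValueError(f"duplicate accession in FASTA: {pid}")
        seen.add(pid)
        records.append(ProteinRecord(protein_id=pid, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def find_peptide(protein: ProteinRecord, peptide_seq: str) -> PeptidePosition:
    """Locate the leftmost exact occurrence of a peptide in its protein.

    Modification annotations are stripped before matching.  A peptide
    occurring more than once keeps the leftmost position with
    ``multi_mapped=True``; absence is reported via ``found=False``, not
    an error.
    """
    pep = strip_modifications(peptide_seq)
    if not pep:
        raise ValueError("empty peptide sequence")
    seq = protein.sequence
    idx = seq.find(pep)
    if idx < 0:
        return PeptidePosition(protein_id=protein.protein_id, peptide_seq=pep)
    start = idx + 1
    end = idx + len(pep)
    return PeptidePosition(
        protein_id=protein.protein_id,
        peptide_seq=pep,
        start=start,
        end=end,
        preceding_aa=seq[idx - 1] if idx > 0 else N_TERMINUS,
        following_aa=seq[end] if end < len(seq) else C_TERMINUS,
        found=True,
        multi_mapped=seq.find(pep, idx + 1) >= 0,
    )


def assign_peptide_type(position: PeptidePosition, proline_rule: bool = False) -> str:
    """Classify trypsin specificity: fully-tryptic / semi-tryptic / non-tryptic.

    The N-terminus is specific when the preceding residue is K/R or the
    peptide starts the protein; the C-terminus when the peptide's last
    residue is K/R or it ends the protein.  With ``proline_rule`` a cut
    followed by proline does not count (trypsin does not cleave K/R-P).
    """
    if not position.found:
        raise ValueError("cannot classify a peptide that was not located")
    n_ok = position.preceding_aa == N_TERMINUS or (
        position.preceding_aa in ("K", "R")
        and not (proline_rule and position.peptide_seq[0] == "P")
    )
    c_ok = position.following_aa == C_TERMINUS or (
        position.peptide_seq[-1] in ("K", "R")
        and not (proline_rule and position.following_aa == "P")
    )
    if n_ok and c_ok:
        return "fully-tryptic"
    if n_ok or c_ok:
        return "semi-tryptic"
    return "non-tryptic"


def sequence_coverage(protein: ProteinRecord, positions: list[PeptidePosition]) -> float:
    """Fraction of residues covered by the union of found peptide intervals."""
    covered = np.zeros(protein.length, dtype=bool)
    for pos in positions:
        if pos.found:
            covered[pos.start - 1:pos.end] = True
    return float(covered.mean()) if protein.length else 0.0


@dataclass
class BarcodeProfile:
    """Per-residue projection of peptide-level differential statistics."""
    protein_id: str
    covered: np.ndarray         # bool, length = protein length
    min_adj_p: np.ndarray       # float, NaN where no peptide overlaps
    max_fold_change: np.ndarray # signed log2 FC of the max-|FC| overlapping peptide

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "protein": self.protein_id,
            "residue": np.arange(1, len(self.covered) + 1),
            "covered": self.covered,
            "adj_p_value": self.min_adj_p,
            "log2_fc": self.max_fold_change,
        })


def barcode_profile(
    protein: ProteinRecord,
    positions: list[PeptidePosition],
    results: pd.DataFrame,
) -> BarcodeProfile:
    """Aggregate differential results onto residues.

    ``results`` carries one row per peptide with columns ``feature``
    (the stripped peptide sequence), ``adj_p_value`` and ``diff``.  Each
    residue records the minimum adjusted p and the signed log2 FC of the
    overlapping peptide with maximal |log2 FC|; uncovered residues stay
    missing.
    """
    n = protein.length
    covered = np.zeros(n, dtype=bool)
    min_p = np.full(n, np.nan)
    max_fc = np.full(n, np.nan)
    stats_of = {}
    if len(results):
        for row in results.itertuples(index=False):
            stats_of[str(row.feature)] = (getattr(row, "adj_p_value", math.nan),
                                          getattr(row, "diff", math.nan))
    for pos in positions:
        if not pos.found:
            continue
        sl = slice(pos.start - 1, pos.end)
        covered[sl] = True
        p, fc = stats_of.get(pos.peptide_seq, (math.nan, math.nan))
        if p is not None and not (isinstance(p, float) and math.isnan(p)):
            seg = min_p[sl]
            min_p[sl] = np.fmin(np.where(np.isnan(seg), np.inf, seg), p)
        if fc is not None and not (isinstance(fc, float) and math.isnan(fc)):
            seg = max_fc[sl]
            replace = np.isnan(seg) | (np.abs(fc) > np.abs(seg))
            max_fc[sl] = np.where(replace, fc, seg)
    min_p[np.isinf(min_p)] = np.nan
    return BarcodeProfile(protein_id=protein.protein_id, covered=covered,
                          min_adj_p=min_p, max_fold_change=max_fc)


def annotate_peptides(
    table: pd.DataFrame,
    proteins: list[ProteinRecord],
    proline_rule: bool = False,
) -> pd.DataFrame:
    """Locate and classify every distinct (protein, peptide) pair of a table."""
    by_id = {p.protein_id: p for p in proteins}
    pairs = table[["protein", "peptide"]].dropna().drop_duplicates()
    rows = []
    for prot_id, pep in pairs.itertuples(index=False):
        rec = by_id.get(prot_id)
        if rec is None:
            rows.append({"protein": prot_id, "peptide": pep, "found": False,
                         "start": pd.NA, "end": pd.NA, "preceding_aa": None,
                         "following_aa": None, "multi_mapped": False, "peptide_type": None,
                         "reason": "protein not in FASTA"})
            continue
        pos = find_peptide(rec, pep)
        rows.append({"protein": prot_id, "peptide": pep, "found": pos.found,
                     "start": pos.start if pos.found else pd.NA,
                     "end": pos.end if pos.found else pd.NA,
                     "preceding_aa": pos.preceding_aa, "following_aa": pos.following_aa,
                     "multi_mapped": pos.multi_mapped,
                     "peptide_type": assign_peptide_type(pos, proline_rule) if pos.found else None,
                     "reason": None if pos.found else "peptide not found in sequence"})
    return pd.DataFrame(rows)
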