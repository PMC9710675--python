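"""Synthetic label-free bottom-up proteomics datasets with known ground truth.

The generative model is hierarchical and matches the assumptions of the
downstream statistics: a protein draws a mean log2 intensity from a
population Normal; each of its peptides carries a fixed additive
ionisation offset; every replicate observation adds Normal measurement
noise; differential proteins add a condition effect in log2 space; and
each observation survives detection with probability
``sigmoid(dropout_slope * (intensity - dropout_midpoint))`` — a smooth,
two-parameter missing-not-at-random surrogate for the intensity-dependent
dropout of real DDA/DIA data.

Protein sequences are synthetic: each protein's sequence is the
concatenation of its peptides, which are built K/R-terminated and K/R-free
internally, so every peptide is fully tryptic and its true position is
known.  This gives the peptide-annotation stage an exact offline ground
truth; it does not emulate real proteome sequence composition.

In dose mode (``generate_dose_response``) responder proteins follow a
four-parameter log-logistic curve across the concentration series and
non-responders are flat; peptide offsets, noise and dropout apply as in
the two-group mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import CANONICAL_COLUMNS

_AA_INTERNAL = list("ACDEFGHILMNPQSTVWY")  # no K/R: keeps peptides cleavage-free inside
_AA_TERM = ["K", "R"]


@dataclass
class SyntheticConfig:
    """Parameters of the generative model (log2 units unless noted).

    Defaults yield ~10-30% missingness with realistic intensity spread.
    """

    n_proteins: int = 100
    peptides_per_protein: int | tuple[int, int] = (2, 5)
    n_conditions: int = 2
    n_replicates: int = 3
    protein_mean_log2: tuple[float, float] = (20.0, 2.0)  # (mu_pop, sd_pop)
    peptide_offset_sd: float = 1.5
    replicate_noise_sd: float = 0.3
    frac_differential: float = 0.1
    effect_log2fc: tuple[float, float] = (1.0, 0.5)  # |effect| ~ Normal, sign random
    dropout_midpoint: float | None = 17.0  # None disables dropout entirely
    dropout_slope: float = 1.0
    doses: Sequence[float] | None = None  # concentration units; dose mode only
    frac_responders: float = 0.2
    ec50_log10_range: tuple[float, float] = (-7.0, -5.0)
    response_amplitude: tuple[float, float] = (1.0, 4.0)  # |d - c| ~ Uniform, sign random
    hill: float = 1.0
    lip_mode: bool = False  # only a random subset of a protein's peptides respond
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        for name in ("peptide_offset_sd", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.protein_mean_log2[1] < 0:
            raise ValueError("population sd must be >= 0")
        for name in ("frac_differential", "frac_responders"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.doses is not None:
            d = list(self.doses)
            if any(x < 0 for x in d):
                raise ValueError("doses must be non-negative")
            if sorted(d) != d or len(set(d)) != len(d):
                raise ValueError("doses must be strictly increasing")


@dataclass
class GroundTruth:
    """Simulator truth for recovery testing.

    Attributes
    ----------
    proteins:
        One row per (protein, condition): true mean, true log2 fold change
        vs the reference condition (0 for null proteins), responder flag.
    peptides:
        One row per peptide: fixed offset, responsive flag (all peptides of
        a differential protein unless lip_mode), 1-based start/end in the
        synthetic protein sequence.
    cells:
        Every pre-dropout observation with its intensity and observed flag.
    dose_response:
        Dose mode only: per protein the true 4PL parameters (hill b, lower
        c, upper d, ec50 e) and responder flag.
    sequences:
        protein -> synthetic amino-acid sequence.
    """

    proteins: pd.DataFrame
    peptides: pd.DataFrame
    cells: pd.DataFrame
    dose_response: pd.DataFrame | None = None
    sequences: dict[str, str] = field(default_factory=dict)

    def write(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in (
            ("truth_proteins.tsv", self.proteins),
            ("truth_peptides.tsv", self.peptides),
            ("truth_cells.tsv", self.cells),
        ):
            p = directory / name
            df.to_csv(p, sep="\t", index=False, na_rep="NA")
            written.append(p)
        if self.dose_response is not None:
            p = directory / "truth_dose_response.tsv"
            self.dose_response.to_csv(p, sep="\t", index=False, na_rep="NA")
            written.append(p)
        if self.sequences:
            p = directory / "truth_proteins.fasta"
            with open(p, "w") as fh:
                for pid, seq in self.sequences.items():
                    fh.write(f">{pid}\n{seq}\n")
            written.append(p)
        return written


def write_config(config: SyntheticConfig, path: str | Path) -> None:
    d = asdict(config)
    if d["doses"] is not None:
        d["doses"] = [float(x) for x in d["doses"]]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def _peptide_counts(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.peptides_per_protein, int):
        if cfg.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein must be >= 1")
        return np.full(cfg.n_proteins, cfg.peptides_per_protein, dtype=int)
    lo, hi = cfg.peptides_per_protein
    if lo < 1 or hi < lo:
        raise ValueError("peptides_per_protein range must satisfy 1 <= lo <= hi")
    return rng.integers(lo, hi + 1, size=cfg.n_proteins)


def _make_peptides(n: int, rng: np.random.Generator, taken: set[str]) -> list[str]:
    """n unique tryptic peptides: 6-19 internal K/R-free residues + K/R terminus."""
    out = []
    while len(out) < n:
        length = int(rng.integers(6, 20))
        body = "".join(rng.choice(_AA_INTERNAL, size=length))
        pep = body + str(rng.choice(_AA_TERM))
        if pep not in taken:
            taken.add(pep)
            out.append(pep)
    return out


def _keep_mask(intensity: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.dropout_midpoint is None:
        return np.ones(intensity.shape, dtype=bool)
    p_keep = 1.0 / (1.0 + np.exp(-cfg.dropout_slope * (intensity - cfg.dropout_midpoint)))
    return rng.random(intensity.shape) < p_keep


def _empty_outputs(dose_mode: bool) -> tuple[pd.DataFrame, GroundTruth]:
    table = pd.DataFrame(columns=CANONICAL_COLUMNS)
    truth = GroundTruth(
        proteins=pd.DataFrame(columns=["protein", "condition", "true_mean", "true_log2fc", "differential"]),
        peptides=pd.DataFrame(columns=["protein", "peptide", "precursor", "offset", "responsive", "start", "end"]),
        cells=pd.DataFrame(columns=["protein", "peptide", "precursor", "sample", "condition",
                                    "replicate", "dose", "intensity_pre_dropout", "observed"]),
        dose_response=pd.DataFrame(columns=["protein", "responder", "hill", "lower", "upper", "ec50"])
        if dose_mode else None,
    )
    return table, truth


def _build_peptide_frame(cfg, rng, protein_ids, diff_flags):
    counts = _peptide_counts(cfg, rng)
    taken: set[str] = set()
    rows = []
    sequences = {}
    for i, pid in enumerate(protein_ids):
        peps = _make_peptides(counts[i], rng, taken)
        offsets = rng.normal(0.0, cfg.peptide_offset_sd, size=counts[i])
        if diff_flags[i] and cfg.lip_mode:
            n_resp = max(1, counts[i] // 2)
            resp_idx = set(rng.choice(counts[i], size=n_resp, replace=False).tolist())
        else:
            resp_idx = set(range(counts[i])) if diff_flags[i] else set()
        charges = rng.choice([2, 3], size=counts[i])
        pos = 0
        seq_parts = []
        for j, pep in enumerate(peps):
            start = pos + 1
            end = pos + len(pep)
            pos = end
            seq_parts.append(pep)
            rows.append({
                "protein": pid, "peptide": pep, "precursor": f"{pep}_{charges[j]}",
                "offset": offsets[j], "responsive": j in resp_idx,
                "start": start, "end": end,
            })
        sequences[pid] = "".join(seq_parts)
    return pd.DataFrame(rows), sequences


def generate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a multi-condition label-free dataset.

    Returns the observed canonical long table (dropped-out cells are
    absent) and the full :class:`GroundTruth`.  Bit-identical under a
    fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.n_proteins == 0:
        return _empty_outputs(dose_mode=False)

    protein_ids = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    conditions = [f"C{c + 1}" for c in range(config.n_conditions)]

    means = rng.normal(*config.protein_mean_log2, size=config.n_proteins)
    n_diff = round(config.frac_differential * config.n_proteins)
    diff_idx = rng.choice(config.n_proteins, size=n_diff, replace=False)
    diff_flags = np.zeros(config.n_proteins, dtype=bool)
    diff_flags[diff_idx] = True

    # one effect per (differential protein, non-reference condition)
    m_eff, s_eff = config.effect_log2fc
    effects = np.zeros((config.n_proteins, config.n_conditions))
    for i in np.flatnonzero(diff_flags):
        for c in range(1, config.n_conditions):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[i, c] = sign * abs(rng.normal(m_eff, s_eff))

    pep_frame, sequences = _build_peptide_frame(config, rng, protein_ids, diff_flags)
    prot_index = {pid: i for i, pid in enumerate(protein_ids)}

    cell_rows = []
    for rec in pep_frame.itertuples(index=False):
        i = prot_index[rec.protein]
        base = means[i] + rec.offset
        for c, cond in enumerate(conditions):
            eff = effects[i, c] if rec.responsive else 0.0
            noise = rng.normal(0.0, config.replicate_noise_sd, size=config.n_replicates)
            intensities = base + eff + noise
            keep = _keep_mask(intensities, config, rng)
            for r in range(config.n_replicates):
                cell_rows.append((rec.protein, rec.peptide, rec.precursor,
                                  f"{cond}_R{r + 1}", cond, r + 1, np.nan,
                                  intensities[r], bool(keep[r])))

    cells = pd.DataFrame(cell_rows, columns=["protein", "peptide", "precursor", "sample",
                                             "condition", "replicate", "dose",
                                             "intensity_pre_dropout", "observed"])
    table = _cells_to_table(cells)

    proteins = pd.DataFrame(
        [{"protein": pid, "condition": cond, "true_mean": means[i],
          "true_log2fc": effects[i, c], "differential": bool(diff_flags[i])}
         for i, pid in enumerate(protein_ids) for c, cond in enumerate(conditions)]
    )
    truth = GroundTruth(proteins=proteins, peptides=pep_frame, cells=cells, sequences=sequences)
    return table, truth


def four_pl(x: np.ndarray | float, hill: float, lower: float, upper: float, ec50: float):
    """LL.4 curve c + (d - c)/(1 + exp(b (ln x - ln e))); limit used at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty(x.shape)
    pos = x > 0
    out[pos] = lower + (upper - lower) / (1.0 + np.exp(hill * (np.log(x[pos]) - math.log(ec50))))
    out[~pos] = upper if hill > 0 else lower
    return out if out.shape else float(out)


def generate_dose_response(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a dose-response experiment across the configured doses.

    Responder proteins' means follow a 4PL curve of the dose; flat
    otherwise.  Requires at least 5 distinct doses (fewer would leave a
    four-parameter fit under-determined).
    """
    config.validate()
    if config.doses is None or len(set(config.doses)) < 5:
        raise ValueError("dose mode needs at least 5 distinct doses")
    rng = np.random.default_rng(config.seed)
    if config.n_proteins == 0:
        return _empty_outputs(dose_mode=True)

    doses = [float(d) for d in config.doses]
    protein_ids = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    means = rng.normal(*config.protein_mean_log2, size=config.n_proteins)

    n_resp = round(config.frac_responders * config.n_proteins)
    resp_idx = rng.choice(config.n_proteins, size=n_resp, replace=False)
    resp_flags = np.zeros(config.n_proteins, dtype=bool)
    resp_flags[resp_idx] = True

    lo_a, hi_a = config.response_amplitude
    lo_e, hi_e = config.ec50_log10_range
    dr_rows = []
    for i, pid in enumerate(protein_ids):
        if resp_flags[i]:
            amp = rng.uniform(lo_a, hi_a) * (1.0 if rng.random() < 0.5 else -1.0)
            ec50 = 10.0 ** rng.uniform(lo_e, hi_e)
            dr_rows.append({"protein": pid, "responder": True, "hill": config.hill,
                            "lower": means[i] + amp, "upper": means[i], "ec50": ec50})
        else:
            dr_rows.append({"protein": pid, "responder": False, "hill": np.nan,
                            "lower": np.nan, "upper": np.nan, "ec50": np.nan})
    dr = pd.DataFrame(dr_rows)

    pep_frame, sequences = _build_peptide_frame(config, rng, protein_ids, resp_flags)
    prot_index = {pid: i for i, pid in enumerate(protein_ids)}

    cell_rows = []
    for rec in pep_frame.itertuples(index=False):
        i = prot_index[rec.protein]
        row = dr.iloc[i]
        for di, dose in enumerate(doses):
            if resp_flags[i] and rec.responsive:
                mean_at = four_pl(dose, row["hill"], row["lower"], row["upper"], row["ec50"])
            else:
                mean_at = means[i]
            base = mean_at + rec.offset
            noise = rng.normal(0.0, config.replicate_noise_sd, size=config.n_replicates)
            intensities = base + noise
            keep = _keep_mask(intensities, config, rng)
            cond = f"D{di + 1}"
            for r in range(config.n_replicates):
                cell_rows.append((rec.protein, rec.peptide, rec.precursor,
                                  f"{cond}_R{r + 1}", cond, r + 1, dose,
                                  intensities[r], bool(keep[r])))

    cells = pd.DataFrame(cell_rows, columns=["protein", "peptide", "precursor", "sample",
                                             "condition", "replicate", "dose",
                                             "intensity_pre_dropout", "observed"])
    table = _cells_to_table(cells)

    proteins = pd.DataFrame(
        [{"protein": pid, "condition": f"D{di + 1}", "true_mean": means[i],
          "true_log2fc": 0.0, "differential": bool(resp_flags[i])}
         for i, pid in enumerate(protein_ids) for di in range(len(doses))]
    )
    truth = GroundTruth(proteins=proteins, peptides=pep_frame, cells=cells,
                        dose_response=dr, sequences=sequences)
    return table, truth


def _cells_to_table(cells: pd.DataFrame) -> pd.DataFrame:
    obs = cells[cells["observed"]]
    table = pd.DataFrame({
        "sample": obs["sample"].to_numpy(),
        "condition": obs["condition"].to_numpy(),
        "replicate": pd.array(obs["replicate"].to_numpy(), dtype="Int64"),
        "protein": obs["protein"].to_numpy(),
        "peptide": obs["peptide"].to_numpy(),
        "precursor": obs["precursor"].to_numpy(),
        "intensity_log2": obs["intensity_pre_dropout"].to_numpy(),
        "dose": obs["dose"].to_numpy(),
    })
    return table.reset_index(drop=True)
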