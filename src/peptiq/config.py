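"""YAML-driven pipeline runner.

Stages communicate through the canonical long TSV on disk, never
in-memory only, so every intermediate is auditable and the chain can be
re-run stage by stage with identical results.  All randomness flows from
one root seed: stage i consumes the i-th child of
``numpy.random.SeedSequence(seed)``, which makes the full chain
bit-reproducible while keeping stages independent.

A run writes ``manifest.json`` listing the seed, the stage order and a
SHA-256 digest of every artifact; two runs with the same config produce
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import enrichment as enr
from .doseresponse import fit_dose_response
from .io import (CANONICAL_COLUMNS, DIALECTS, ColumnMap, read_canonical,
                 read_quant_table, sample_conditions, to_matrix, write_quant_table)
from .lfq import quantify_proteins
from .preprocess import filter_min_observations, impute_mnar, median_normalize
from .qc import qc_report
from .simulate import SyntheticConfig, generate_dataset, generate_dose_response, write_config
from .stats import differential_abundance

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "qc", "normalize", "filter", "impute",
                "quantify", "diff", "drc", "annotate", "enrich")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a YAML mapping")
    return cfg


def validate_config(cfg: dict, base_dir: Path) -> None:
    """Check stage names and that every referenced path exists, before any stage runs."""
    stages = cfg.get("stages", [])
    if not stages:
        raise ValueError("config lists no stages")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}; known: {list(KNOWN_STAGES)}")
    paths = []
    if cfg.get("input"):
        paths.append(cfg["input"])
    for stage in ("annotate",):
        if cfg.get(stage, {}).get("fasta"):
            paths.append(cfg[stage]["fasta"])
    if cfg.get("enrich", {}).get("terms"):
        paths.append(cfg["enrich"]["terms"])
    for p in paths:
        if not (base_dir / p).exists() and not Path(p).exists():
            raise ValueError(f"referenced path does not exist: {p}")
    if "simulate" not in stages and not cfg.get("input"):
        raise ValueError("config needs an input table unless the chain starts with 'simulate'")


def _resolve(path: str, base_dir: Path) -> Path:
    p = Path(path)
    return p if p.exists() else base_dir / path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(root_seed: int, index: int) -> int:
    children = np.random.SeedSequence(root_seed).spawn(index + 1)
    return int(children[index].generate_state(1)[0] % (2 ** 31))


def _write_df(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def run_pipeline(cfg: dict, base_dir: str | Path = ".") -> dict:
    """Execute the configured stage chain; returns the manifest dict.

    The manifest (also written to ``<output_dir>/manifest.json``) maps
    every artifact's path (relative to the output directory) to its
    SHA-256 digest, alongside the seed and stage order.
    """
    base_dir = Path(base_dir)
    validate_config(cfg, base_dir)
    outdir = base_dir / cfg.get("output_dir", "peptiq_out")
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    level = cfg.get("level", "peptide")
    stages = cfg["stages"]

    artifacts: list[Path] = []
    current: Path | None = None
    current_level = level
    if cfg.get("input"):
        src = _resolve(cfg["input"], base_dir)
        dialect = cfg.get("dialect", "canonical")
        if dialect == "canonical":
            table = read_canonical(src)
        else:
            cmap = ColumnMap(**cfg["column_map"]) if cfg.get("column_map") else None
            table = read_quant_table(src, column_map=cmap, dialect=None if cmap else dialect)
        current = outdir / "input.tsv"
        write_quant_table(table, current)
        artifacts.append(current)

    for i, stage in enumerate(stages):
        params = dict(cfg.get(stage) or {})
        sseed = _stage_seed(seed, i)
        try:
            current, current_level, new_files = _run_stage(
                stage, params, current, current_level, outdir, sseed)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        artifacts.extend(new_files)

    manifest = {
        "seed": seed,
        "stages": list(stages),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(artifacts))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _require_table(stage: str, current: Path | None) -> pd.DataFrame:
    if current is None:
        raise PipelineError(stage, "no upstream table; put 'simulate' first or set input")
    return read_canonical(current)


def _run_stage(stage, params, current, level, outdir, sseed):
    new_files: list[Path] = []

    if stage == "simulate":
        mode = params.pop("mode", "dataset")
        params.setdefault("seed", sseed)
        sim_cfg = SyntheticConfig(**params)
        if mode == "dose_response":
            table, truth = generate_dose_response(sim_cfg)
        else:
            table, truth = generate_dataset(sim_cfg)
        current = outdir / "simulated.tsv"
        write_quant_table(table, current)
        new_files.append(current)
        new_files.extend(truth.write(outdir))
        cfg_path = outdir / "simulate_config.yaml"
        write_config(sim_cfg, cfg_path)
        new_files.append(cfg_path)
        return current, level, new_files

    table = _require_table(stage, current)

    if stage == "qc":
        qc_level = params.get("level", level)
        report = qc_report(table, level=qc_level)
        for name in ("ids_per_sample", "intensity_quartiles", "cv", "completeness_per_sample"):
            new_files.append(_write_df(report[name], outdir / f"qc_{name}.tsv"))
        corr = report["sample_correlation"]
        if corr is not None:
            p = outdir / "qc_sample_correlation.tsv"
            corr.to_csv(p, sep="\t", na_rep="NA")
            new_files.append(p)
        summary = pd.DataFrame([{"completeness_overall": report["completeness_overall"]}])
        new_files.append(_write_df(summary, outdir / "qc_summary.tsv"))
        return current, level, new_files

    if stage == "normalize":
        res = median_normalize(table)
        current = outdir / "normalized.tsv"
        write_quant_table(res.table, current)
        shifts = res.shifts.rename("shift_log2").reset_index()
        new_files += [current, _write_df(shifts, outdir / "normalization_shifts.tsv")]
        return current, level, new_files

    if stage == "filter":
        out = filter_min_observations(table, level=params.get("level", level),
                                      min_per_condition=int(params.get("min_per_condition", 2)),
                                      mode=params.get("mode", "any"))
        current = outdir / "filtered.tsv"
        write_quant_table(out, current)
        new_files.append(current)
        return current, level, new_files

    if stage == "impute":
        imp_level = params.get("level", level)
        matrix = to_matrix(table, imp_level)
        res = impute_mnar(matrix, shift_sd=float(params.get("shift_sd", 1.8)),
                          width_sd=float(params.get("width_sd", 0.3)),
                          seed=int(params.get("seed", sseed)))
        long = res.matrix.stack().rename("intensity_log2").reset_index()
        meta = table[["sample", "condition", "replicate", "dose"]].drop_duplicates("sample")
        long = long.merge(meta, on="sample", how="left")
        for col in ("protein", "peptide", "precursor"):
            if col not in long.columns:
                long[col] = long[imp_level] if col == imp_level else pd.NA
        if imp_level != "protein":
            key = table[[imp_level, "protein"]].drop_duplicates()
            long = long.drop(columns=["protein"]).merge(key, on=imp_level, how="left")
        current = outdir / "imputed.tsv"
        write_quant_table(long, current)
        flags = res.imputed.stack().rename("imputed").reset_index()
        new_files += [current, _write_df(flags, outdir / "imputed_flags.tsv")]
        return current, imp_level, new_files

    if stage == "quantify":
        q_level = params.get("level", "peptide" if level == "protein" else level)
        prof = quantify_proteins(table, level=q_level,
                                 method=params.get("method", "maxlfq"),
                                 min_shared=int(params.get("min_shared", 1)))
        p = outdir / "protein_matrix.tsv"
        prof.to_csv(p, sep="\t", na_rep="NA")
        new_files.append(p)
        long = prof.stack().rename("intensity_log2").reset_index()
        meta = table[["sample", "condition", "replicate", "dose"]].drop_duplicates("sample")
        long = long.merge(meta, on="sample", how="left")
        long["peptide"] = pd.NA
        long["precursor"] = pd.NA
        current = outdir / "protein_quant.tsv"
        write_quant_table(long, current)
        new_files.append(current)
        return current, "protein", new_files

    if stage == "diff":
        d_level = params.get("level", level)
        res = differential_abundance(table, level=d_level,
                                     method=params.get("method", "moderated"),
                                     ref_condition=params.get("ref_condition"))
        new_files.append(_write_df(res, outdir / "differential.tsv"))
        return current, level, new_files

    if stage == "drc":
        d_level = params.get("level", level)
        res = fit_dose_response(table, level=d_level,
                                alpha=float(params.get("alpha", 0.05)),
                                min_r2=float(params.get("min_r2", 0.8)))
        new_files.append(_write_df(res, outdir / "dose_response.tsv"))
        return current, level, new_files

    if stage == "annotate":
        fasta = params.get("fasta") or (outdir / "truth_proteins.fasta")
        proteins = ann.read_fasta(fasta)
        positions = ann.annotate_peptides(table, proteins,
                                          proline_rule=bool(params.get("proline_rule", False)))
        new_files.append(_write_df(positions, outdir / "peptide_positions.tsv"))
        diff_path = outdir / "differential.tsv"
        if diff_path.exists():
            results = pd.read_csv(diff_path, sep="\t", na_values="NA")
            by_id = {p.protein_id: p for p in proteins}
            frames = []
            for prot_id, grp in positions[positions["found"]].groupby("protein"):
                rec = by_id.get(prot_id)
                if rec is None:
                    continue
                pos_objs = [ann.find_peptide(rec, pep) for pep in grp["peptide"]]
                sub = results[results["feature"].isin(grp["peptide"])]
                frames.append(ann.barcode_profile(rec, pos_objs, sub).to_frame())
            if frames:
                new_files.append(_write_df(pd.concat(frames, ignore_index=True),
                                           outdir / "barcode.tsv"))
        return current, level, new_files

    if stage == "enrich":
        background = set(table["protein"].dropna())
        alpha = float(params.get("alpha", 0.05))
        hits: set[str] = set()
        diff_path = outdir / "differential.tsv"
        drc_path = outdir / "dose_response.tsv"
        if params.get("hits_from", "diff") == "drc" and drc_path.exists():
            res = pd.read_csv(drc_path, sep="\t", na_values="NA")
            hits = set(res.loc[res["hit"] == True, "feature"])  # noqa: E712
        elif diff_path.exists():
            res = pd.read_csv(diff_path, sep="\t", na_values="NA")
            sig = res[res["adj_p_value"] < alpha]
            feats = set(sig["feature"])
            if level == "protein":
                hits = feats & background
            else:
                hits = set(table.loc[table[level].isin(feats), "protein"].dropna())
        terms_path = params.get("terms")
        if terms_path is None:
            raise PipelineError("enrich", "no 'terms' file configured")
        terms = enr.read_gmt(terms_path)
        out = enr.enrich(hits & background, background, terms)
        new_files.append(_write_df(out, outdir / "enrichment.tsv"))
        return current, level, new_files

    raise PipelineError(stage, "unknown stage")
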