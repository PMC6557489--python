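"""Run configuration, manifest, and the stage pipeline.

A run is described by one YAML config naming a stage and its parameters;
``run_pipeline`` validates it, executes the stage chain, writes outputs,
and drops a JSON manifest (parameters, input digests, seeds, package
version, timestamp) sufficient to reproduce the run byte-for-byte given
the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .eiv_normalization import RobustConfig, bootstrap_ci
from .reporter_analysis import (
    TableDialect,
    classify_crm,
    fold_change,
    group_slope,
    load_luminescence_table,
    qpcr_relative_expression,
    rank_sum_test,
)
from .sequence_sites import (
    apply_mutation_plan,
    design_site_mutation,
    read_count_matrix,
    read_fasta,
    scan_sites,
    sites_to_bed,
    write_fasta,
)
from .synthetic_data import simulate_luminescence
from .thermo_model import load_model_spec, predict_mutant_series

logger = logging.getLogger(__name__)

STAGES = ("scan", "mutate", "predict", "normalize", "foldchange", "qpcr", "simulate")


class ConfigSchemaError(ValueError):
    pass


def _require(cfg: dict, field: str, typ, stage: str):
    if field not in cfg:
        raise ConfigSchemaError(
            f"stage {stage!r}: missing field {field!r} (expected {typ.__name__})"
        )
    val = cfg[field]
    if typ is float and isinstance(val, int):
        val = float(val)
    if not isinstance(val, typ):
        raise ConfigSchemaError(
            f"stage {stage!r}: field {field!r} must be {typ.__name__}, "
            f"got {type(val).__name__}"
        )
    return val


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _robust_config(cfg: dict) -> RobustConfig:
    keys = ("c_rho", "c_chi", "kappa", "xtol", "max_eval", "n_boot", "ci_level")
    return RobustConfig(**{k: cfg[k] for k in keys if k in cfg})


def run_pipeline(config_path) -> dict:
    """Execute the configured stage; returns the manifest (also written to
    ``<outdir>/manifest.json``).  Raises on any stage or schema error."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigSchemaError("config must be a mapping")
    stage = _require(cfg, "stage", str, "top-level")
    if stage not in STAGES:
        raise ConfigSchemaError(f"unknown stage {stage!r}; expected one of {STAGES}")
    outdir = Path(_require(cfg, "outdir", str, stage))
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    def track(path) -> Path:
        p = Path(path)
        inputs[str(p)] = _digest(p)
        return p

    if stage == "scan":
        fasta = track(_require(cfg, "fasta", str, stage))
        matrix_paths = _require(cfg, "matrices", list, stage)
        matrices = [read_count_matrix(track(p)) for p in matrix_paths]
        q_min = float(cfg.get("q_min", 0.01))
        for rec in read_fasta(fasta):
            sites = scan_sites(rec, matrices, q_min)
            (outdir / f"{rec.id}.sites.tsv").write_text(sites_to_bed(sites, rec.id))
    elif stage == "mutate":
        fasta = track(_require(cfg, "fasta", str, stage))
        matrix_paths = _require(cfg, "matrices", list, stage)
        matrices = [read_count_matrix(track(p)) for p in matrix_paths]
        q_min = float(cfg.get("q_min", 0.01))
        tf = _require(cfg, "tf", str, stage)
        records = read_fasta(fasta)
        mutants = []
        for rec in records:
            for site in scan_sites(rec, matrices, q_min):
                if site.tf_name == tf:
                    plan = design_site_mutation(rec, site, matrices, q_min)
                    rec = apply_mutation_plan(rec, plan)
            mutants.append(rec)
        write_fasta(mutants, outdir / "mutants.fasta")
    elif stage == "predict":
        fasta = track(_require(cfg, "fasta", str, stage))
        matrix_paths = _require(cfg, "matrices", list, stage)
        matrices = [read_count_matrix(track(p)) for p in matrix_paths]
        spec = load_model_spec(track(_require(cfg, "model_spec", str, stage)))
        records = {r.id: r for r in read_fasta(fasta)}
        promoter = records[_require(cfg, "promoter", str, stage)]
        conditions = _require(cfg, "conditions", list, stage)
        constructs = [("0", promoter, None)] + [
            (rid, promoter, rec) for rid, rec in records.items() if rec is not promoter
        ]
        folds = predict_mutant_series(constructs, spec, matrices, conditions)
        folds.to_csv(outdir / "predicted_folds.tsv", sep="\t", index=False)
    elif stage == "normalize":
        table = load_luminescence_table(
            track(_require(cfg, "luminescence", str, stage)), TableDialect()
        )
        rc = _robust_config(cfg)
        seed = cfg.get("seed")
        if cfg.get("ci", False) and seed is None:
            raise ConfigSchemaError(
                "stage 'normalize': field 'seed' (int) is required when ci=true"
            )
        rows = []
        for (construct, condition), _ in table.groupby(["construct", "condition"]):
            fit = group_slope(table, construct, condition, rc)
            row = {
                "construct": construct,
                "condition": condition,
                "beta": fit.beta,
                "scale": fit.scale,
                "n": fit.n,
                "converged": fit.converged,
            }
            if cfg.get("ci", False):
                g = table[
                    (table["construct"] == construct)
                    & (table["condition"] == condition)
                ]
                row["ci_low"], row["ci_high"] = bootstrap_ci(
                    g["renilla"], g["firefly"], rc, int(seed)
                )
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "slopes.tsv", sep="\t", index=False)
    elif stage == "foldchange":
        table = load_luminescence_table(
            track(_require(cfg, "luminescence", str, stage)), TableDialect()
        )
        rc = _robust_config(cfg)
        seed = _require(cfg, "seed", int, stage)
        mode = cfg.get("mode", "vs_uninduced_promoter")
        folds = []
        for (construct, condition), _ in table.groupby(["construct", "condition"]):
            folds.append(fold_change(table, construct, condition, mode, rc, seed))
        classes = {c.construct: c.label for c in classify_crm(folds)}
        pd.DataFrame(
            [
                {
                    "construct": f.construct,
                    "condition": f.condition,
                    "fold": f.value,
                    "ci_low": f.ci[0],
                    "ci_high": f.ci[1],
                    "class": classes[f.construct],
                }
                for f in folds
            ]
        ).to_csv(outdir / "folds.tsv", sep="\t", index=False)
    elif stage == "qpcr":
        df = pd.read_csv(track(_require(cfg, "qpcr", str, stage)))
        ct_target = cfg.get("ct_target", "Ct_target")
        ct_reference = cfg.get("ct_reference", "Ct_reference")
        if "uninduced_flag" not in df.columns and "oht" in df.columns:
            df["uninduced_flag"] = ~df["oht"].astype(bool)
        rel = qpcr_relative_expression(df, ct_target, ct_reference)
        rel.to_csv(outdir / "relative_expression.tsv", sep="\t", index=False)
        if "cytokine" in rel.columns:
            groups = rel[~rel["uninduced_flag"]].groupby("cytokine")
            if len(groups) == 2:
                (na, a), (nb, b) = list(groups)
                w, p = rank_sum_test(
                    a["relative_expression"], b["relative_expression"]
                )
                (outdir / "rank_sum.json").write_text(
                    json.dumps({"groups": [na, nb], "W": w, "p": p}, indent=2)
                )
    elif stage == "simulate":
        seed = _require(cfg, "seed", int, stage)
        beta = float(_require(cfg, "true_beta", float, stage))
        table, truth = simulate_luminescence(
            true_beta=beta,
            n=int(cfg.get("n", 10)),
            transfection_sdlog=float(cfg.get("transfection_sdlog", 0.35)),
            measurement_cv=float(cfg.get("measurement_cv", 0.1)),
            outlier_frac=float(cfg.get("outlier_frac", 0.0)),
            outlier_scale=float(cfg.get("outlier_scale", 10.0)),
            seed=seed,
        )
        table.rename(
            columns={
                "firefly": "Luc",
                "renilla": "Ren",
                "construct": "Construct",
                "condition": "Condition",
            }
        ).to_csv(outdir / "luminescence.csv", index=False)
        (outdir / "truth.json").write_text(
            json.dumps(
                {
                    "seed": truth.seed,
                    "true_slope": {f"{k[0]}|{k[1]}": v for k, v in truth.true_slope.items()},
                    "outlier_rows": list(truth.outlier_rows or ()),
                    "params": truth.params,
                },
                indent=2,
            )
        )

    manifest = {
        "stage": stage,
        "parameters": {k: v for k, v in cfg.items() if k != "stage"},
        "input_digests": inputs,
        "seed": cfg.get("seed"),
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
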