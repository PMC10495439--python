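"""Configuration, stage orchestration and run manifests.

Each stage reads and writes only documented TSV/JSON files inside the run
directory, so a run is fully described by its YAML configuration plus the
seed, and any stage can be re-executed in isolation once its inputs
exist.  Stage order: simulate -> meta -> screen -> rank -> score ->
evaluate -> profile.  A JSON run manifest (config snapshot, input
digests, timings, output inventory) is written atomically at the end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, efficacy, io, meta, screen, score, simulate, tme
from .stats import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "meta", "screen", "rank", "score", "evaluate", "profile")

#: file produced-by map used for dependency error messages
_PRODUCERS = {
    "trials.tsv": "simulate",
    "panel.tsv": "simulate",
    "sample_map.tsv": "simulate",
    "clinical.tsv": "simulate",
    "expression.tsv": "simulate",
    "cell_fractions.tsv": "simulate",
    "predictiveness_OS.tsv": "meta",
    "predictiveness_PFS.tsv": "meta",
    "medians.tsv": "screen",
    "screen.tsv": "screen",
    "interactions.tsv": "rank",
    "ps_model.json": "score",
    "scores.tsv": "score",
}


def default_config() -> dict:
    """Every tunable with its documented default."""
    return {
        "seed": 0,
        "preset": "paper-pattern",          # or "null"
        "simulation": {},                    # SimulationConfig overrides
        "meta": {"i2_threshold": 75.0},
        "screen": {"alpha": 0.05},
        "rank": {"endpoint": "OS", "biomarker": "CD274"},
        "score": {"gene": None,              # default: top-ranked gene
                  "reference": "TREATED_ARM"},
        "evaluate": {"mode": "IHC2",
                     "comparison": "POS_vs_NEG_within_ICI",
                     "reference": "TREATED_ARM",
                     "evaluable_only": False},
        "profile": {"reps": 200, "max_k": 6, "gmt": None,
                    "delta_area_threshold": 0.1},
    }


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        if val is not None:
            cfg[key] = val
    return cfg


def _sim_config(cfg: dict) -> simulate.SimulationConfig:
    maker = {"paper-pattern": simulate.paper_pattern_config,
             "null": simulate.null_config}.get(cfg.get("preset"))
    if maker is None:
        raise ValidationError(f"unknown preset '{cfg.get('preset')}'")
    return maker(seed=int(cfg.get("seed", 0)), **cfg.get("simulation", {}))


def _need(out_dir: Path, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = out_dir / name
        if not p.exists():
            producer = _PRODUCERS.get(name, "an earlier stage")
            raise ValidationError(
                f"missing input {p}; run the '{producer}' stage first")
        paths.append(p)
    return paths


def _stage_simulate(cfg: dict, out_dir: Path) -> list[Path]:
    sc = _sim_config(cfg)
    trials, truth_t = simulate.simulate_trial_table(sc)
    panel, sample_cancer, truth_p = simulate.simulate_expression_panel(sc)
    clinical, expression, truth_c = simulate.simulate_cohort(sc)
    fractions = simulate.simulate_cell_fractions(clinical, expression, sc)
    outputs = [
        io.write_tsv(trials, out_dir / "trials.tsv"),
        io.write_tsv(panel.reset_index(), out_dir / "panel.tsv"),
        io.write_tsv(sample_cancer.rename_axis("sample").reset_index(),
                     out_dir / "sample_map.tsv"),
        io.write_tsv(clinical, out_dir / "clinical.tsv"),
        io.write_tsv(expression.reset_index(), out_dir / "expression.tsv"),
        io.write_tsv(fractions.reset_index(), out_dir / "cell_fractions.tsv"),
    ]
    truth = {"trials": json.loads(truth_t.to_json()),
             "panel": json.loads(truth_p.to_json()),
             "cohort": json.loads(truth_c.to_json())}
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    outputs.append(truth_path)
    return outputs


def _stage_meta(cfg: dict, out_dir: Path) -> list[Path]:
    (trials_path,) = _need(out_dir, "trials.tsv")
    trials = io.read_tsv(trials_path, required=meta.TRIAL_COLUMNS)
    outputs = []
    for endpoint in ("OS", "PFS"):
        res = meta.compute_predictiveness(trials, endpoint,
                                          i2_threshold=cfg["meta"]["i2_threshold"])
        for cancer, reason in res.dropped.items():
            logger.info("meta: dropped %s (%s, %s)", cancer, endpoint, reason)
        outputs.append(io.write_tsv(res.table,
                                    out_dir / f"predictiveness_{endpoint}.tsv"))
    return outputs


def _read_predictiveness(out_dir: Path, endpoint: str) -> meta.PredictivenessResult:
    (p,) = _need(out_dir, f"predictiveness_{endpoint}.tsv")
    return meta.PredictivenessResult(table=io.read_tsv(p), endpoint=endpoint)


def _stage_screen(cfg: dict, out_dir: Path) -> list[Path]:
    panel_path, map_path = _need(out_dir, "panel.tsv", "sample_map.tsv")
    panel = io.read_panel(panel_path)
    sample_map = io.read_tsv(map_path, required=["sample", "cancer"])
    sample_cancer = sample_map.set_index("sample")["cancer"]
    pred_os = _read_predictiveness(out_dir, "OS")
    pred_pfs = _read_predictiveness(out_dir, "PFS")
    medians = screen.median_profile(panel, sample_cancer)
    screened = screen.cross_cancer_screen(medians, pred_os, pred_pfs,
                                          alpha=cfg["screen"]["alpha"])
    return [
        io.write_tsv(medians.reset_index(), out_dir / "medians.tsv"),
        io.write_tsv(screened, out_dir / "screen.tsv"),
    ]


def _stage_rank(cfg: dict, out_dir: Path) -> list[Path]:
    clin_path, expr_path, screen_path = _need(
        out_dir, "clinical.tsv", "expression.tsv", "screen.tsv")
    clinical = io.read_tsv(clin_path, required=["patient_id", "arm"])
    expression = io.read_panel(expr_path)
    screened = io.read_tsv(screen_path, required=["gene", "passes"])
    biomarker = cfg["rank"]["biomarker"]
    candidates = [g for g in screened[screened["passes"]]["gene"]
                  if g in expression.index and g != biomarker]
    if not candidates:
        candidates = [g for g in screened["gene"]
                      if g in expression.index and g != biomarker]
        logger.warning("rank: no screen-passing candidates; ranking all %d",
                       len(candidates))
    ici = clinical[clinical["arm"] == "ICI"]
    ranked = screen.rank_interactions(ici, expression, biomarker, candidates,
                                      endpoint=cfg["rank"]["endpoint"])
    return [io.write_tsv(ranked, out_dir / "interactions.tsv")]


def _stage_score(cfg: dict, out_dir: Path) -> list[Path]:
    inter_path, med_path, clin_path, expr_path = _need(
        out_dir, "interactions.tsv", "medians.tsv", "clinical.tsv",
        "expression.tsv")
    ranked = io.read_tsv(inter_path, required=["gene", "z"])
    medians = io.read_tsv(med_path).set_index("cancer")
    pred_os = _read_predictiveness(out_dir, "OS")
    gene = cfg["score"]["gene"] or str(ranked.iloc[0]["gene"])
    if gene not in medians.columns:
        raise ValidationError(f"score: gene '{gene}' absent from medians.tsv")
    model = score.fit_ps_model(medians[gene], pred_os.hrd_series(), gene=gene)
    clinical = io.read_tsv(clin_path, required=["patient_id", "arm"])
    expression = io.read_panel(expr_path)
    scores = score.score_and_split(clinical, expression, model,
                                   reference=cfg["score"]["reference"])
    model_path = out_dir / "ps_model.json"
    model_path.write_text(model.to_json())
    return [model_path, io.write_tsv(scores, out_dir / "scores.tsv")]


def _stage_evaluate(cfg: dict, out_dir: Path) -> list[Path]:
    clin_path, scores_path, expr_path = _need(
        out_dir, "clinical.tsv", "scores.tsv", "expression.tsv")
    clinical = io.read_tsv(clin_path, required=["patient_id", "arm", "os_time",
                                                "os_event"])
    scores = io.read_tsv(scores_path, required=["patient_id", "ps", "group"])
    expression = io.read_panel(expr_path)
    ev = cfg["evaluate"]
    strata, n_excluded = efficacy.stratify_pdl1(
        clinical, expression, ev["mode"], reference=ev["reference"])
    logger.info("evaluate: %d patients excluded (missing stratum field)",
                n_excluded)
    grid = efficacy.efficacy_grid(clinical, scores, strata, ev["comparison"],
                                  evaluable_only=ev["evaluable_only"])
    return [io.write_tsv(grid, out_dir / "efficacy.tsv")]


def _stage_profile(cfg: dict, out_dir: Path) -> list[Path]:
    (expr_path,) = _need(out_dir, "expression.tsv")
    expression = io.read_panel(expr_path)
    normalized = tme.normalize_expression(expression)
    if cfg["profile"]["gmt"]:
        sets = io.read_gmt(cfg["profile"]["gmt"])
    else:
        # default: score each gene family present (CD8 score when possible)
        sets = [tme.GeneSet("CD8_score", ("CD8A", "CD8B"))] \
            if {"CD8A", "CD8B"} & set(expression.index) else \
            [tme.GeneSet("panel_mean", tuple(expression.index[:50]))]
    scores_df, coverage = tme.signature_scores(normalized, sets)
    outputs = [io.write_tsv(scores_df.reset_index(),
                            out_dir / "signatures.tsv")]
    frac_path = out_dir / "cell_fractions.tsv"
    if frac_path.exists():
        fractions = io.read_tsv(frac_path).set_index("patient_id")
        res = tme.consensus_cluster(fractions,
                                    max_k=cfg["profile"]["max_k"],
                                    reps=cfg["profile"]["reps"],
                                    seed=int(cfg.get("seed", 0)),
                                    delta_area_threshold=cfg["profile"]
                                    ["delta_area_threshold"])
        subtype = tme.assign_immune_subtype(fractions,
                                            seed=int(cfg.get("seed", 0)),
                                            reps=cfg["profile"]["reps"])
        assign = pd.DataFrame({
            "sample": res.samples,
            "cluster": res.labels(),
            "chosen_k": res.chosen_k,
            "immune_subtype": subtype.to_numpy(),
        })
        cons = pd.DataFrame(res.matrix(), index=res.samples,
                            columns=res.samples)
        outputs += [
            io.write_tsv(assign, out_dir / "consensus_assignments.tsv"),
            io.write_tsv(cons.reset_index().rename(columns={"index": "sample"}),
                         out_dir / "consensus_matrix.tsv"),
        ]
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "meta": _stage_meta,
    "screen": _stage_screen,
    "rank": _stage_rank,
    "score": _stage_score,
    "evaluate": _stage_evaluate,
    "profile": _stage_profile,
}


def run_pipeline(config: dict | str | os.PathLike | None = None,
                 stages=STAGES, out_dir=".") -> dict:
    """Execute the requested stages in dependency order; write a manifest.

    ``config`` is a config dict (see :func:`default_config`) or a YAML
    path.  Returns the run manifest (also written to ``run_manifest.json``
    atomically).
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stage(s) {unknown}; valid: {STAGES}")
    ordered = [s for s in STAGES if s in stages]
    manifest = {
        "tool": "predscreen",
        "version": __version__,
        "seed": int(cfg.get("seed", 0)),
        "config": cfg,
        "stages": {},
        "outputs": {},
    }
    for stage in ordered:
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](cfg, out_dir)
        dt = time.perf_counter() - t0
        rows = {}
        for p in outputs:
            if p.suffix == ".tsv":
                with open(p) as fh:
                    rows[p.name] = sum(1 for _ in fh) - 1
        logger.info("stage %s: %.2fs, outputs=%s rows=%s", stage, dt,
                    [p.name for p in outputs], rows)
        manifest["stages"][stage] = {"seconds": round(dt, 3), "rows": rows}
        for p in outputs:
            manifest["outputs"][p.name] = io.file_digest(p)
    tmp = out_dir / "run_manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    os.replace(tmp, out_dir / "run_manifest.json")
    return manifest
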