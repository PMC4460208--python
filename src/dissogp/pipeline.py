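"""End-to-end workflow orchestration.

Runs the study's modeling chain in order — data acquisition (synthetic or
CSV), neural-network sweep, collective sensitivity analysis and input
reduction, symbolic regression (direct and Weibull-indirect), de-novo
multistage fitting, and leave-one-formulation-out cross-validation — from
a single YAML/dict config with one top-level seed.  Every stage writes its
artifacts under the output directory and contributes to a deterministic
JSON summary: rerunning with an identical config reproduces the summary
byte for byte.

Stage seeds derive from the top-level seed as
``(seed * 10007 + stage_index) % 2**31`` so stages are independently
reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import ann as ann_mod
from . import datasets as dsm
from . import gp as gp_mod
from . import sensitivity as sens_mod
from .fitting import crossval_fit, multistage_fit
from .models import fit_weibull_profile
from .synthetic import simulate_profiles

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "run_pipeline", "stage_seed"]

STAGE_ORDER = ("data", "ann", "sensitivity", "gp_direct", "gp_indirect",
               "fit", "crossval")


class ConfigError(ValueError):
    """Invalid or internally inconsistent pipeline configuration."""


def stage_seed(seed: int, stage: str) -> int:
    return (int(seed) * 10007 + STAGE_ORDER.index(stage)) % (2 ** 31)


def _validate(config: dict) -> dict:
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("outdir", "pipeline_out")
    stages = {s: dict(cfg.get("stages", {}).get(s, {})) for s in STAGE_ORDER}
    for s in STAGE_ORDER:
        stages[s].setdefault("enabled", False)
    data = dict(cfg.get("data", {"source": "synthetic"}))
    if data.get("source", "synthetic") not in ("synthetic", "csv"):
        raise ConfigError(f"unknown data source {data.get('source')!r}")
    if data.get("source") == "csv" and "path" not in data:
        raise ConfigError("data.source=csv requires data.path")
    enabled = [s for s in STAGE_ORDER if stages[s]["enabled"]]
    if enabled and not stages["data"]["enabled"]:
        raise ConfigError("every modeling stage depends on the data stage")
    if stages["sensitivity"]["enabled"] and not stages["ann"]["enabled"]:
        raise ConfigError("sensitivity analysis requires the ann stage")
    for g in ("gp_direct", "gp_indirect"):
        if (stages[g]["enabled"] and stages[g].get("use_reduced_inputs", True)
                and not stages["sensitivity"]["enabled"]):
            raise ConfigError(
                f"{g} with use_reduced_inputs needs the sensitivity stage "
                "(set use_reduced_inputs: false to run on raw inputs)"
            )
    cfg["stages"], cfg["data"] = stages, data
    return cfg


def _gp_config(opts: dict, seed: int, default_stop: float) -> gp_mod.GPConfig:
    return gp_mod.GPConfig(
        population_size=int(opts.get("population_size", 200)),
        size_limit=int(opts.get("size_limit", 30)),
        fitness_stop=float(opts.get("fitness_stop", default_stop)),
        max_generations=int(opts.get("max_generations", 15)),
        time_budget_s=opts.get("time_budget_s"),
        seed=seed,
    )


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute the enabled stages in study order; returns the summary dict.

    Raises ConfigError before touching any data if stage dependencies are
    unmet.  The summary (also written to ``<outdir>/summary.json``) holds
    each stage's key numbers; heavyweight artifacts (dataset CSV, model and
    tree JSON) are written alongside it.
    """
    cfg = _validate(config)
    outdir = Path(outdir if outdir is not None else cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    summary: dict = {"seed": seed, "stages_run": []}

    ds = None
    folds = None
    if stages["data"]["enabled"]:
        d = cfg["data"]
        if d.get("source", "synthetic") == "synthetic":
            ds = simulate_profiles(noise_sd=float(d.get("noise_sd", 1.0)),
                                   seed=stage_seed(seed, "data"))
        else:
            ds = dsm.read_dissolution_csv(d["path"])
        dsm.write_dissolution_csv(ds, outdir / "dataset.csv")
        folds = dsm.split_leave_one_formulation_out(ds)
        summary["stages_run"].append("data")
        summary["data"] = {"n_records": len(ds),
                           "n_formulations": len(ds.formulations),
                           "n_folds": len(folds),
                           "provenance": ds.provenance}

    ensemble, scaling = [], None
    if stages["ann"]["enabled"]:
        opts = stages["ann"]
        inputs = tuple(opts.get("inputs", ("d_mm", "L_mm", "t_min")))
        scaling = dsm.ScalingSpec.from_dataset(ds, columns=(*inputs, "Q_pct"))
        scaled = dsm.scale_linear(ds, scaling)
        sfolds = dsm.split_leave_one_formulation_out(scaled)
        fold = sfolds[0]
        records = []
        for a_i, layout in enumerate(opts.get("architectures", [[6], [10]])):
            mcfg = ann_mod.MLPConfig(
                hidden_layout=tuple(layout),
                activation=opts.get("activation", "tanh"),
                max_epochs=int(opts.get("max_epochs", 20_000)),
                stop_points=opts.get("stop_points", ann_mod.STOP_POINTS),
                seed=stage_seed(seed, "ann") + a_i,
            )
            model, trace = ann_mod.train_on_dataset(fold.train, mcfg,
                                                    inputs=inputs, test=fold.test)
            best = ann_mod.select_best_snapshot(trace, "test_rmse")
            best_rmse = min(s.test_rmse for s in trace.snapshots)
            ensemble.append(best)
            records.append({"hidden_layout": list(layout),
                            "best_epoch": best.epochs_trained,
                            # held-out RMSE also drives snapshot selection
                            # (selection-labelled, see methods note)
                            "test_rmse_scaled": round(float(best_rmse), 10)})
            (outdir / f"ann_{a_i}.json").write_text(best.to_json())
        summary["stages_run"].append("ann")
        summary["ann"] = {"inputs": list(inputs), "models": records}

    report = None
    if stages["sensitivity"]["enabled"]:
        opts = stages["sensitivity"]
        inputs = summary["ann"]["inputs"]
        scaled = dsm.scale_linear(ds, scaling)
        X = scaled.df.loc[:, inputs].to_numpy(dtype=float)
        report = sens_mod.collective_sensitivity(ensemble, X, tuple(inputs))
        retained = sens_mod.reduce_inputs(report,
                                          float(opts.get("threshold", 0.05)))
        (outdir / "sensitivity.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True))
        summary["stages_run"].append("sensitivity")
        summary["sensitivity"] = {**report.to_dict(), "retained": list(retained)}
        summary["sensitivity"]["mean_scores"] = [
            round(s, 10) for s in summary["sensitivity"]["mean_scores"]]

    if stages["gp_direct"]["enabled"]:
        opts = stages["gp_direct"]
        res = gp_mod.evolve_direct(ds, _gp_config(opts,
                                                  stage_seed(seed, "gp_direct"),
                                                  default_stop=1.0))
        (outdir / "gp_direct.json").write_text(res.tree.to_json())
        summary["stages_run"].append("gp_direct")
        summary["gp_direct"] = {"expression": str(res.tree),
                                "train_rmse": round(res.train_rmse, 10),
                                "size": res.tree.size,
                                "generations": res.generations}

    if stages["gp_indirect"]["enabled"]:
        opts = stages["gp_indirect"]
        rows = []
        for spec in ds.formulation_specs():
            prof = ds.profile(spec.formulation_id)
            p, fit_rmse = fit_weibull_profile(prof["t_min"], prof["Q_pct"])
            rows.append({"d": spec.d, "L": spec.L, "A": p.A, "K": p.K,
                         "rmse": fit_rmse})
        base = _gp_config(opts, stage_seed(seed, "gp_indirect"), 0.01)
        res_A, res_K = gp_mod.evolve_indirect(
            rows, cfg_A=base,
            cfg_K=gp_mod.GPConfig(**{**base.__dict__,
                                     "fitness_stop": float(opts.get("k_fitness_stop", 5.0)),
                                     "seed": base.seed + 1}))
        (outdir / "gp_indirect.json").write_text(json.dumps(
            {"A": json.loads(res_A.tree.to_json()),
             "K": json.loads(res_K.tree.to_json())}, sort_keys=True))
        summary["stages_run"].append("gp_indirect")
        summary["gp_indirect"] = {
            "weibull_table": [{k: round(float(v), 8) for k, v in r.items()}
                              for r in rows],
            "A_expression": str(res_A.tree), "A_rmse": round(res_A.train_rmse, 10),
            "K_expression": str(res_K.tree), "K_rmse": round(res_K.train_rmse, 10),
        }

    if stages["fit"]["enabled"]:
        opts = stages["fit"]
        out = {}
        for eq in opts.get("equations", ["eq7_direct"]):
            fr = multistage_fit(eq, ds, seed=stage_seed(seed, "fit"),
                                sann_evals=int(opts.get("sann_evals", 2000)))
            out[eq] = {"params": [round(float(p), 8) for p in fr.params],
                       "train_rmse": round(fr.train_rmse, 8),
                       "winning_method": fr.winning_method}
        summary["stages_run"].append("fit")
        summary["fit"] = out

    if stages["crossval"]["enabled"]:
        opts = stages["crossval"]
        out = {}
        for eq in opts.get("equations", ["eq7_direct"]):
            cv = crossval_fit(eq, folds,
                              preprocessing=opts.get("preprocessing", "original"),
                              seed=stage_seed(seed, "crossval"),
                              sann_evals=int(opts.get("sann_evals", 2000)))
            out[eq] = {
                "pooled_test_rmse": round(cv.pooled_test_rmse, 8),
                "param_cv_pct": [round(float(c), 8) for c in cv.param_cv_pct],
                "fold_params": [[round(float(p), 8) for p in r.params]
                                for r in cv.fold_results],
            }
        summary["stages_run"].append("crossval")
        summary["crossval"] = out

    text = json.dumps(summary, indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(text + "\n")
    return summary
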