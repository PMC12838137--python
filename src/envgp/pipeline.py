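"""End-to-end orchestration of the analysis pathways.

Four pathways mirror the study workflow: (1) genomic deduplication,
across-environment BLUEs and across-environment prediction benchmarks;
(2) within-environment model benchmarks (M_1..M_8) under the quadrant
cross-validation design; (3) core-set G-by-E patterns, environment
clustering and EV importance; (4) reference-set curation and
enviromically adapted selection gains.  Every stage writes CSV/JSON
artifacts plus a manifest naming the seed and configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enviromics import build_erms, cluster_environments, monthly_evs
from .genomics import build_grms, deduplicate, filter_markers, rogers_distance
from .gxe import cluster_gxe, ev_importance, extract_gxe_patterns, select_core_set
from .mixedmodel import build_model, estimate_blues, fit_gibbs, predict
from .selection import (
    curate_reference_set,
    enviromically_adapted,
    selection_gain,
)
from .simulate import SimConfig, simulate_study
from .validation import CVResult, prediction_ability, quadrant_plan

__all__ = ["PipelineConfig", "run_pipeline", "run_quadrant_cv", "predict_full_matrix"]


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (one YAML document)."""

    out_dir: str
    seed: int = 1
    sim: dict | None = None        # SimConfig keyword arguments
    inputs: dict | None = None     # or paths: markers, marker_map, catalog, weather, phenotypes
    models: list = field(default_factory=lambda: ["M_1", "M_2", "M_6"])
    stages: list = field(default_factory=lambda: ["blues", "cv", "cluster", "select"])
    cv: dict = field(default_factory=lambda: {"runs": 3, "min_genotypes_per_env": 20})
    mcmc: dict = field(default_factory=lambda: {"nIter": 1500, "burnIn": 300})
    clustering: dict = field(default_factory=lambda: {"k": "auto", "min_size": 3,
                                                      "core_size": 50})
    selection: dict = field(default_factory=lambda: {"top_frac": 0.07,
                                                     "random_frac": 0.03,
                                                     "adapted_frac": 0.10,
                                                     "overall_top_n": 20,
                                                     "rate": 0.32})
    importance: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of 'sim' or 'inputs' must be given")
        if self.inputs:
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"input {key!r}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# reusable workflow pieces
# ---------------------------------------------------------------------------
def _kernels_for(models, grms, erms):
    grm_a, grm_d, grm_aa = grms
    erm_l, erm_nl, yrm, srm = erms
    return {
        "GRM_a": grm_a, "GRM_d": grm_d, "GRM_aa": grm_aa,
        "ERM_l": erm_l, "ERM_nl": erm_nl, "YRM": yrm, "SRM": srm,
    }


def run_quadrant_cv(
    pheno: pd.DataFrame,
    kernels: dict,
    models: list,
    plan=None,
    env_meta: pd.DataFrame | None = None,
    gs_params: pd.DataFrame | None = None,
    runs: int = 3,
    min_genotypes_per_env: int = 20,
    seed: int = 1,
    mcmc: dict | None = None,
) -> dict:
    """Fit each model on every quadrant-CV run and score cv1..cv4.

    Returns ``{model_name: CVResult}``; one fit per (model, run) serves
    all four test cells.
    """
    mcmc = dict(mcmc or {})
    if plan is None:
        plan = quadrant_plan(
            pheno, min_genotypes_per_env=min_genotypes_per_env, runs=runs, seed=seed
        )
    data = plan.meta["data"]
    out = {}
    for model in models:
        records = []
        for run in plan.runs:
            train = data.iloc[run["train"]].reset_index(drop=True)
            spec = build_model(model, train, kernels, env_meta=env_meta,
                               gs_params=gs_params)
            fit = fit_gibbs(spec, seed=seed + run["run"], **mcmc)
            for cell, idx in run["tests"].items():
                test = data.iloc[idx]
                yhat = predict(fit, spec, test)
                scores = prediction_ability(
                    yhat, test["value"].to_numpy(), test["environment"].to_numpy()
                )
                for _, row in scores.iterrows():
                    records.append({"run": run["run"], "cell": cell, **row.to_dict()})
        out[model] = CVResult(model, pd.DataFrame(records))
    return out


def predict_full_matrix(
    pheno: pd.DataFrame,
    kernels: dict,
    genotypes,
    environments,
    model: str = "M_6",
    seed: int = 1,
    mcmc: dict | None = None,
) -> pd.DataFrame:
    """Train on all records and predict every genotype-environment cell."""
    spec = build_model(model, pheno, kernels)
    fit = fit_gibbs(spec, seed=seed, **(mcmc or {}))
    grid = pd.DataFrame(
        {
            "genotype": np.repeat(list(genotypes), len(environments)),
            "environment": np.tile(list(environments), len(genotypes)),
        }
    )
    yhat = predict(fit, spec, grid)
    return pd.DataFrame(
        yhat.reshape(len(genotypes), len(environments)),
        index=list(genotypes),
        columns=list(environments),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------
def _load_inputs(cfg: PipelineConfig):
    from .genomics import GenotypeCatalog, MarkerMatrix

    paths = cfg.inputs
    markers = MarkerMatrix.from_csv(paths["markers"], paths["marker_map"])
    catalog = GenotypeCatalog.from_csv(paths["catalog"])
    weather = pd.read_csv(paths["weather"])
    pheno = pd.read_csv(paths["phenotypes"])
    ev = monthly_evs(weather)
    return markers, catalog, weather, ev, pheno, None


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured pathways; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "version": __version__,
        "stages": {},
    }
    t0 = time.time()

    def _stage_done(name):
        manifest["stages"][name] = {"wall_time_s": round(time.time() - t0, 2)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    try:
        if cfg.sim is not None:
            sim_cfg = SimConfig(**{**cfg.sim, "seed": cfg.seed})
            markers, catalog, weather, ev, pheno, truth = simulate_study(sim_cfg)
            markers.to_csv(out / "markers.csv", out / "marker_map.csv")
            catalog.to_csv(out / "catalog.csv")
            pheno.to_csv(out / "phenotypes.csv", index=False)
            ev.to_csv(out / "ev_matrix.csv")
            if truth is not None:
                truth.to_json(out / "truth.json")
            _stage_done("simulate")
        else:
            markers, catalog, weather, ev, pheno, truth = _load_inputs(cfg)

        markers = filter_markers(markers)
        dist = rogers_distance(markers)
        dedup = deduplicate(dist)
        dist.to_csv(out / "rogers_distance.csv")
        pd.Series(dedup.mapping, name="canonical").to_csv(
            out / "duplicates.csv", index_label="genotype"
        )
        _stage_done("qc")

        grms = build_grms(markers)
        erms = build_erms(ev)
        kernels = _kernels_for(cfg.models, grms, erms)
        for k in kernels.values():
            k.to_csv(out / f"kernel_{k.kind}.csv")
        _stage_done("kernels")

        if "blues" in cfg.stages:
            blues = estimate_blues(pheno, dedup, seed=cfg.seed)
            blues.to_csv(out / "blues.csv")
            _stage_done("blues")
        else:
            blues = None

        if "cv" in cfg.stages:
            results = run_quadrant_cv(
                pheno, kernels, cfg.models, seed=cfg.seed,
                mcmc=cfg.mcmc, **cfg.cv,
            )
            summary = pd.DataFrame(
                {
                    m: res.records.groupby("cell")["r"].mean()
                    for m, res in results.items()
                }
            )
            summary.to_csv(out / "cv_summary.csv")
            for m, res in results.items():
                res.records.to_csv(out / f"cv_{m}.csv", index=False)
            _stage_done("cv")

        if "cluster" in cfg.stages:
            core_size = min(cfg.clustering.get("core_size", 50),
                            dist.n - 1)
            core = select_core_set(dist, n=core_size)
            pred = predict_full_matrix(
                pheno, kernels, core, ev.environments, seed=cfg.seed,
                mcmc=cfg.mcmc,
            )
            patterns = extract_gxe_patterns(pred, seed=cfg.seed)
            assignment = cluster_gxe(
                patterns, k=cfg.clustering.get("k", "auto"),
                min_size=cfg.clustering.get("min_size", 3), seed=cfg.seed,
            )
            assignment.assignment.to_csv(out / "environment_clusters.csv")
            cluster_environments(ev).write_newick(out / "ev_tree.nwk")
            imp_kwargs = {"n_estimators": 300, **cfg.importance}
            try:
                imp = ev_importance(ev, assignment, **imp_kwargs)
                imp.long.to_csv(out / "ev_importance.csv", index=False)
                manifest["ev_accuracy"] = imp.accuracy
            except ValueError as exc:
                manifest["ev_importance_skipped"] = str(exc)
            _stage_done("cluster")
        else:
            assignment = None

        if "select" in cfg.stages:
            if blues is None:
                blues = estimate_blues(pheno, dedup, seed=cfg.seed)
            sel = cfg.selection
            ref = curate_reference_set(
                blues["blue"], sel.get("top_frac", 0.07),
                sel.get("random_frac", 0.03), seed=cfg.seed,
            )
            pred_ref = predict_full_matrix(
                pheno, kernels, list(ref.index), ev.environments,
                seed=cfg.seed, mcmc=cfg.mcmc,
            )
            adapted = enviromically_adapted(pred_ref, sel.get("adapted_frac", 0.10))
            report = selection_gain(
                pred_ref, list(ref.index), adapted, blues=blues["blue"],
                overall_top_n=min(sel.get("overall_top_n", 20), len(ref)),
                rate=sel.get("rate", 0.32),
            )
            report.to_csv(out / "selection_gain.csv")
            manifest["mean_boost"] = report.mean_boost
            _stage_done("select")
    except Exception as exc:
        manifest["failed_stage"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
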