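"""Configuration-driven orchestration of the full synthetic analysis.

``run_pipeline`` executes the stages in order — simulate surveys, compute
catch metrics, fit the algorithm roster, evaluate, ensemble, project onto
delta-corrected scenario layers, and account range change — writing every
table as CSV, every raster as NetCDF, and a JSON metrics file into a run
directory stamped with the configuration hash. Every stochastic step
draws from a seed recorded in the configuration, so re-running the same
config reproduces identical outputs.
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

from loligosdm.ensemble import build_ensemble, importance_table, response_curve
from loligosdm.evaluation import evaluate, split
from loligosdm.grids import GridSpec, stack_mean
from loligosdm.models import ALGORITHM_IDS, fit
from loligosdm.range_change import binarize, habitat_area, range_change
from loligosdm.scenarios import (
    SCENARIOS,
    ScenarioSpec,
    delta_correct_stack,
    project,
    scenario_shift,
)
from loligosdm.survey import env_range_summary, seasonal_summary, write_survey_csv
from loligosdm.synthetic import (
    SEASONS,
    GaussianResponse,
    NicheSpec,
    ScenarioDelta,
    generate_env_stack,
    generate_scenario_layers,
    simulate_survey,
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, seeds included.

    ``niche`` maps covariate name -> {"optimum": float, "breadth": float};
    unlisted covariates are flat. ``seeds`` must carry the four stage
    seeds (simulation, split, fit, permutation).
    """

    species: str = "synthetic-loliginid"
    covariates: list[str] = field(default_factory=lambda: ["sst", "sbt", "sss", "sbs"])
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHM_IDS))
    test_fraction: float = 0.2
    auc_gate: float = 0.8
    sre_q: float = 0.025
    n_permutations: int = 10
    seeds: dict[str, int] = field(
        default_factory=lambda: {"simulation": 1, "split": 2, "fit": 3, "permutation": 4}
    )
    scenarios: list[str] = field(default_factory=lambda: [s.label for s in SCENARIOS])
    threshold_strategy: str = "max_tss"
    grid: dict[str, float] = field(default_factory=dict)
    n_stations: int = 150
    niche: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"sbt": {"optimum": 20.0, "breadth": 2.0}}
    )
    detection_scale: float = 10.0
    dispersion: float = 2.0
    gcm_bias: dict[str, float] = field(
        default_factory=lambda: {"sst": 0.8, "sbt": 0.8, "sss": -0.3, "sbs": -0.3}
    )
    gcm_noise_sd: float = 0.1
    write_maps: bool = True

    # ---- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def grid_spec(self) -> GridSpec:
        return GridSpec(**self.grid) if self.grid else GridSpec()

    def niche_spec(self) -> NicheSpec:
        responses = {
            c: GaussianResponse(optimum=d["optimum"], breadth=d["breadth"])
            for c, d in self.niche.items()
        }
        return NicheSpec(
            responses=responses,
            detection_scale=self.detection_scale,
            dispersion=self.dispersion,
        )


def _scenario_by_label(label: str) -> ScenarioSpec:
    for s in SCENARIOS:
        if s.label == label:
            return s
    raise ValueError(f"unknown scenario label {label!r}")


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage and return the populated run directory.

    Stage failures raise with the stage named; an empty AUC gate
    propagates as :class:`loligosdm.ensemble.EmptyEnsembleError`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.perf_counter()

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{time.perf_counter() - t0:8.2f}s] {stage}: {msg}")

    cfg_hash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")
    log("config", f"hash={cfg_hash}")

    # ---- stage: data ----------------------------------------------------
    spec = config.grid_spec()
    niche = config.niche_spec()
    sim_seed = int(config.seeds["simulation"])
    stacks = {}
    surveys = []
    for i, season in enumerate(SEASONS):
        stack = generate_env_stack(spec, season=season, seed=sim_seed + i)
        stacks[season] = stack
        surveys.append(
            simulate_survey(stack, niche, n_stations=config.n_stations, seed=sim_seed + 100 + i)
        )
    survey = pd.concat(surveys, ignore_index=True)
    survey["station_id"] = np.arange(len(survey))
    survey["presence"] = (survey["count"] > 0).astype(int)
    write_survey_csv(survey, outdir / "survey.csv")
    annual = stack_mean(list(stacks.values()), season="annual")
    log("data", f"{len(survey)} stations over {len(SEASONS)} seasons; "
        f"prevalence={survey['presence'].mean():.2f}")

    # ---- stage: metrics -------------------------------------------------
    summary = seasonal_summary(survey)
    summary.to_frame().to_csv(outdir / "seasonal_summary.csv")
    env_range_summary(survey).to_csv(outdir / "env_ranges.csv")
    log("metrics", f"grand total CPUEw={summary.grand_total_cpue_w:.2f} g/h")

    # ---- stage: fit + evaluate ------------------------------------------
    occ = survey[["presence", *config.covariates]].dropna().reset_index(drop=True)
    train, test = split(
        occ, test_fraction=config.test_fraction, seed=int(config.seeds["split"])
    )
    models, reports = {}, []
    for algo in config.algorithms:
        hp = {"q": config.sre_q} if algo == "SRE" else {}
        model = fit(algo, train, config.covariates, hyperparams=hp,
                    seed=int(config.seeds["fit"]))
        models[algo] = model
        rep = evaluate(model, test, split_seed=int(config.seeds["split"]),
                       test_fraction=config.test_fraction)
        reports.append(rep)
        log("evaluate", f"{algo}: AUC={rep.auc:.3f} TSS={rep.tss:.3f}")
    pd.DataFrame([asdict(r) for r in reports]).to_csv(
        outdir / "eval_reports.csv", index=False
    )

    # ---- stage: ensemble ------------------------------------------------
    ens = build_ensemble(models, reports, test, auc_min=config.auc_gate)
    member_ids = [m.algorithm for m in ens.members]
    log("ensemble", f"members={member_ids} threshold={ens.threshold:.3f}")
    with open(outdir / "ensemble.json", "w") as fh:
        json.dump(
            {
                "members": member_ids,
                "weights": ens.weights.tolist(),
                "member_aucs": ens.member_aucs,
                "auc_gate": ens.auc_gate,
                "threshold": ens.threshold,
            },
            fh, indent=2,
        )
    diag_models = {**{k: models[k] for k in member_ids}, "ensemble": ens}
    imp = importance_table(
        diag_models, occ[config.covariates], config.covariates,
        n_perm=config.n_permutations, seed=int(config.seeds["permutation"]),
    )
    imp.to_csv(outdir / "importance.csv")
    curves = []
    for c in config.covariates:
        cur = response_curve(ens, occ[config.covariates], c)
        cur.insert(0, "covariate", c)
        curves.append(cur)
    pd.concat(curves, ignore_index=True).to_csv(outdir / "response_curves.csv", index=False)

    # ---- stage: project -------------------------------------------------
    baseline_map = project(ens, annual, scenario="baseline")
    if config.write_maps:
        baseline_map.to_netcdf(outdir / "suitability_baseline.nc")
    current_bin = binarize(baseline_map, ens.threshold)
    log("project", f"baseline suitable cells={current_bin.n_suitable}/{baseline_map.n_sea}")

    rows = []
    for k, label in enumerate(config.scenarios):
        sspec = _scenario_by_label(label)
        delta = ScenarioDelta(
            shift=scenario_shift(sspec, config.covariates),
            gcm_bias=config.gcm_bias,
            noise_sd=config.gcm_noise_sd,
        )
        gcm_base, gcm_fut, _truth_fut = generate_scenario_layers(
            annual, delta, seed=sim_seed + 1000 + k
        )
        corrected = delta_correct_stack(annual, gcm_base, gcm_fut)
        smap = project(ens, corrected, scenario=label)
        if config.write_maps:
            smap.to_netcdf(outdir / f"suitability_{label}.nc")
        fut_bin = binarize(smap, ens.threshold)
        rep = range_change(current_bin, fut_bin, scenario=label)
        rows.append({
            "scenario": label,
            "loss_pct": rep.loss_pct,
            "gain_pct": rep.gain_pct,
            "net_pct": rep.net_pct,
            "kept": rep.kept,
            "lost": rep.lost,
            "gained": rep.gained,
            "current_total": rep.current_total,
            "current_area_km2": rep.current_area_km2,
            "future_area_km2": rep.future_area_km2,
        })
        log("range_change", f"{label}: loss={rep.loss_pct:.2f}% gain={rep.gain_pct:.2f}%")
    rc = pd.DataFrame(rows)
    rc.to_csv(outdir / "range_change.csv", index=False)

    metrics = {
        "config_hash": cfg_hash,
        "species": config.species,
        "n_stations": int(len(survey)),
        "prevalence": float(survey["presence"].mean()),
        "grand_total_cpue_w": summary.grand_total_cpue_w,
        "grand_total_cpue_n": summary.grand_total_cpue_n,
        "ensemble_members": member_ids,
        "ensemble_threshold": float(ens.threshold),
        "member_aucs": {k: float(v) for k, v in ens.member_aucs.items()},
        "baseline_suitable_cells": int(current_bin.n_suitable),
        "baseline_area_km2": float(habitat_area(current_bin)),
        "range_change": {
            r["scenario"]: {k: r[k] for k in ("loss_pct", "gain_pct", "net_pct")}
            for r in rows
        },
    }
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    log("done", f"total {time.perf_counter() - t0:.1f}s")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


REQUIRED_OUTPUTS = [
    "config.yaml", "survey.csv", "seasonal_summary.csv", "env_ranges.csv",
    "eval_reports.csv", "ensemble.json", "importance.csv",
    "response_curves.csv", "range_change.csv", "metrics.json",
]


def report(run_dir) -> dict:
    """Load a completed run's tables and metrics, checking consistency.

    Returns a dict of DataFrames plus the parsed metrics JSON. Raises if
    the run is incomplete or the JSON disagrees with the CSV tables.
    """
    run_dir = Path(run_dir)
    missing = [f for f in REQUIRED_OUTPUTS if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing {missing}")
    out = {
        "config": RunConfig.from_yaml(run_dir / "config.yaml"),
        "survey": pd.read_csv(run_dir / "survey.csv"),
        "seasonal_summary": pd.read_csv(run_dir / "seasonal_summary.csv", index_col=0),
        "env_ranges": pd.read_csv(run_dir / "env_ranges.csv", index_col=0),
        "eval_reports": pd.read_csv(run_dir / "eval_reports.csv"),
        "importance": pd.read_csv(run_dir / "importance.csv", index_col=0),
        "response_curves": pd.read_csv(run_dir / "response_curves.csv"),
        "range_change": pd.read_csv(run_dir / "range_change.csv"),
    }
    with open(run_dir / "metrics.json") as fh:
        out["metrics"] = json.load(fh)

    rc = out["range_change"]
    if not np.allclose(rc["net_pct"], rc["gain_pct"] + rc["loss_pct"]):
        raise ValueError("range-change CSV violates net = gain + loss")
    for _, row in rc.iterrows():
        jm = out["metrics"]["range_change"][row["scenario"]]
        if not np.isclose(jm["net_pct"], row["net_pct"]):
            raise ValueError("metrics JSON disagrees with range-change CSV")
    seas = out["seasonal_summary"]
    body = seas.drop(index="total")
    if not np.isclose(seas.loc["total", "total_cpue_w"], body["total_cpue_w"].sum()):
        raise ValueError("seasonal summary total row inconsistent")
    return out
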