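"""End-to-end orchestration: simulate -> match -> filter -> fit -> split
-> gam -> centroids.

Each stage reads and writes plain files (CSV tables, CF NetCDF rasters,
JSON reports) under the configured output directory, so any stage can be
re-run or replaced with real inputs of the same schema.  A manifest
records per-stage content hashes; a stage is skipped when its inputs,
configuration and outputs are unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, centroids as cen, envmatch, gam, infer, synth, zoib

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "match", "filter", "fit", "split", "gam", "centroids"]


@dataclass
class PipelineConfig:
    """Declarative settings for the whole analysis.

    Defaults mirror the reference study conditions: collinearity
    threshold 0.7, four MCMC chains of 4000 iterations with a 2000-draw
    burn-in, five spatially blocked CV folds, 100 posterior predictive
    replicates, and 95% intervals throughout.
    """

    outdir: str = "runs/default"
    seed: int = 0
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    # matching / collinearity
    collinearity_threshold: float = 0.7
    priority: list[str] = field(default_factory=lambda: list(envmatch.DEFAULT_PRIORITY))
    # sampling events
    n_individuals: int = 1000
    subsample_fraction: float = 0.5
    # ZOIB fit
    method: str = "map"  # "map" or "mcmc" (MCMC adds diagnostics + PPC)
    chains: int = 4
    iterations: int = 4000
    burn_in: int = 2000
    prior_scale: float = 1.0
    sigma_u: float = 0.5
    n_ppc: int = 100
    # cross-validation
    cv_k: int = 5
    cv_blocking: str = "spatial_block"
    # GAM
    gam_k: int = 10
    gam_grid: int = 100
    # centroids
    bootstrap_B: int = 1000
    ci_level: float = 0.95
    min_records_per_year: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.collinearity_threshold <= 1:
            raise ValueError("collinearity threshold must lie in (0, 1]")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        # the master seed feeds every stage substream
        self.sim.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        tp = sim_raw.pop("true_params", None)
        sim = synth.SimConfig(**sim_raw)
        if tp:
            sim.true_params = zoib.ZOIBParams(**tp)
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        tp = d["sim"]["true_params"]
        for k, v in tp.items():
            if isinstance(v, np.ndarray):
                tp[k] = v.tolist()
        return d


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]


class _Run:
    """Shared state for one pipeline invocation."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"stages": {}}
        self.manifest["config"] = config.to_dict()
        self.manifest["config_hash"] = _hash_obj(config.to_dict())
        self.manifest["version"] = __version__

    def save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, default=str))

    def path(self, name: str) -> Path:
        return self.out / name


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(run: _Run) -> list[Path]:
    cfg = run.config
    fields = synth.generate_env_fields(cfg.sim)
    written = fields.to_netcdf(run.path("fields"))
    logbook = synth.generate_logbook(cfg.sim, fields)
    events = synth.generate_sampling_events(
        logbook, cfg.n_individuals, cfg.subsample_fraction, seed=cfg.seed
    )
    p1 = synth.write_logbook_csv(logbook, run.path("logbook.csv"))
    p2 = synth.write_events_csv(events, run.path("events.csv"))
    return written + [p1, p2]


def _stage_match(run: _Run) -> list[Path]:
    fields = envmatch.EnvFieldSet.from_netcdf(run.path("fields"))
    # CHLA arrives on its coarse native grid; bring it to the fine grid first
    fine = next(f for f in fields if f.variable == "SST")
    regridded = envmatch.EnvFieldSet(
        [
            envmatch.regrid(f, fine.lon, fine.lat) if f.variable == "CHLA" else f
            for f in fields
        ]
    )
    out = []
    for name in ("logbook", "events"):
        df = pd.read_csv(run.path(f"{name}.csv"))
        matched = envmatch.match(
            df[[c for c in df.columns if c not in envmatch.VARIABLES]],
            regridded,
        )
        path = run.path(f"matched_{name}.csv")
        matched.to_csv(path, index=False)
        out.append(path)
    return out


def _stage_filter(run: _Run) -> list[Path]:
    cfg = run.config
    matched = pd.read_csv(run.path("matched_logbook.csv"))
    retained, corr = envmatch.correlation_filter(
        matched,
        envmatch.VARIABLES,
        threshold=cfg.collinearity_threshold,
        priority=cfg.priority,
    )
    p1 = run.path("retained_variables.json")
    p1.write_text(json.dumps({"retained": retained}, indent=2))
    p2 = run.path("correlation_matrix.csv")
    corr.to_csv(p2)
    return [p1, p2]


def _load_training(run: _Run):
    cfg = run.config
    retained = json.loads(run.path("retained_variables.json").read_text())["retained"]
    events = pd.read_csv(run.path("matched_events.csv"))
    data, scaler = zoib.make_design(
        events, retained, response="proportion_blue", block_size=cfg.sim.block_size
    )
    return retained, events, data, scaler


def _stage_fit(run: _Run) -> list[Path]:
    cfg = run.config
    retained, events, data, scaler = _load_training(run)
    init = infer.default_init(data, prior_scale=cfg.prior_scale, sigma_u=cfg.sigma_u)
    map_fit = infer.fit_map(data, init=init)
    report = infer.FitReport(map_estimate=map_fit.params)
    outputs = []
    if cfg.method == "mcmc":
        draws = infer.fit_mcmc(
            data,
            chains=cfg.chains,
            iterations=cfg.iterations,
            burn_in=cfg.burn_in,
            seed=cfg.seed,
            map_fit=map_fit,
        )
        report.rhat = infer.rhat(draws)
        ppc = infer.posterior_predictive(
            draws, data, map_fit.params, n_rep=cfg.n_ppc, seed=cfg.seed
        )
        report.ppc_summary = ppc.summary
    report.cv_metrics = infer.kfold_cv(
        data, k=cfg.cv_k, blocking=cfg.cv_blocking, seed=cfg.seed, init=init
    )
    payload = report.to_dict()
    payload["map_estimate"] = {
        "beta_mu": map_fit.params.beta_mu.tolist(),
        "beta_phi": map_fit.params.beta_phi.tolist(),
        "beta_zoi": map_fit.params.beta_zoi.tolist(),
        "beta_coi": map_fit.params.beta_coi.tolist(),
        "sigma_u": map_fit.params.sigma_u,
        "covariates": ["intercept"] + retained,
    }
    payload["scaler"] = {"mean": scaler[0].tolist(), "sd": scaler[1].tolist()}
    payload["seed"] = cfg.seed
    p = run.path("fit_report.json")
    p.write_text(json.dumps(payload, indent=2, default=float))
    outputs.append(p)
    return outputs


def _stage_split(run: _Run) -> list[Path]:
    cfg = run.config
    payload = json.loads(run.path("fit_report.json").read_text())
    est = payload["map_estimate"]
    retained = est["covariates"][1:]
    params = zoib.ZOIBParams(
        est["beta_mu"], est["beta_phi"], est["beta_zoi"], est["beta_coi"],
        sigma_u=est["sigma_u"], prior_scale=cfg.prior_scale,
    )
    scaler = (
        np.asarray(payload["scaler"]["mean"]),
        np.asarray(payload["scaler"]["sd"]),
    )
    logbook = pd.read_csv(run.path("matched_logbook.csv"))
    data, _ = zoib.make_design(
        logbook, retained, block_size=cfg.sim.block_size, standardizer=scaler
    )
    # random effects are location-specific to the training blocks; pooled
    # prediction uses the population-level (u = 0) mean
    p_blue = zoib.predict_mean(params, data.X)
    split = infer.split_catch_table(logbook, p_blue)
    p = run.path("split_catch.csv")
    split.to_csv(p, index=False)
    return [p]


def _stage_gam(run: _Run) -> list[Path]:
    cfg = run.config
    retained = json.loads(run.path("retained_variables.json").read_text())["retained"]
    split = pd.read_csv(run.path("split_catch.csv"))
    outputs = []
    summaries = []
    ranges = {}
    for species, col in (("blue", "blue_per_set"), ("chub", "chub_per_set")):
        y = gam.log1p_response(split[col])
        fit = gam.fit_additive(y, split[retained], k=cfg.gam_k)
        summ = fit.summary()
        summ.insert(1, "species", species)
        summaries.append(summ)
        curves = []
        ranges[species] = {}
        for var in retained:
            pe = gam.partial_effect(fit, var, cfg.gam_grid)
            opt = gam.optimal_range(pe)
            ranges[species][var] = {
                "lower": opt.lower, "upper": opt.upper, "informative": opt.informative,
            }
            curves.append(
                pd.DataFrame(
                    {"variable": var, "x": pe.grid, "effect": pe.effect,
                     "lower": pe.lower, "upper": pe.upper}
                )
            )
        pc = run.path(f"gam_partial_effects_{species}.csv")
        pd.concat(curves).to_csv(pc, index=False)
        outputs.append(pc)
        ranges[species]["_model"] = {
            "r_squared_adj": fit.r_squared,
            "deviance_explained": fit.deviance_explained,
        }
    ps = run.path("gam_summary.csv")
    pd.concat(summaries).to_csv(ps, index=False)
    pr = run.path("gam_optimal_ranges.json")
    pr.write_text(json.dumps(ranges, indent=2))
    return outputs + [ps, pr]


def _stage_centroids(run: _Run) -> list[Path]:
    cfg = run.config
    split = pd.read_csv(run.path("split_catch.csv"))
    split["p_chub"] = 1.0 - split["p_blue"]
    outputs = []
    series = {}
    trends = {}
    for species, wcol in (("blue", "p_blue"), ("chub", "p_chub")):
        s = cen.annual_centroids(
            split, wcol, B=cfg.bootstrap_B, level=cfg.ci_level,
            seed=cfg.seed, min_records=cfg.min_records_per_year,
        )
        series[species] = s
        p = run.path(f"centroids_{species}.csv")
        s.to_csv(p, index=False)
        outputs.append(p)
        trends[species] = {
            "lat": cen.ols_trend(s["year"], s["lat"]).to_dict(),
            "lon": cen.ols_trend(s["year"], s["lon"]).to_dict(),
        }
    dist, dist_trend = cen.centroid_distance_series(series["blue"], series["chub"])
    pd_path = run.path("centroid_distance.csv")
    dist.to_csv(pd_path, index=False)
    trends["distance_km"] = dist_trend.to_dict()
    pt = run.path("centroid_trends.json")
    pt.write_text(json.dumps(trends, indent=2, default=float))
    return outputs + [pd_path, pt]


_STAGE_FUNCS = {
    "simulate": (_stage_simulate, []),
    "match": (_stage_match, ["logbook.csv", "events.csv"]),
    "filter": (_stage_filter, ["matched_logbook.csv"]),
    "fit": (_stage_fit, ["matched_events.csv", "retained_variables.json"]),
    "split": (_stage_split, ["matched_logbook.csv", "fit_report.json"]),
    "gam": (_stage_gam, ["split_catch.csv", "retained_variables.json"]),
    "centroids": (_stage_centroids, ["split_catch.csv"]),
}


def run_pipeline(
    config: PipelineConfig, stages: list[str] | None = None, force: bool = False
) -> dict:
    """Execute the pipeline stages in order, skipping stages whose inputs,
    config and outputs are unchanged (content-hash check).

    Returns the run manifest; partial outputs are retained on failure and
    the failing stage named in the raised exception.
    """
    run = _Run(config)
    for stage in stages or STAGES:
        func, input_names = _STAGE_FUNCS[stage]
        inputs = [run.path(n) for n in input_names]
        missing = [p for p in inputs if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"stage '{stage}': missing inputs {[str(p) for p in missing]}"
            )
        stage_hash = _hash_obj(
            {"stage": stage, "config": run.manifest["config_hash"],
             "inputs": _hash_files(inputs)}
        )
        prev = run.manifest["stages"].get(stage)
        outputs_exist = prev and all(Path(o).exists() for o in prev["outputs"])
        if not force and prev and prev["hash"] == stage_hash and outputs_exist:
            logger.info("stage %s: up to date, skipping", stage)
            continue
        logger.info("stage %s: running", stage)
        t0 = time.time()
        try:
            outputs = func(run)
        except Exception as exc:
            run.save_manifest()
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        run.manifest["stages"][stage] = {
            "hash": stage_hash,
            "outputs": [str(o) for o in outputs],
            "elapsed_s": round(time.time() - t0, 3),
            "seed": config.seed,
        }
        run.save_manifest()
    run.save_manifest()
    return run.manifest


# ---------------------------------------------------------------------------
# input validation

def validate_inputs(paths: dict) -> list[dict]:
    """Schema and roster checks for pipeline inputs.

    ``paths`` may contain ``logbook`` and ``events`` (CSV) and
    ``fields_dir`` (directory of per-variable NetCDF files).  Returns a
    list of machine-readable findings; empty means all checks passed.
    """
    findings: list[dict] = []

    def add(severity, message, location):
        findings.append({"severity": severity, "message": message, "location": location})

    if "logbook" in paths:
        path = Path(paths["logbook"])
        try:
            df = pd.read_csv(path)
        except OSError as exc:
            raise OSError(f"cannot read logbook file {path}: {exc}") from exc
        for col in ("vessel_id", "date", "lon", "lat", "sets", "mixed_catch_kg"):
            if col not in df.columns:
                add("error", f"missing required column '{col}'", str(path))
        if "mixed_catch_kg" in df.columns:
            bad = df.index[df["mixed_catch_kg"] < 0]
            for i in bad:
                add("error", f"negative catch in column 'mixed_catch_kg' at row {i}", str(path))
        if "sets" in df.columns and (df["sets"] < 1).any():
            add("error", "haul counts below 1 in column 'sets'", str(path))

    if "events" in paths:
        path = Path(paths["events"])
        df = pd.read_csv(path)
        for col in ("date", "lon", "lat", "n_individuals", "n_blue", "n_chub"):
            if col not in df.columns:
                add("error", f"missing required column '{col}'", str(path))
        if {"n_individuals", "n_blue", "n_chub"} <= set(df.columns):
            bad = df.index[df["n_blue"] + df["n_chub"] != df["n_individuals"]]
            for i in bad:
                add("error", f"species counts do not sum to n_individuals at row {i}", str(path))

    if "fields_dir" in paths:
        d = Path(paths["fields_dir"])
        present = {p.stem for p in d.glob("*.nc")}
        for var in envmatch.VARIABLES:
            if var not in present:
                add("error", f"environmental roster missing variable '{var}'", str(d))
        fields = envmatch.EnvFieldSet.from_netcdf(d)
        for f in fields:
            if not (-90 <= f.lat.min() and f.lat.max() <= 90):
                add("error", f"{f.variable} latitude axis outside [-90, 90]", str(d))
            if not (-180 <= f.lon.min() and f.lon.max() < 360):
                add("error", f"{f.variable} longitude axis outside [-180, 360)", str(d))
        if "logbook" in paths and len(fields):
            df = pd.read_csv(paths["logbook"])
            days = set(pd.to_datetime(df["date"]).dt.date)
            missing_days = days - set(fields.dates)
            if missing_days:
                add(
                    "error",
                    f"{len(missing_days)} record dates lack environmental fields",
                    str(d),
                )
    return findings
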