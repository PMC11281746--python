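"""Configured, seeded, resumable analysis pipeline.

Stages run in dependency order

    simulate -> deprivation -> map -> scan -> global_fit -> svc

each reading the artifacts of its upstream stages from the output directory
and writing standard text formats (GeoJSON for geometry, CSV for tables,
JSON for configs/reports).  A manifest records per-stage parameter hashes,
outputs and wall time; re-running an unchanged stage is a no-op.  All float
columns are written at 6 significant digits so identical configs and seeds
produce byte-identical artifacts across machines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import spatialenroll
from spatialenroll import deprivation as deprivation_mod
from spatialenroll import disease_mapping, global_regression, scan_statistic, svc_regression
from spatialenroll import spatial_structure, synthetic_region

log = logging.getLogger("spatialenroll.pipeline")

STAGES = ["simulate", "deprivation", "map", "scan", "global_fit", "svc"]
FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """One JSON document with per-stage parameter blocks."""

    seed: int = 0
    output_dir: str = "spatialenroll_out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulate: dict = field(default_factory=dict)
    map: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    global_fit: dict = field(default_factory=dict)
    svc: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = json.load(fh)
        bad = [k for k in doc if k not in cls.__dataclass_fields__]
        if bad:
            raise ValueError(f"unknown config fields {bad}")
        return cls(**doc)

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 10007 + STAGES.index(stage) + 1) % (2**31)

    def stage_params(self, stage: str) -> dict:
        return getattr(self, stage, {}) if stage != "deprivation" else {}


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


class Pipeline:
    """Executes stages in order, with manifest-based caching."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = {}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    # ---------------------------------------------------------------- stages

    def run(self) -> dict:
        """Run all configured stages; returns the manifest."""
        upstream_hash = ""
        for stage in STAGES:
            if stage not in self.config.stages:
                continue
            params = {
                "params": self.config.stage_params(stage),
                "seed": self.config.stage_seed(stage),
                "upstream": upstream_hash,
                "version": spatialenroll.__version__,
            }
            h = _hash(params)
            entry = self.manifest.get(stage)
            if entry and entry["hash"] == h and all(
                (self.out / f).exists() for f in entry["outputs"]
            ):
                log.info("[%s] cached, skipping", stage)
                upstream_hash = h
                continue
            log.info("[%s] running", stage)
            t0 = time.time()
            try:
                outputs = getattr(self, f"_stage_{stage}")()
            except Exception:
                log.exception("[%s] failed", stage)
                raise
            self.manifest[stage] = {
                "hash": h,
                "parameters": self.config.stage_params(stage),
                "outputs": outputs,
                "wall_time_s": round(time.time() - t0, 3),
                "version": spatialenroll.__version__,
            }
            self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
            upstream_hash = h
        return self.manifest

    def _require(self, stage: str, name: str) -> Path:
        p = self.out / name
        if not p.exists():
            raise FileNotFoundError(f"[{stage}] missing upstream artifact {p}")
        return p

    def _stage_simulate(self) -> list[str]:
        params = dict(self.config.simulate)
        params["seed"] = self.config.stage_seed("simulate")
        cfg = synthetic_region.SimulationConfig(**params)
        ds = synthetic_region.simulate_dataset(cfg)
        spatial_structure.write_geojson(self.out / "areas.geojson", ds.areas)
        spatial_structure.write_edge_list(self.out / "adjacency.csv", ds.graph)
        _write_csv(ds.covariates, self.out / "covariates.csv")
        ins = ds.insurants.copy()
        ins["age"] = ins["age"].round(2)
        _write_csv(ins, self.out / "insurants.csv")
        (self.out / "simulation_config.json").write_text(cfg.to_json())
        truth = {
            "structured_field": np.round(ds.structured_field, 6).tolist(),
            "unstructured_field": np.round(ds.unstructured_field, 6).tolist(),
            "svc_fields": {k: np.round(v, 6).tolist() for k, v in ds.svc_truth.items()},
            "unenrollment_rate": round(ds.unenrollment_rate, 6),
        }
        (self.out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        return [
            "areas.geojson", "adjacency.csv", "covariates.csv",
            "insurants.csv", "simulation_config.json", "ground_truth.json",
        ]

    def _stage_deprivation(self) -> list[str]:
        cov = pd.read_csv(self._require("deprivation", "covariates.csv"))
        depr = deprivation_mod.compute_deprivation(cov)
        _write_csv(depr, self.out / "deprivation.csv")
        return ["deprivation.csv"]

    def _stage_map(self) -> list[str]:
        areas = spatial_structure.read_geojson(self._require("map", "areas.geojson"))
        graph = spatial_structure.read_edge_list(
            self._require("map", "adjacency.csv"), [a.area_id for a in areas]
        )
        O = np.array([a.n_unenrolled for a in areas], float)
        nd = np.array([a.n_diabetics for a in areas], float)
        E = disease_mapping.expected_counts(nd, O)
        p = dict(self.config.map)
        inference = disease_mapping.InferenceConfig(
            chains=p.get("chains", 4),
            draws=p.get("draws", 5000),
            burn=p.get("burn", 2000),
            seed=self.config.stage_seed("map"),
        )
        post = disease_mapping.fit_bym(
            disease_mapping.MappingInputs(O, E, graph), inference=inference
        )
        global_rate = O.sum() / max(nd.sum(), 1.0)
        rates = disease_mapping.smoothed_rates(post, global_rate)
        _write_csv(rates, self.out / "smoothed_rates.csv")
        spatial_structure.write_geojson(
            self.out / "smoothed_rates.geojson",
            areas,
            extra={
                r.area_id: {"theta_mean": round(r.theta_mean, 6), "rate": round(r.rate, 6)}
                for r in rates.itertuples()
            },
        )
        centroids = np.array([a.centroid for a in areas])
        order = {a.area_id: i for i, a in enumerate(areas)}
        vals = rates.set_index("area_id")["rate"].reindex([a.area_id for a in areas]).to_numpy()
        xmin, ymin = centroids.min(axis=0)
        xmax, ymax = centroids.max(axis=0)
        grid = disease_mapping.GridSpec.from_bbox(
            xmin, ymin, xmax, ymax, n=p.get("surface_grid_n", 50)
        )
        surface = disease_mapping.interpolate_surface(centroids, vals, grid)
        _write_csv(surface.to_frame(), self.out / "surface.csv")
        report = {
            "dic": global_regression.compute_dic(post.deviance_samples, post.deviance_at_mean),
            "diagnostics": {
                "rhat": post.diagnostics["rhat"],
                "converged": post.diagnostics["converged"],
            },
            "global_rate": global_rate,
            "matern": {k: v for k, v in surface.matern.items() if k != "model"},
        }
        (self.out / "map_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return ["smoothed_rates.csv", "smoothed_rates.geojson", "surface.csv", "map_report.json"]

    def _stage_scan(self) -> list[str]:
        areas = spatial_structure.read_geojson(self._require("scan", "areas.geojson"))
        O = np.array([a.n_unenrolled for a in areas], float)
        nd = np.array([a.n_diabetics for a in areas], float)
        E = disease_mapping.expected_counts(nd, O)
        dist = spatial_structure.centroid_distance_matrix(areas)
        p = dict(self.config.scan)
        clusters = scan_statistic.detect_clusters(
            O, E, dist, [a.area_id for a in areas],
            max_radius_km=p.get("max_radius_km", 30.0),
            n_sim=p.get("n_sim", 9999),
            seed=self.config.stage_seed("scan"),
        )
        _write_csv(scan_statistic.clusters_to_frame(clusters), self.out / "clusters.csv")
        member_props = {}
        for c in clusters:
            for aid in c.window.member_area_ids:
                member_props.setdefault(
                    aid, {"cluster_rank": c.rank, "cluster_p": c.p_value}
                )
        cluster_areas = [a for a in areas if a.area_id in member_props]
        spatial_structure.write_geojson(
            self.out / "clusters.geojson", cluster_areas, extra=member_props
        )
        return ["clusters.csv", "clusters.geojson"]

    def _load_design(self, stage: str):
        areas = spatial_structure.read_geojson(self._require(stage, "areas.geojson"))
        graph = spatial_structure.read_edge_list(
            self._require(stage, "adjacency.csv"), [a.area_id for a in areas]
        )
        ins = pd.read_csv(self._require(stage, "insurants.csv"))
        cov = pd.read_csv(self._require(stage, "covariates.csv"))
        depr = pd.read_csv(self._require(stage, "deprivation.csv"))
        cov = cov.drop(columns=["deprivation"], errors="ignore").merge(
            depr[["area_id", "index"]].rename(columns={"index": "deprivation"}),
            on="area_id",
        )
        design = global_regression.build_design(ins, cov, [a.area_id for a in areas])
        return design, graph

    def _stage_global_fit(self) -> list[str]:
        design, graph = self._load_design("global_fit")
        p = dict(self.config.global_fit)
        effects = p.get("effect_types", ["none", "iid", "besag", "bym"])
        cfg = global_regression.FitConfig(
            n_draws=p.get("n_draws", 1000), seed=self.config.stage_seed("global_fit")
        )
        vif = global_regression.compute_vif(design)
        _write_csv(vif, self.out / "vif.csv")
        fits, report = [], {}
        for eff in effects:
            f = global_regression.fit_global(design, graph, eff, cfg)
            fits.append(f)
            ors = f.odds_ratios()
            ors["percent_change"] = [
                global_regression.percent_change(v) for v in ors["or_mean"]
            ]
            _write_csv(ors, self.out / f"odds_ratios_{eff}.csv")
            report[eff] = {
                "dic": f.dic,
                "taus": f.taus,
                "diagnostics": f.diagnostics,
                "coefficients": f.posterior.summary().round(6).to_dict("records"),
            }
        _write_csv(
            global_regression.model_comparison_table(fits),
            self.out / "model_comparison.csv",
        )
        (self.out / "global_fit_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        return (
            ["vif.csv", "model_comparison.csv", "global_fit_report.json"]
            + [f"odds_ratios_{e}.csv" for e in effects]
        )

    def _stage_svc(self) -> list[str]:
        design, graph = self._load_design("svc")
        sim_cfg = json.loads((self.out / "simulation_config.json").read_text())
        p = dict(self.config.svc)
        block = p.get("coarse_block", 2)
        mapping = svc_regression.block_mapping(
            sim_cfg["n_rows"], sim_cfg["n_cols"], block, design.area_ids
        )
        coarse = svc_regression.coarsen(graph, mapping)
        covariates = p.get(
            "covariates",
            ["male", "age", "foreign_citizenship", "unemployed",
             "household_size", "commuter_pct"],
        )
        fit = svc_regression.fit_svc(
            design, coarse, covariates,
            config=global_regression.FitConfig(
                n_draws=p.get("n_draws", 1000), seed=self.config.stage_seed("svc")
            ),
            vary_intercept=p.get("vary_intercept", True),
        )
        frames = []
        for name, fld in fit.fields.items():
            df = fld.to_frame()
            df.insert(0, "covariate", name)
            frames.append(df)
        _write_csv(pd.concat(frames, ignore_index=True), self.out / "svc_fields.csv")
        report = {
            "dic": fit.dic,
            "taus": fit.taus,
            "diagnostics": fit.diagnostics,
            "global_coefficients": fit.global_coefficients.round(6).to_dict("records"),
        }
        (self.out / "svc_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return ["svc_fields.csv", "svc_report.json"]


def run(config: PipelineConfig) -> dict:
    """Run the configured pipeline; returns the manifest."""
    return Pipeline(config).run()


def validate_inputs(output_dir) -> list[str]:
    """Validate pipeline artifacts: GeoJSON validity, CSV schemas, count
    invariants and referential integrity.  Returns a list of violations
    (empty = clean)."""
    out = Path(output_dir)
    errors: list[str] = []
    areas = None
    if not (out / "areas.geojson").exists():
        errors.append("areas.geojson missing")
    else:
        # lenient per-feature parse so one bad area does not mask the rest
        from shapely.geometry import shape as shapely_shape

        try:
            doc = json.loads((out / "areas.geojson").read_text())
            feats = doc["features"]
        except Exception as exc:
            errors.append(f"areas.geojson unreadable: {exc}")
            feats = []
        areas = []
        for feat in feats:
            props = feat.get("properties", {})
            aid = str(props.get("area_id", "?"))
            geom = shapely_shape(feat["geometry"])
            if not geom.is_valid:
                errors.append(f"invalid polygon for area {aid}")
            nu, ndi, nin = (
                int(props.get("n_unenrolled", 0)),
                int(props.get("n_diabetics", 0)),
                int(props.get("n_insurants", 0)),
            )
            if not (0 <= nu <= ndi <= nin):
                errors.append(
                    f"count invariant violated in area {aid}: {nu} unenrolled, "
                    f"{ndi} diabetics, {nin} insurants"
                )
                continue
            areas.append(
                spatial_structure.AreaUnit(
                    aid, geom, (geom.centroid.x, geom.centroid.y), nin, ndi, nu
                )
            )
    if areas is not None:
        ids = {a.area_id for a in areas}
        if (out / "insurants.csv").exists():
            ins = pd.read_csv(out / "insurants.csv")
            needed = {"insurant_id", "area_id", "age", "diabetic", "enrolled"}
            missing = needed - set(ins.columns)
            if missing:
                errors.append(f"insurants.csv missing columns {sorted(missing)}")
            else:
                unknown = set(ins["area_id"]) - ids
                if unknown:
                    errors.append(
                        f"insurants reference unknown areas {sorted(unknown)[:5]}"
                    )
                bad = ins[(ins["enrolled"].notna()) & (ins["diabetic"] != 1)]
                if len(bad):
                    errors.append(
                        f"{len(bad)} non-diabetic insurants with enrollment defined"
                    )
        if (out / "covariates.csv").exists():
            cov = pd.read_csv(out / "covariates.csv")
            if set(cov["area_id"]) != ids:
                errors.append("covariates.csv area ids do not match areas.geojson")
    return errors
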