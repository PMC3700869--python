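"""Pipeline orchestration: simulate -> home ranges -> seasons -> RSF ->
landscape metrics -> home-range-size model comparison.

A single config dict (usually loaded from YAML) drives every stage; every
analysis threshold (isopleth level, RSI cutoff, availability density, split
ratio, MCP inclusion fraction, confidence-set rule) is a named key so
sensitivity runs are one-line edits. Outputs are pure functions of
(inputs, config, seed): a re-run with the same seed writes byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geo_io, home_range, hr_models, landscape_metrics, rsf
from . import season_clustering, synthetic_data

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "arcrange_out",
    "stages": {
        "simulate": True,
        "homerange": True,
        "seasons": True,
        "rsf": True,
        "metrics": True,
        "compare": True,
    },
    "landscape": {},  # LandscapeSpec overrides
    "movement": {},  # MovementSpec overrides
    "isopleth_level": 0.95,
    "rsi_threshold": 2.0,
    "availability_density": 1.0,  # points per km^2
    "train_ratio": 0.80,
    "mcp_inclusion": 0.60,
    "confidence_rule": 0.10,
    "bandwidth_method": "lscv",  # or "reference"
    "ud_cell_factor": 1.0,  # UD cell = factor * raster cell
    "candidate_sets": [
        [],
        ["rs"],
        ["s1lsi"],
        ["rs", "s1lsi"],
        ["s2prop", "s2lsi"],
        ["rs", "s2prop", "s2lsi"],
        ["s3prop", "s3lsi"],
        ["rs", "s3prop", "s3lsi"],
        ["wlsi"],
        ["rs", "wlsi"],
    ],
}

STAGE_ORDER = ["simulate", "homerange", "seasons", "rsf", "metrics", "compare"]
STAGE_DEPS = {
    "homerange": ["simulate"],
    "seasons": ["simulate"],
    "rsf": ["homerange", "seasons"],
    "metrics": ["homerange", "rsf"],
    "compare": ["metrics"],
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(cfg, user)
    _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, new: dict) -> None:
    for k, v in new.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def run(config: dict) -> dict:
    """Execute the enabled stages in order and return the run report.

    Raises :class:`StageError` naming the failing stage; a stage whose
    dependencies are disabled refuses with a dependency error. Artifacts
    (fix CSV, raster TIFF + legend, GeoJSON polygons, metric and model CSVs,
    report JSON) land under ``config["out_dir"]``.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    _deep_update(cfg, config)
    stages = cfg["stages"]
    for stage in STAGE_ORDER:
        if stages.get(stage):
            missing = [d for d in STAGE_DEPS.get(stage, []) if not stages.get(d)]
            if missing:
                raise StageError(stage, f"requires disabled stage(s) {missing}")

    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"seed": seed, "stages": {}}
    state: dict = {}

    if stages.get("simulate"):
        _stage_simulate(cfg, seed, out_dir, state, report)
    if stages.get("homerange"):
        _stage_homerange(cfg, out_dir, state, report)
    if stages.get("seasons"):
        _stage_seasons(cfg, out_dir, state, report)
    if stages.get("rsf"):
        _stage_rsf(cfg, seed, out_dir, state, report)
    if stages.get("metrics"):
        _stage_metrics(cfg, out_dir, state, report)
    if stages.get("compare"):
        _stage_compare(cfg, out_dir, state, report)

    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _stage_simulate(cfg, seed, out_dir, state, report):
    try:
        lspec = synthetic_data.LandscapeSpec(**{"seed": seed, **cfg["landscape"]})
        mspec = synthetic_data.MovementSpec(**{"seed": seed + 1, **cfg["movement"]})
        raster = synthetic_data.generate_landscape(lspec)
        fixes, truth = synthetic_data.simulate_tracks(raster, mspec)
    except Exception as err:  # noqa: BLE001
        raise StageError("simulate", str(err)) from err
    geo_io.write_raster(raster, out_dir / "landscape.tif")
    geo_io.write_fixes(fixes, out_dir / "fixes.csv")
    truth.to_json(out_dir / "truth.json")
    state["raster"] = raster
    state["truth"] = truth
    state["fixes"] = geo_io.annotate_fixes(fixes, raster)
    report["stages"]["simulate"] = {
        "n_animals": int(fixes["animal_id"].nunique()),
        "n_fixes": int(len(fixes)),
    }


def _stage_homerange(cfg, out_dir, state, report):
    raster, fixes = state["raster"], state["fixes"]
    truth = state.get("truth")
    ud_cell = cfg["ud_cell_factor"] * raster.cell_size
    areas, mcps, uds = [], {}, {}
    for animal, sub in fixes.groupby("animal_id", sort=True):
        xy = sub[["x", "y"]].to_numpy(float)
        try:
            if cfg["bandwidth_method"] == "reference":
                h = home_range.normal_reference_bandwidth(xy)
            else:
                h, _ = home_range.lscv_bandwidth(xy, cell_size=raster.cell_size)
            grid = home_range.make_grid(xy, h, ud_cell)
            ud = home_range.kernel_ud(xy, h, grid)
            iso = home_range.isopleth(ud, cfg["isopleth_level"])
            mcp = home_range.mcp(xy, animal_id=animal)
        except ValueError as err:
            raise StageError("homerange", f"animal {animal}: {err}") from err
        uds[animal] = ud
        mcps[animal] = mcp
        iso.animal_id = animal
        status = truth.statuses.get(animal) if truth else None
        areas.append(
            {
                "animal_id": animal,
                "year": int(pd.to_datetime(sub["timestamp"]).dt.year.iloc[0]),
                "status": status,
                "bandwidth": h,
                "area_km2": iso.area_km2,
                "log10_area": float(np.log10(iso.area_km2)),
            }
        )
        geo_io.write_polygon_geojson(
            iso.geometry, out_dir / f"kernel95_{animal}.geojson",
            {"animal_id": animal, "kind": iso.kind},
        )
        geo_io.write_polygon_geojson(
            mcp.geometry, out_dir / f"mcp_{animal}.geojson",
            {"animal_id": animal, "kind": "mcp100"},
        )
        state.setdefault("isopleths", {})[animal] = iso
    area_df = pd.DataFrame(areas)
    area_df.to_csv(out_dir / "home_ranges.csv", index=False)
    state["areas"] = area_df
    state["mcps"] = mcps
    report["stages"]["homerange"] = {
        "n_ranges": len(area_df),
        "mean_area_km2": float(area_df["area_km2"].mean()),
    }


def _stage_seasons(cfg, out_dir, state, report):
    try:
        partition = season_clustering.define_seasons(state["fixes"])
    except ValueError as err:
        raise StageError("seasons", str(err)) from err
    (out_dir / "seasons.json").write_text(json.dumps(partition.to_json_dict()))
    state["fixes"] = geo_io.assign_seasons(state["fixes"], partition.breaks_week)
    state["partition"] = partition
    report["stages"]["seasons"] = partition.to_json_dict()


def _stage_rsf(cfg, seed, out_dir, state, report):
    raster, fixes, mcps = state["raster"], state["fixes"], state["mcps"]
    rng = np.random.default_rng(seed + 1000)
    train, test = rsf.train_test_split(fixes, cfg["train_ratio"], seed=seed + 2000)
    selection_maps, ratios = {}, {}
    stage_report = {}
    for season_id in sorted(fixes["season_id"].unique()):
        used = train[train["season_id"] == season_id]
        avail_frames = []
        for animal in used["animal_id"].unique():
            pts = rsf.sample_availability(
                mcps[animal], cfg["availability_density"], rng=rng
            )
            avail_frames.append(
                pd.DataFrame(
                    {"animal_id": animal, "timestamp": pd.Timestamp("2000-01-01"),
                     "x": pts[:, 0], "y": pts[:, 1]}
                )
            )
        available = geo_io.annotate_fixes(pd.concat(avail_frames), raster)
        try:
            effects = rsf.fit_rsf(used, available, raster, season_id=season_id)
        except ValueError as err:
            raise StageError("rsf", f"season {season_id}: {err}") from err
        rsf.effects_table(effects).to_csv(
            out_dir / f"rsf_season{season_id}.csv", index=False
        )
        smap = rsf.build_selection_map(raster, effects, season_id=season_id)
        selection_maps[int(season_id)] = smap
        test_s = test[test["season_id"] == season_id]
        try:
            ratio = rsf.selection_ratio(test_s, mcps, smap, season_id=season_id)
            ratios[int(season_id)] = ratio
            stage_report[f"season{season_id}"] = {
                "mean_w": ratio.mean_w,
                "wald_f": ratio.wald_f,
                "p": ratio.p,
                "n_animals": len(ratio.animals),
                "n_excluded": len(ratio.excluded),
            }
        except ValueError as err:
            stage_report[f"season{season_id}"] = {"error": str(err)}
    state["selection_maps"] = selection_maps
    state["ratios"] = ratios
    report["stages"]["rsf"] = stage_report


def _stage_metrics(cfg, out_dir, state, report):
    raster = state["raster"]
    rows = []
    for _, rec in state["areas"].iterrows():
        animal = rec["animal_id"]
        iso = state["isopleths"][animal]
        try:
            m = landscape_metrics.range_metrics(
                iso, raster, state["selection_maps"],
                animal_id=animal, year=rec["year"], status=rec["status"],
            )
        except ValueError as err:
            raise StageError("metrics", f"animal {animal}: {err}") from err
        rows.append(m)
    table = landscape_metrics.metrics_table(rows)
    table.to_csv(out_dir / "range_metrics.csv", index=False)
    state["metrics"] = table
    report["stages"]["metrics"] = {"n_rows": len(table)}


def _stage_compare(cfg, out_dir, state, report):
    df = state["metrics"].dropna(axis=1, how="any")
    candidates = [
        [t for t in terms] for terms in cfg["candidate_sets"]
        if all(t == "rs" or t in df.columns for t in terms)
    ]
    try:
        records = hr_models.fit_candidates(df, candidates)
    except Exception as err:  # noqa: BLE001
        raise StageError("compare", str(err)) from err
    table = hr_models.records_table(records)
    table.to_csv(out_dir / "model_comparison.csv", index=False)
    conf = hr_models.confidence_set(records)
    importance = hr_models.importance_weights(conf)
    report["stages"]["compare"] = {
        "best_model": records[0].name,
        "confidence_set": [r.name for r in conf],
        "importance": importance,
    }
    state["records"] = records
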