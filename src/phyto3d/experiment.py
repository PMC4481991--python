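"""Orchestrate the full monitoring study on synthetic data.

The default design mirrors a greenhouse monitoring campaign: 5 plants
observed on 6 consecutive days, each plant-day captured by both measurement
systems (30 clouds per method).  Every cloud runs through the preparation
chain and the organ-level measurement; laser values serve as the reference
(``ref``) and photogrammetric values as the actual measurement (``act``) in
the agreement analysis.  Because the plants are synthetic, ground truth is
additionally logged so both methods can be benchmarked against truth —
something a real-plant study cannot do.

Reproducibility: every random stream derives deterministically from
``master_seed`` via ``numpy.random.SeedSequence`` spawn keys, so any subset
of the experiment reruns identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .accuracy import AccuracyReport, MeasurementPairs, relative_difference
from .cloud import PointCloud
from .io import write_cloud
from .phenotype import PhenotypeResult, measure_plant
from .preprocess import PrepParams, prepare
from .synthetic import (PlantConfig, SensorProfile, generate_plant,
                        laser_profile, photogrammetric_profile, sample_sensor,
                        true_parameters)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "compare_cleaning_influence", "color_filter_leaf_area_errors"]

PARAMETER_UNITS = {
    "single_leaf_area": "mm^2",
    "cumulated_leaf_area": "mm^2",
    "main_stem_height": "mm",
    "convex_hull_volume": "dm^3",
}


def _derive_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentConfig:
    """Complete, serializable description of one synthetic study."""

    n_plants: int = 5
    n_days: int = 6
    plant_template: PlantConfig = field(default_factory=PlantConfig)
    laser: SensorProfile = field(default_factory=laser_profile)
    photogrammetric: SensorProfile = field(default_factory=photogrammetric_profile)
    photo_budget_range: Tuple[int, int] = (15000, 55000)
    randomize_photo_scale: bool = True
    prep: PrepParams = field(default_factory=PrepParams)
    segmentation_mode: str = "labels"
    n_single_leaves: int = 26
    truth_hull_spacing: float = 0.25
    master_seed: int = 0
    write_clouds: bool = False

    def validate(self) -> None:
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        self.laser.validate()
        self.photogrammetric.validate()
        self.plant_template.validate()

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_plants": self.n_plants,
            "n_days": self.n_days,
            "plant": self.plant_template.__dict__ | {
                "leaf_size_range": list(self.plant_template.leaf_size_range)},
            "laser": self.laser.__dict__,
            "photogrammetric": self.photogrammetric.__dict__,
            "photo_budget_range": list(self.photo_budget_range),
            "randomize_photo_scale": self.randomize_photo_scale,
            "prep": {
                "raster_spacing_mm": self.prep.raster_spacing_mm,
                "outlier_k": self.prep.outlier_k,
                "outlier_n_sigma": self.prep.outlier_n_sigma,
                "color_filter": self.prep.color_filter,
                "max_saturation": self.prep.color_spec.max_saturation,
                "min_value": self.prep.color_spec.min_value,
                "base_plane_z": self.prep.base_plane_z,
                "crop_radius": self.prep.crop_radius,
                "crop_mode": self.prep.crop_mode,
            },
            "segmentation_mode": self.segmentation_mode,
            "n_single_leaves": self.n_single_leaves,
            "truth_hull_spacing": self.truth_hull_spacing,
            "master_seed": self.master_seed,
            "write_clouds": self.write_clouds,
        }

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        from .preprocess import ColorFilterSpec
        kwargs: dict = {}
        for key in ("n_plants", "n_days", "segmentation_mode", "n_single_leaves",
                    "truth_hull_spacing", "master_seed", "write_clouds",
                    "randomize_photo_scale"):
            if key in raw:
                kwargs[key] = raw[key]
        if "photo_budget_range" in raw:
            kwargs["photo_budget_range"] = tuple(raw["photo_budget_range"])
        if "plant" in raw:
            plant = dict(raw["plant"])
            if "leaf_size_range" in plant:
                plant["leaf_size_range"] = tuple(plant["leaf_size_range"])
            kwargs["plant_template"] = PlantConfig(**plant)
        if "laser" in raw:
            kwargs["laser"] = SensorProfile(**raw["laser"])
        if "photogrammetric" in raw:
            kwargs["photogrammetric"] = SensorProfile(**raw["photogrammetric"])
        if "prep" in raw:
            p = dict(raw["prep"])
            spec = ColorFilterSpec(
                max_saturation=p.pop("max_saturation", 0.15),
                min_value=p.pop("min_value", 0.5))
            kwargs["prep"] = PrepParams(color_spec=spec, **p)
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    params: pd.DataFrame          # one row per plant-day-method
    leaves: pd.DataFrame          # one row per plant-day-method-leaf
    truth: pd.DataFrame           # one row per plant-day
    report: AccuracyReport
    cleaning: pd.DataFrame        # pre/post cleaning influence table
    failures: List[str] = field(default_factory=list)


def _measure_one(cloud: PointCloud, cfg: ExperimentConfig) -> PhenotypeResult:
    return measure_plant(cloud, segmentation_mode=cfg.segmentation_mode)


def run_experiment(config: ExperimentConfig,
                   out_dir: Optional[str] = None) -> ExperimentResult:
    """Run the full plants x days x sensors study and evaluate agreement."""
    config.validate()
    master = config.master_seed
    param_rows: List[dict] = []
    leaf_rows: List[dict] = []
    truth_rows: List[dict] = []
    failures: List[str] = []
    cleaning_raw: Dict[str, Tuple[PhenotypeResult, PhenotypeResult]] = {}

    budgets = np.linspace(config.photo_budget_range[0], config.photo_budget_range[1],
                          max(config.n_days, 2)).round().astype(int)[:config.n_days]
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        if config.write_clouds:
            os.makedirs(os.path.join(out_dir, "clouds"), exist_ok=True)

    for p in range(config.n_plants):
        plant_seed = _derive_seed(master, 1, p)
        for d in range(config.n_days):
            plant_cfg = replace(config.plant_template, seed=plant_seed, day_index=d)
            model = generate_plant(plant_cfg)
            truth = true_parameters(model, hull_spacing=config.truth_hull_spacing)
            truth_rows.append({
                "plant": p, "day": d,
                "n_leaves": len(truth.single_leaf_areas),
                "cumulated_leaf_area_mm2": truth.cumulated_leaf_area,
                "stem_height_mm": truth.main_stem_height,
                "hull_volume_dm3": truth.convex_hull_volume,
            })
            for leaf_id, area in zip(truth.leaf_ids, truth.single_leaf_areas):
                leaf_rows.append({"plant": p, "day": d, "method": "truth",
                                  "leaf_id": int(leaf_id), "area_mm2": float(area)})

            photo_profile = replace(
                config.photogrammetric, point_budget=int(budgets[d]))
            if config.randomize_photo_scale:
                scale_rng = np.random.default_rng(_derive_seed(master, 2, p, d))
                photo_profile = replace(
                    photo_profile,
                    scale_factor=float(np.exp(scale_rng.uniform(
                        np.log(0.002), np.log(0.01)))))

            for method, profile, raster in (
                    ("laser", config.laser, True),
                    ("photogrammetric", photo_profile, False)):
                tag = f"plant{p}_day{d}_{method}"
                try:
                    seed = _derive_seed(master, 3, p, d, 0 if method == "laser" else 1)
                    cloud = sample_sensor(model, profile, seed)
                    prepared, log = prepare(cloud, config.prep,
                                            rasterize_cloud=raster)
                    result = _measure_one(prepared, config)
                except Exception as exc:  # record and continue with other items
                    failures.append(f"{tag}: {type(exc).__name__}: {exc}")
                    continue
                param_rows.append({
                    "plant": p, "day": d, "method": method,
                    "scale_factor": profile.scale_factor,
                    "n_raw": cloud.n, "n_prepared": prepared.n,
                    "cumulated_leaf_area_mm2": result.cumulated_leaf_area,
                    "stem_height_mm": result.main_stem_height,
                    "hull_volume_dm3": result.convex_hull_volume,
                })
                for leaf_id, area in sorted(result.single_leaf_areas.items()):
                    leaf_rows.append({"plant": p, "day": d, "method": method,
                                      "leaf_id": leaf_id, "area_mm2": area})
                if config.write_clouds and out_dir:
                    write_cloud(prepared, os.path.join(out_dir, "clouds", tag + ".ply"))

                # cleaning-influence example: first plant, final day.
                # "Pre-cleaning" skips outlier and false-point removal but keeps
                # scaling/cropping/rasterization (those are preparation, not
                # cleaning), so the difference isolates the cleaning steps.
                if p == 0 and d == config.n_days - 1:
                    try:
                        raw_prep = replace(config.prep, outlier_n_sigma=1e18,
                                           color_filter=False)
                        raw_cloud, _ = prepare(cloud, raw_prep, rasterize_cloud=raster)
                        raw_result = _measure_one(raw_cloud, config)
                        cleaning_raw[method] = (raw_result, result)
                    except Exception as exc:
                        failures.append(f"{tag} cleaning comparison: "
                                        f"{type(exc).__name__}: {exc}")

    params = pd.DataFrame(param_rows)
    leaves = pd.DataFrame(leaf_rows)
    truth_df = pd.DataFrame(truth_rows)

    report = _evaluate(config, params, leaves, truth_df)
    cleaning = _cleaning_table(cleaning_raw)

    result = ExperimentResult(config=config, params=params, leaves=leaves,
                              truth=truth_df, report=report, cleaning=cleaning,
                              failures=failures)
    if out_dir:
        _write_outputs(result, out_dir)
    return result


def _evaluate(config: ExperimentConfig, params: pd.DataFrame,
              leaves: pd.DataFrame, truth_df: pd.DataFrame) -> AccuracyReport:
    report = AccuracyReport()
    if params.empty:
        return report
    wide = params.pivot_table(index=["plant", "day"], columns="method",
                              values=["cumulated_leaf_area_mm2", "stem_height_mm",
                                      "hull_volume_dm3"])
    for param, column in (("cumulated_leaf_area", "cumulated_leaf_area_mm2"),
                          ("main_stem_height", "stem_height_mm"),
                          ("convex_hull_volume", "hull_volume_dm3")):
        if ("laser" not in wide[column]) or ("photogrammetric" not in wide[column]):
            continue
        sub = wide[column].dropna()
        if len(sub) >= 2:
            report.add(MeasurementPairs(
                parameter_name=param, units=PARAMETER_UNITS[param],
                ref=sub["laser"].to_numpy(), act=sub["photogrammetric"].to_numpy()))

    # single leaves: stratified sample (small/medium/large by reference area)
    # drawn from the first two plants
    single = _single_leaf_pairs(config, leaves)
    if single is not None:
        report.add(single)

    # truth benchmark (possible only because the plants are synthetic)
    report.extras["truth_benchmark"] = _truth_benchmark(params, truth_df)
    return report


def _single_leaf_pairs(config: ExperimentConfig,
                       leaves: pd.DataFrame) -> Optional[MeasurementPairs]:
    if leaves.empty:
        return None
    plants = sorted(leaves["plant"].unique())[:2]
    sub = leaves[leaves["plant"].isin(plants) & (leaves["method"] != "truth")]
    wide = sub.pivot_table(index=["plant", "day", "leaf_id"], columns="method",
                           values="area_mm2").dropna()
    if len(wide) < 2 or "laser" not in wide or "photogrammetric" not in wide:
        return None
    ref = wide["laser"].to_numpy()
    act = wide["photogrammetric"].to_numpy()
    n_wanted = min(config.n_single_leaves, len(ref))
    if len(ref) > n_wanted:
        terciles = np.quantile(ref, [1 / 3, 2 / 3])
        strata = np.digitize(ref, terciles)
        rng = np.random.default_rng(_derive_seed(config.master_seed, 4))
        chosen: List[int] = []
        base, extra = divmod(n_wanted, 3)
        for s in range(3):
            members = np.flatnonzero(strata == s)
            take = min(base + (1 if s < extra else 0), len(members))
            chosen.extend(rng.choice(members, size=take, replace=False))
        # top up from anywhere if a stratum ran short
        remaining = np.setdiff1d(np.arange(len(ref)), chosen)
        if len(chosen) < n_wanted and len(remaining):
            chosen.extend(rng.choice(remaining, size=min(n_wanted - len(chosen),
                                                         len(remaining)),
                                     replace=False))
        chosen_arr = np.sort(np.asarray(chosen, dtype=int))
        ref, act = ref[chosen_arr], act[chosen_arr]
    return MeasurementPairs(parameter_name="single_leaf_area",
                            units=PARAMETER_UNITS["single_leaf_area"],
                            ref=ref, act=act)


def _truth_benchmark(params: pd.DataFrame, truth_df: pd.DataFrame) -> dict:
    merged = params.merge(truth_df, on=["plant", "day"], suffixes=("", "_truth"))
    out: dict = {}
    for method in sorted(merged["method"].unique()):
        sub = merged[merged["method"] == method]
        entry = {}
        for param, column in (("cumulated_leaf_area", "cumulated_leaf_area_mm2"),
                              ("main_stem_height", "stem_height_mm"),
                              ("convex_hull_volume", "hull_volume_dm3")):
            t = sub[column + "_truth"].to_numpy()
            a = sub[column].to_numpy()
            ok = t != 0
            if ok.any():
                entry[param + "_mape_pct"] = float(
                    np.mean(np.abs((t[ok] - a[ok]) / t[ok])) * 100.0)
        out[method] = entry
    return out


def _cleaning_table(cleaning_raw: Dict[str, Tuple[PhenotypeResult, PhenotypeResult]]
                    ) -> pd.DataFrame:
    rows = []
    for method, (raw, clean) in sorted(cleaning_raw.items()):
        for param, pre, post in (
                ("cumulated_leaf_area_mm2", raw.cumulated_leaf_area,
                 clean.cumulated_leaf_area),
                ("hull_volume_dm3", raw.convex_hull_volume,
                 clean.convex_hull_volume)):
            rows.append({
                "method": method, "parameter": param,
                "pre_cleaning": pre, "after_cleaning": post,
                "difference_pct": relative_difference(pre, post) if pre != 0 else 0.0,
            })
    return pd.DataFrame(rows)


def compare_cleaning_influence(result_raw: PhenotypeResult,
                               result_clean: PhenotypeResult,
                               method: str = "") -> pd.DataFrame:
    """Pre/post/difference rows for cumulated leaf area and hull volume."""
    return _cleaning_table({method or "method": (result_raw, result_clean)})


def color_filter_leaf_area_errors(master_seed: int, day: int = 3,
                                  config: Optional[ExperimentConfig] = None
                                  ) -> Tuple[float, float]:
    """Absolute relative error of the cumulated leaf area vs truth on one
    artifact-bearing photogrammetric cloud, with and without color filtering.

    Returns ``(error_with_filter, error_without_filter)`` as fractions.
    """
    cfg = config or ExperimentConfig()
    plant_seed = _derive_seed(master_seed, 1, 0)
    model = generate_plant(replace(cfg.plant_template, seed=plant_seed, day_index=day))
    truth = true_parameters(model, hull_spacing=max(cfg.truth_hull_spacing, 0.25))
    profile = replace(cfg.photogrammetric, point_budget=30000)
    cloud = sample_sensor(model, profile, _derive_seed(master_seed, 3, 0, day, 1))
    errors = []
    for use_filter in (True, False):
        prep = replace(cfg.prep, color_filter=use_filter)
        prepared, _ = prepare(cloud, prep, rasterize_cloud=False)
        res = measure_plant(prepared, segmentation_mode=cfg.segmentation_mode)
        errors.append(abs(res.cumulated_leaf_area - truth.cumulated_leaf_area)
                      / truth.cumulated_leaf_area)
    return errors[0], errors[1]


def _write_outputs(result: ExperimentResult, out_dir: str) -> None:
    result.params[result.params["method"] == "laser"].to_csv(
        os.path.join(out_dir, "params_laser.csv"), index=False)
    result.params[result.params["method"] == "photogrammetric"].to_csv(
        os.path.join(out_dir, "params_photo.csv"), index=False)
    result.leaves.to_csv(os.path.join(out_dir, "leaf_areas.csv"), index=False)
    result.truth.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
    result.cleaning.to_csv(os.path.join(out_dir, "cleaning_influence.csv"), index=False)
    report = result.report.to_dict()
    report["failures"] = result.failures
    report["config"] = result.config.to_dict()
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "log.txt"), "w") as fh:
        fh.write(f"plants={result.config.n_plants} days={result.config.n_days} "
                 f"master_seed={result.config.master_seed}\n")
        for line in result.failures:
            fh.write("FAIL " + line + "\n")
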