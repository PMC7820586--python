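"""Seeded end-to-end orchestration of the mapping analysis.

Stage order mirrors the analysis flow: synthetic database (criteria,
stations, cases) -> kriging -> variogram report -> autocorrelation ->
frequency-ratio weighting -> random-forest susceptibility map ->
validation -> leave-one-factor-out sensitivity. Every stage writes its
outputs under the run directory and the manifest lists them all, keyed by
a stable hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .autocorrelation import (aggregate_points, build_weights, getis_ord,
                              global_morans_i, local_morans_i)
from .errors import GeoRiskError, ParameterError
from .frequency_ratio import classify_raster, compute_fr, fr_reclassify
from .geostatistics import (empirical_semivariogram, fit_variogram_model,
                            ordinary_kriging)
from .grid import CasePoints, CriterionRaster, StudyArea
from .susceptibility import (classify_map, extract_features,
                             predict_susceptibility, sample_pseudo_absence,
                             split_points, train_random_forest)
from .synthetic_data import (SyntheticScenario, default_scenario,
                             generate_cases, generate_criteria,
                             sample_stations)
from .validation import (PredictionPairs, confusion_at, error_metrics,
                         roc_curve, run_sensitivity)

log = logging.getLogger("georisk")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; YAML/JSON round-trippable."""

    seed: int = 0
    # study frame (used when criteria are synthetic)
    area_width: float = 10_000.0
    area_height: float = 7_300.0
    cell_size: float = 100.0
    # synthetic scenario
    n_criteria: int = 13
    n_cases: int = 872
    driver_indices: list[int] = field(default_factory=lambda: [0, 1, 2])
    driver_coefficients: list[float] = field(default_factory=lambda: [1.5, 1.2, 1.0])
    spatial_range: float = 4000.0
    nugget_fraction: float = 0.1
    station_count: int = 20
    station_noise_sd: float = 0.05
    # geostatistics
    variogram_family: str = "spherical"
    n_lags: int = 12
    standardize_variogram: bool = True
    use_kriged_criteria: bool = True
    # autocorrelation
    aggregation_factor: int = 5
    weights_scheme: str = "queen"
    # FR + model
    binning_method: str = "natural-breaks"
    n_classes: int = 5
    train_fraction: float = 0.7
    split_rounding: str = "round"
    pseudo_absence_min_distance_cells: float = 2.0
    n_trees: int = 100
    map_classes: int = 5
    # io
    out_dir: str = "georisk_run"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must be in (0, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ParameterError("seed must be an integer")

    # -- (de)serialization -----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ParameterError(f"unknown config key(s): {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def scenario(self) -> SyntheticScenario:
        return SyntheticScenario(
            seed=self.seed, n_criteria=self.n_criteria, n_cases=self.n_cases,
            driver_indices=tuple(self.driver_indices),
            driver_coefficients=tuple(self.driver_coefficients),
            spatial_range=self.spatial_range,
            nugget_fraction=self.nugget_fraction,
            station_count=self.station_count,
            station_noise_sd=self.station_noise_sd,
            train_fraction=self.train_fraction)

    def area(self) -> StudyArea:
        return StudyArea.rectangle(self.area_width, self.area_height,
                                   self.cell_size)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    timing_s: dict[str, float] = field(default_factory=dict)
    status: str = "ok"
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.timing_s[name] = round(time.perf_counter() - self.t0, 3)
            if exc_type is not None:
                manifest.status = "failed"
                manifest.failed_stage = name
                log.error("stage %s: FAILED (%s)", name, exc)
            else:
                log.info("stage %s: done in %.2fs", name,
                         manifest.timing_s[name])
            return False
    return _Timer()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute every stage on the synthetic scenario and write all reports.

    Returns the manifest; on stage failure the manifest (with partial
    outputs preserved) is still written before the error propagates.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.config_hash(), config.seed)
    log.info("run %s -> %s (seed %d)", manifest.config_hash, out, config.seed)

    def record(key: str, path: Path) -> None:
        manifest.outputs[key] = str(path.relative_to(out))

    try:
        _run_stages(config, out, manifest, record)
    finally:
        gio.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


def _run_stages(config, out, manifest, record) -> None:
    area = config.area()
    scenario = config.scenario()
    seedseq = np.random.SeedSequence(config.seed)
    sub = {name: int(s.generate_state(1)[0]) for name, s in zip(
        ["stations", "cases", "split", "absence", "rf", "autocorr"],
        seedseq.spawn(6))}

    # 1. synthetic spatial database ------------------------------------
    with _stage(manifest, "database"):
        criteria = generate_criteria(area, scenario)
        for r in criteria:
            record(f"criterion/{r.name}", gio.write_raster(r, out / f"{r.name}.asc"))
        stations = [sample_stations(r, scenario.station_count,
                                    scenario.station_noise_sd,
                                    seed=sub["stations"] + k)
                    for k, r in enumerate(criteria)]
        st_rows = [{"criterion": s.variable_name, "x": x, "y": y, "value": v}
                   for s in stations for x, y, v in zip(s.x, s.y, s.values)]
        st_path = out / "stations.csv"
        pd.DataFrame(st_rows).to_csv(st_path, index=False)
        record("stations", st_path)

        cases = generate_cases(area, criteria, scenario)
        cases = split_points(cases, config.train_fraction, seed=sub["split"],
                             rounding=config.split_rounding)
        record("cases_csv", gio.write_points(cases, out / "cases.csv"))
        record("cases_geojson", gio.write_points(cases, out / "cases.geojson"))
        record("scenario", gio.write_json(scenario.to_dict(),
                                          out / "scenario.json"))

    # 2. variogram + kriging -------------------------------------------
    with _stage(manifest, "geostatistics"):
        vario_rows = []
        kriged = []
        for s in stations:
            s_std = s.standardized() if config.standardize_variogram else s
            emp = empirical_semivariogram(s_std, n_lags=config.n_lags)
            model = fit_variogram_model(emp, config.variogram_family)
            vario_rows.append({"criterion": s.variable_name,
                               **model.to_dict()})
            kr = ordinary_kriging(s, model, area)
            kriged.append(kr)
            record(f"kriged/{s.variable_name}",
                   gio.write_raster(kr, out / f"kriged_{s.variable_name}.asc"))
        record("variograms", gio.write_json(vario_rows, out / "variograms.json"))

    model_criteria = kriged if config.use_kriged_criteria else criteria

    # 3. autocorrelation ------------------------------------------------
    with _stage(manifest, "autocorrelation"):
        units = aggregate_points(cases.presences, area,
                                 cell=config.aggregation_factor * config.cell_size)
        w_moran = build_weights(units, config.weights_scheme,
                                row_standardize=True)
        w_gi = build_weights(units, "distance-band", row_standardize=False,
                             self_inclusive=True)
        moran = global_morans_i(units, w_moran)
        g = getis_ord(units, build_weights(units, "distance-band",
                                           row_standardize=False),
                      mode="global_G", seed=sub["autocorr"])
        report = [moran.to_dict(), g.to_dict()]
        record("autocorrelation", gio.write_json(report, out / "autocorrelation.json"))
        local = local_morans_i(units, w_moran, seed=sub["autocorr"])
        gi = getis_ord(units, w_gi, mode="local_Gi_star")
        lab = units.to_grid(np.array(
            [{"not-significant": 0, "H-H": 1, "H-L": 2, "L-H": 3, "L-L": 4}[l]
             for l in local.labels], dtype=float))
        record("local_moran_labels", gio.write_raster(
            CriterionRaster(units.area, lab, "local_moran"),
            out / "local_moran_labels.asc"))
        hot = units.to_grid(np.array(
            [{"not-significant": 0, "hot": 1, "cold": -1}[l]
             for l in gi.labels], dtype=float))
        record("gi_star_labels", gio.write_raster(
            CriterionRaster(units.area, hot, "gi_star"),
            out / "gi_star_labels.asc"))

    # 4. frequency ratio ------------------------------------------------
    with _stage(manifest, "frequency_ratio"):
        train_presences = cases.train.presences
        fr_surfaces = []
        fr_frames = []
        for r in model_criteria:
            scheme = classify_raster(r, config.binning_method,
                                     config.n_classes, seed=config.seed)
            table = compute_fr(train_presences, r, scheme)
            fr_frames.append(table.to_frame())
            fr_surfaces.append(fr_reclassify(r, table, scheme))
        fr_path = out / "fr_tables.csv"
        pd.concat(fr_frames, ignore_index=True).to_csv(fr_path, index=False)
        record("fr_tables", fr_path)
        for surf in fr_surfaces:
            record(f"fr_surface/{surf.name}",
                   gio.write_raster(surf, out / f"{surf.name}.asc"))

    # 5. susceptibility model -------------------------------------------
    with _stage(manifest, "random_forest"):
        absences = sample_pseudo_absence(
            cases.presences, area, n=len(cases.presences),
            min_distance=config.pseudo_absence_min_distance_cells * config.cell_size,
            seed=sub["absence"])
        absences = split_points(absences, config.train_fraction,
                                seed=sub["absence"] + 1,
                                rounding=config.split_rounding)
        labeled = CasePoints.concatenate([cases, absences])
        features = extract_features(labeled, fr_surfaces)
        train_fm = features.in_partition("train")
        rf, importances = train_random_forest(train_fm, config.n_trees,
                                              seed=sub["rf"])
        imp_path = out / "importances.csv"
        pd.DataFrame(sorted(importances.items(), key=lambda kv: -kv[1]),
                     columns=["criterion", "importance"]).to_csv(imp_path,
                                                                 index=False)
        record("importances", imp_path)
        smap = predict_susceptibility(rf, fr_surfaces)
        record("probability", gio.write_raster(smap.probability,
                                               out / "susceptibility.asc"))
        classed = classify_map(smap.probability, config.map_classes,
                               seed=config.seed)
        record("classes", gio.write_raster(classed.classes,
                                           out / "susceptibility_class.asc"))
        record("class_breaks", gio.write_json(
            {"breaks": classed.breaks, "names": list(classed.class_names)},
            out / "class_breaks.json"))

    # 6. validation -----------------------------------------------------
    with _stage(manifest, "validation"):
        report = {}
        roc_frames = []
        for part in ("train", "test"):
            fm = features.in_partition(part)
            pairs = PredictionPairs(fm.y, rf.predict_proba(fm.x)[:, 1])
            xs, ys, auc = roc_curve(pairs)
            rmse, mae = error_metrics(pairs)
            conf = confusion_at(pairs, 0.5)
            report[part] = {"AUC": auc, "RMSE": rmse, "MAE": mae,
                            "TP_rate": conf.tpr, "FP_rate": conf.fpr,
                            "n": len(pairs)}
            roc_frames.append(pd.DataFrame(
                {"partition": part, "X_fpr": xs, "Y_tpr": ys}))
        record("validation", gio.write_json(report, out / "validation.json"))
        roc_path = out / "roc_points.csv"
        pd.concat(roc_frames, ignore_index=True).to_csv(roc_path, index=False)
        record("roc_points", roc_path)

    # 7. sensitivity ----------------------------------------------------
    with _stage(manifest, "sensitivity"):
        trainer = lambda fm, s: train_random_forest(fm, config.n_trees, s)[0]  # noqa: E731
        sens = run_sensitivity(train_fm, trainer, seed=sub["rf"])
        sens_path = out / "sensitivity.csv"
        sens.to_frame().to_csv(sens_path, index=False)
        record("sensitivity", sens_path)
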