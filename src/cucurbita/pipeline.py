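"""End-to-end orchestration: classify -> smooth -> detect -> quantify ->
grid -> evaluate, with a machine-readable run report.

The pipeline operates on a synthetic scene (generated in-process from a
config) or on user-supplied rasters; every stage is a pure function of
the configuration and inputs, all randomness is explicitly seeded, and
re-running with the same configuration reproduces all tabular outputs
bit-identically.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .classify import build_training_set, classify_image, confusion_metrics, train_classifier
from .evaluate import match_detections, precision_audit
from .geometry import SplitThresholds, detect_fruits
from .gridmap import aggregate_grid, count_weight_correlation, field_summary
from .morphology import MorphConfig, smooth_mask
from .quantify import (class_summary, fit_weight_model,
                       records_from_detections, records_to_frame, spheroid_volume)
from .raster import write_raster
from .scene import Scene, SceneConfig, assign_weights, render_scene, truth_to_frame
from .vector import detections_to_geojson, grid_to_geojson, write_geojson

log = logging.getLogger("cucurbita")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; no wall-clock seeding."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    n_train_per_class: int = 4000
    n_test_eval: int = 1000
    n_trees: int = 500
    morph: MorphConfig = field(default_factory=MorphConfig)
    thresholds: SplitThresholds = field(default_factory=SplitThresholds)
    cell_size_m: float = 3.0
    match_radius_m: float = 0.5
    audit_sample: int = 200
    n_calibration: int = 40
    calibration_noise_sd_g: float = 35.0
    seed: int = 0
    out_dir: str | None = None

    def seeds(self) -> dict:
        # independent per-stage streams derived from the master seed
        ss = np.random.SeedSequence(self.seed)
        names = ("scene", "sampling", "forest", "weights", "audit")
        children = ss.spawn(len(names))
        return {n: int(c.generate_state(1)[0] % (2**31))
                for n, c in zip(names, children)}


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(report, name):
    log.info("stage: %s", name)

    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            report["stages"][name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None and not isinstance(exc, StageFailure):
                raise StageFailure(name, exc) from exc
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig, scene: Scene | None = None) -> dict:
    """Run the full workflow; returns the report dict.

    When ``scene`` is not given it is rendered from ``config.scene``
    (with the scene seed derived from the master seed).  When
    ``config.out_dir`` is set, all artifacts (rasters, GeoJSON, CSV
    tables, the JSON report) are written there.
    """
    seeds = config.seeds()
    report: dict = {
        "version": __version__,
        "seeds": seeds,
        "config": _config_dict(config),
        "stages": {},
    }
    out = config.out_dir
    if out:
        os.makedirs(out, exist_ok=True)

    with _stage(report, "scene"):
        if scene is None:
            scene_cfg = SceneConfig(**{**vars(config.scene), "seed": seeds["scene"]})
            scene = render_scene(scene_cfg)
        truth = assign_weights(scene.fruits, seed=seeds["weights"],
                               noise_sd=config.calibration_noise_sd_g)
        scene.fruits = truth
        report["n_truth_fruits"] = len(truth)

    with _stage(report, "train"):
        split = build_training_set(scene, n_per_class=config.n_train_per_class,
                                   n_test_eval=config.n_test_eval,
                                   seed=seeds["sampling"])
        model = train_classifier(split.train, n_trees=config.n_trees,
                                 seed=seeds["forest"])
        report["n_trees"] = model.n_trees

    with _stage(report, "classify"):
        mask = classify_image(model, scene)
        pred = mask[split.evaluation.rows, split.evaluation.cols]
        cm = confusion_metrics(pred, split.evaluation.labels)
        report["classification"] = {
            "oa_percent": round(cm.oa, 2),
            "pa_percent": {str(k): round(v, 2) for k, v in cm.pa.items()},
            "ua_percent": {str(k): round(v, 2) for k, v in cm.ua.items()},
            "counts": cm.counts.tolist(),
        }
        log.info("pixel OA %.2f%%", cm.oa)

    with _stage(report, "smooth"):
        clean = smooth_mask(mask, config.morph)

    with _stage(report, "detect"):
        detections = detect_fruits(clean, config.thresholds)
        report["n_detections"] = len(detections)
        log.info("%d objects detected", len(detections))

    with _stage(report, "quantify"):
        # calibration on the "harvested" subset of the ground truth
        rng = np.random.default_rng(seeds["weights"])
        k = min(config.n_calibration, len(truth))
        cal = [truth[i] for i in rng.choice(len(truth), size=k, replace=False)]
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")   # tolerate h > d survey fruits
            volumes = [spheroid_volume(f.diameter_cm, f.height_cm) for f in cal]
        weights = [f.weight_g for f in cal]
        wmodel = fit_weight_model(volumes, weights)
        records = records_from_detections(detections, wmodel, scene.transform)
        table = class_summary(records)
        report["weight_model"] = {"slope_g_per_cm3": round(wmodel.slope, 4),
                                  "intercept_g": round(wmodel.intercept, 2),
                                  "r_squared": round(wmodel.r_squared, 4),
                                  "n": wmodel.n}
        report["class_table"] = {
            "classes": table["weight_class"].tolist(),
            "counts": table["count"].tolist(),
            "percent": table["percent"].tolist(),
            "marketable_share_percent": table.attrs["marketable_share"],
        }

    with _stage(report, "grid"):
        grid = aggregate_grid(records, cell_size_m=config.cell_size_m)
        fs = field_summary(grid)
        report["field_summary"] = {k: (round(v, 4) if isinstance(v, float) else v)
                                   for k, v in asdict(fs).items()}
        try:
            report["field_summary"]["count_weight_r"] = round(
                count_weight_correlation(grid), 4)
        except ValueError:
            report["field_summary"]["count_weight_r"] = None

    with _stage(report, "evaluate"):
        match = match_detections(truth, records, radius_m=config.match_radius_m)
        precision = precision_audit(records, scene.label_mask,
                                    n_sample=config.audit_sample,
                                    seed=seeds["audit"],
                                    transform=scene.transform)
        report["evaluation"] = {
            "detection_rate": round(match.detection_rate, 4),
            "n_matched": len(match.pairs),
            "n_unmatched_truth": len(match.unmatched_truth),
            "n_unmatched_detections": len(match.unmatched_detections),
            "match_radius_m": config.match_radius_m,
            "audit_precision": precision,
        }
        log.info("detection rate %.1f%%", 100 * match.detection_rate)

    if out:
        with _stage(report, "write"):
            write_raster(os.path.join(out, "scene.tif"), scene.image, scene.transform)
            write_raster(os.path.join(out, "mask_raw.tif"),
                         mask.astype(np.uint8), scene.transform)
            write_raster(os.path.join(out, "mask_clean.tif"),
                         clean.astype(np.uint8), scene.transform)
            truth_to_frame(truth).to_csv(os.path.join(out, "truth.csv"), index=False)
            records_to_frame(records).to_csv(
                os.path.join(out, "fruit_records.csv"), index=False)
            table.to_csv(os.path.join(out, "class_summary.csv"), index=False)
            grid.to_frame().to_csv(os.path.join(out, "grid.csv"), index=False)
            write_geojson(detections_to_geojson(detections, scene.transform, records),
                          os.path.join(out, "detections.geojson"))
            write_geojson(grid_to_geojson(grid), os.path.join(out, "grid.geojson"))
            with open(os.path.join(out, "report.json"), "w") as fh:
                json.dump(report, fh, indent=1)
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    # SizeDistribution dataclasses inside SceneConfig serialize via asdict already
    return d
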