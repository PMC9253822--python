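"""End-to-end orchestration: scene/image -> features -> selection -> model
-> map -> calibration -> metrics, from one configuration object.

Every artifact is written under ``output_dir`` and recorded (with a SHA-256
hash) in ``manifest.json`` together with the seed, stage timings and library
versions, so a run is fully reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .calibration import DEFAULT_ORDER, DEFAULT_THRESHOLD, calibrate_map
from .classifiers import predict_map, train_classifier
from .feature_selection import gini_importance, subset_search
from .metrics import MetricsReport, evaluate
from .multiscale import (
    DEFAULT_WAVELET,
    DEFAULT_WINDOWS,
    DT1_FEATURES,
    build_feature_stack,
)
from .raster_io import (
    MultispectralImage,
    SampleSet,
    read_multispectral,
    read_samples,
    write_raster,
    write_samples,
)
from .synthetic_scene import SceneSpec, generate_sample_set, generate_scene

log = logging.getLogger("residuemap")


@dataclass
class PipelineConfig:
    """One run of the full workflow.

    Either ``image_path``/``samples_path`` point at existing inputs, or
    ``synthetic`` is true and a seeded scene is generated in place.
    """

    output_dir: str = "residuemap_run"
    image_path: str | None = None
    samples_path: str | None = None
    synthetic: bool = True
    scene_size: tuple[int, int] = (256, 256)
    n_samples_per_class: int = 400
    windows: Sequence[int] = DEFAULT_WINDOWS
    wavelet: str = DEFAULT_WAVELET
    fusion_rule: str = "maxabs"
    method: str = "svm"
    classifier_config: Mapping | None = None
    run_selection: bool = True
    importance_repeats: int = 10
    calibration_order: Sequence[int] = DEFAULT_ORDER
    calibration_threshold: int = DEFAULT_THRESHOLD
    seed: int = 0
    feature_subset: Sequence[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    metrics: MetricsReport
    metrics_calibrated: MetricsReport
    selected_features: tuple[str, ...]
    artifacts: dict[str, str] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}
    rng_seed = int(config.seed)

    def stage(name: str):
        log.info("stage: %s", name)
        return time.perf_counter()

    # --- inputs -----------------------------------------------------------
    t0 = stage("inputs")
    if config.synthetic:
        spec = SceneSpec(size=tuple(config.scene_size), seed=rng_seed)
        image, truth_map = generate_scene(spec)
        samples = generate_sample_set(
            truth_map, config.n_samples_per_class, seed=rng_seed
        )
        write_raster(image, out / "scene.tif")
        write_raster(truth_map, out / "truth.tif")
        write_samples(samples, out / "samples.csv")
        artifacts["scene"] = str(out / "scene.tif")
        artifacts["truth"] = str(out / "truth.tif")
    else:
        if not config.image_path or not config.samples_path:
            raise ValueError(
                "non-synthetic runs need image_path and samples_path"
            )
        image = read_multispectral(config.image_path)
        samples = read_samples(
            config.samples_path, image.shape, seed=rng_seed
        )
    artifacts["samples"] = str(out / "samples.csv")
    if not config.synthetic:
        write_samples(samples, out / "samples.csv")
    timings["inputs"] = time.perf_counter() - t0

    # --- feature stack ----------------------------------------------------
    t0 = stage("features")
    stack = build_feature_stack(
        image, windows=config.windows, wavelet=config.wavelet,
        rule=config.fusion_rule,
    )
    stack_image = MultispectralImage(
        np.stack([stack.layers[n] for n in stack.names]),
        band_names=stack.names,
        geotransform=image.geotransform,
    )
    write_raster(stack_image, out / "features.tif")
    artifacts["features"] = str(out / "features.tif")
    timings["features"] = time.perf_counter() - t0

    # --- sample tables ----------------------------------------------------
    train = samples.train
    val = samples.validation
    X_train = stack.sample_table(train["row"].to_numpy(), train["col"].to_numpy())
    y_train = train["label"].to_numpy()
    X_val = stack.sample_table(val["row"].to_numpy(), val["col"].to_numpy())
    y_val = val["label"].to_numpy()

    # --- importance + subset search ---------------------------------------
    selected = tuple(config.feature_subset or ())
    if config.run_selection and not selected:
        t0 = stage("selection")
        table = gini_importance(
            X_train, y_train, stack.names,
            n_repeats=config.importance_repeats, seed=rng_seed,
        )
        (out / "importance.json").write_text(
            json.dumps(table.as_dict(), indent=2)
        )
        artifacts["importance"] = str(out / "importance.json")
        trials, selected = subset_search(
            X_train, y_train, X_val, y_val, stack.names,
            ranking=table.ranking(),
            extra_trials=[DT1_FEATURES, DT1_FEATURES + ("PC1",)],
            seed=rng_seed,
        )
        (out / "subset_trials.json").write_text(
            json.dumps(
                [
                    {"features": list(t.features), "kappa": t.kappa, "oa": t.oa,
                     "model": t.model_tag}
                    for t in trials
                ],
                indent=2,
            )
        )
        artifacts["subset_trials"] = str(out / "subset_trials.json")
        timings["selection"] = time.perf_counter() - t0
    elif not selected:
        selected = stack.names

    # --- training ---------------------------------------------------------
    t0 = stage("training")
    idx = [stack.names.index(n) for n in selected]
    model = train_classifier(
        config.method, X_train[:, idx], y_train,
        feature_names=selected, config=config.classifier_config,
        seed=rng_seed,
    )
    model_meta = {
        "method": model.method,
        "feature_names": list(model.feature_names),
        "hyperparameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.hyperparameters.items()
        },
        "seed": model.seed,
        "train_time_s": model.train_time,
        "scaled": model.scaler is not None,
    }
    (out / "model.json").write_text(json.dumps(model_meta, indent=2))
    artifacts["model"] = str(out / "model.json")
    timings["training"] = time.perf_counter() - t0

    # --- classification ---------------------------------------------------
    t0 = stage("classification")
    nodata = None
    if image.nodata is not None:
        nodata = ~image.valid_mask()
    raw_map, timing = predict_map(model, stack.subset(selected), nodata)
    write_raster(raw_map, out / "map_raw.tif")
    artifacts["map_raw"] = str(out / "map_raw.tif")
    timings["classification"] = time.perf_counter() - t0

    # --- calibration ------------------------------------------------------
    t0 = stage("calibration")
    calibrated = calibrate_map(
        raw_map, order=config.calibration_order,
        threshold=config.calibration_threshold,
    )
    write_raster(calibrated, out / "map_calibrated.tif")
    artifacts["map_calibrated"] = str(out / "map_calibrated.tif")
    timings["calibration"] = time.perf_counter() - t0

    # --- evaluation -------------------------------------------------------
    t0 = stage("evaluation")
    vr, vc = val["row"].to_numpy(), val["col"].to_numpy()
    report = evaluate(y_val, raw_map.labels[vr, vc], tc=timing.seconds)
    report_cal = evaluate(y_val, calibrated.labels[vr, vc], tc=timing.seconds)
    report.to_json(out / "metrics.json")
    report_cal.to_json(out / "metrics_calibrated.json")
    artifacts["metrics"] = str(out / "metrics.json")
    artifacts["metrics_calibrated"] = str(out / "metrics_calibrated.json")
    timings["evaluation"] = time.perf_counter() - t0

    manifest = {
        "residuemap_version": __version__,
        "numpy_version": np.__version__,
        "seed": rng_seed,
        "config": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in asdict(config).items()
            if not isinstance(v, Mapping) or v is None
        },
        "selected_features": list(selected),
        "stage_timings_s": timings,
        "artifacts": {
            name: {"path": path, "sha256": _sha256(Path(path))}
            for name, path in artifacts.items()
            if Path(path).exists()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    artifacts["manifest"] = str(out / "manifest.json")
    return PipelineResult(
        metrics=report,
        metrics_calibrated=report_cal,
        selected_features=tuple(selected),
        artifacts=artifacts,
    )
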