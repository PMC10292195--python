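"""Configuration-driven orchestration of the full analysis.

Stages, in order: obtain inputs (synthetic generation or file ingest) ->
apply mask -> assign 100-km blocks -> repeated spatial CV evaluation ->
deployment fit -> per-scenario probability / MoV / hard-class prediction
-> optional legend aggregation -> confidence-filtered transition detection
with equal-area accounting -> scenario agreement. Every artifact path ends
up in a JSON run manifest together with the echoed config, a config hash
and library versions; identical configs reproduce bit-identical synthetic
inputs.
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
import yaml

from . import io as bio_io
from .blocking import assign_blocks, make_spatial_folds
from .ensemble import HyperParams, fit_stacked_model, predict_probabilities
from .evaluation import run_spatial_cv
from .maps import (
    ProbabilityCube,
    TranslationScheme,
    hard_classify,
    margin_of_victory,
    translate_probabilities,
)
from .synthetic import (
    STANDARD_LAYER_SPEC,
    CovariateStack,
    GridSpec,
    ObservationTable,
    ScenarioDelta,
    extract_features,
    generate_covariates,
    generate_true_labels,
    perturb_scenario,
    sample_observations,
)
from .transitions import detect_transitions, pixel_areas, scenario_agreement, transition_areas

__all__ = ["RunConfig", "PipelineError", "apply_mask", "run_pipeline", "DEMO_CONFIG"]

log = logging.getLogger("biomeshift")


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


@dataclass
class RunConfig:
    """Validated run configuration (usually loaded from YAML)."""

    output_dir: str
    grid: dict
    covariates: dict
    labels: dict
    observations: dict
    scenarios: list
    cv: dict = field(default_factory=lambda: {"k": 5, "repeats": 5})
    block_size_km: float = 100.0
    mov_threshold: float = 50.0
    filter_mode: str = "both"
    aggregation: dict | None = None
    mask_path: str | None = None
    points_path: str | None = None
    hyperparams: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=lambda: {"data": 0, "folds": 0, "learners": 0})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "grid": self.grid,
            "covariates": self.covariates,
            "labels": self.labels,
            "observations": self.observations,
            "scenarios": self.scenarios,
            "cv": self.cv,
            "block_size_km": self.block_size_km,
            "mov_threshold": self.mov_threshold,
            "filter_mode": self.filter_mode,
            "aggregation": self.aggregation,
            "mask_path": self.mask_path,
            "points_path": self.points_path,
            "hyperparams": self.hyperparams,
            "seeds": self.seeds,
        }

    def validate(self) -> None:
        tags = [s["scenario_tag"] for s in self.scenarios]
        if len(set(tags)) != len(tags):
            raise ValueError("scenario tags must be unique")
        for s in self.scenarios:
            if float(s.get("precipitation_scale", 1.0)) <= 0:
                raise ValueError(f"scenario {s['scenario_tag']}: precipitation_scale must be > 0")
        for p in (self.mask_path, self.points_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if self.filter_mode not in ("both", "current", "future"):
            raise ValueError("filter_mode must be both / current / future")
        GridSpec(**self.grid)  # raises on bad grid
        HyperParams(**self.hyperparams)


def apply_mask(stack: CovariateStack, mask_raster: np.ndarray) -> CovariateStack:
    """Union the stack's mask with an exclusion raster (nonzero = exclude)."""
    mask_raster = np.asarray(mask_raster)
    if mask_raster.shape != stack.grid.shape:
        raise ValueError("mask raster does not match the stack grid")
    out = stack.copy()
    extra = mask_raster.astype(bool) if mask_raster.dtype != bool else mask_raster
    out.mask = out.mask | extra
    for name in out.layers:
        out.layers[name][out.mask] = np.nan
    return out


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage=%s status=start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage=%s status=error error=%r", name, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage=%s status=done wall_s=%.2f", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def _layer_spec(cfg: dict):
    spec = cfg.get("layer_spec", "standard")
    if spec == "standard":
        return STANDARD_LAYER_SPEC
    return [tuple(item) for item in spec]


def _write_cube(outdir: Path, tag: str, cube: ProbabilityCube, mov: np.ndarray,
                hard, sd=None) -> list[Path]:
    d = outdir / tag
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, name in enumerate(cube.class_list):
        safe = str(name).replace(" ", "_").replace("/", "-")
        paths.append(bio_io.write_ascii_grid(d / f"prob_{i:02d}_{safe}.asc",
                                             cube.values[i], cube.grid))
        if sd is not None:
            paths.append(bio_io.write_ascii_grid(d / f"sd_{i:02d}_{safe}.asc",
                                                 sd[i], cube.grid))
    paths.append(bio_io.write_ascii_grid(d / "mov.asc", mov, cube.grid))
    hard_out = np.where(hard.classes < 0, np.nan, hard.classes.astype(float))
    paths.append(bio_io.write_ascii_grid(d / "hard_class.asc", hard_out, cube.grid))
    legend = d / "legend.json"
    legend.write_text(json.dumps({"classes": list(map(str, cube.class_list))}, indent=2))
    paths.append(legend)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the run manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(
            level=logging.INFO,
            format="%(asctime)s %(name)s %(levelname)s %(message)s",
        )
    cfg_echo = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_echo, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    artifacts: list[Path] = []
    data_seed = int(config.seeds.get("data", 0))
    fold_seed = int(config.seeds.get("folds", 0))
    learner_seed = int(config.seeds.get("learners", 0))
    hp = HyperParams(**config.hyperparams)

    @_stage("inputs")
    def _inputs():
        grid = GridSpec(**config.grid)
        stack = generate_covariates(
            grid,
            _layer_spec(config.covariates),
            corr_length=float(config.covariates.get("corr_length", 6.0)),
            seed=data_seed,
        )
        if config.mask_path:
            mask_arr, mask_grid = bio_io.read_ascii_grid(config.mask_path)
            if mask_grid != grid:
                raise ValueError("mask raster grid mismatch")
            stack = apply_mask(stack, np.nan_to_num(mask_arr, nan=1.0) != 0)
        labels = generate_true_labels(
            stack,
            K=int(config.labels["K"]),
            rule_seed=data_seed + 1,
            prevalence_skew=float(config.labels.get("prevalence_skew", 1.0)),
            latent_layers=tuple(config.labels["latent_layers"])
            if "latent_layers" in config.labels
            else None,
        )
        if config.points_path:
            frame = pd.read_csv(config.points_path)
            obs = ObservationTable(frame=frame, legend=list(labels.class_names))
        else:
            obs = sample_observations(
                labels,
                n_points=int(config.observations["n_points"]),
                n_clusters=int(config.observations.get("n_clusters", 25)),
                label_noise=float(config.observations.get("label_noise", 0.0)),
                seed=data_seed + 2,
            )
        artifacts.extend(bio_io.write_stack(outdir / "covariates", stack))
        artifacts.append(bio_io.write_observations_csv(outdir / "observations.csv", obs))
        artifacts.append(
            bio_io.write_observations_geojson(outdir / "observations.geojson", obs)
        )
        return stack, labels, obs

    stack, labels, obs = _inputs()

    @_stage("blocking")
    def _blocking():
        X, feature_names = extract_features(stack, obs)
        blocks = assign_blocks(obs, block_size_km=config.block_size_km)
        folds = make_spatial_folds(blocks, k=int(config.cv.get("k", 5)),
                                   repeat_index=0, seed=fold_seed)
        fold_csv = outdir / "folds.csv"
        frame = blocks.frame.copy()
        frame["fold"] = folds.fold
        frame["repeat"] = 0
        frame.to_csv(fold_csv, index=False)
        artifacts.append(fold_csv)
        return X, feature_names, blocks, folds

    X, feature_names, blocks, folds = _blocking()
    y = obs.label_codes()

    @_stage("evaluation")
    def _evaluate():
        report = run_spatial_cv(
            X,
            y,
            blocks,
            k=int(config.cv.get("k", 5)),
            repeats=int(config.cv.get("repeats", 5)),
            hp=hp,
            seed=fold_seed,
            class_list=list(labels.class_names),
        )
        per_repeat = outdir / "metrics_per_repeat.csv"
        report.per_repeat.to_csv(per_repeat, index=False)
        class_csv = outdir / "metrics_per_class.csv"
        report.class_table.to_csv(class_csv, index=False)
        summary = bio_io.write_json(outdir / "metrics_summary.json", report.to_json_dict())
        artifacts.extend([per_repeat, class_csv, summary])
        return report

    report = _evaluate()

    @_stage("fit")
    def _fit():
        m = fit_stacked_model(
            X,
            y,
            folds,
            hp=hp,
            feature_names=feature_names,
            class_list=list(labels.class_names),
            seed=learner_seed,
        )
        model_path = outdir / "model.joblib"
        m.save(model_path)
        artifacts.append(model_path)
        return m

    model = _fit()

    scheme = None
    if config.aggregation:
        targets = tuple(dict.fromkeys(config.aggregation.values()))
        scheme = TranslationScheme(mapping=dict(config.aggregation), target_list=targets)

    @_stage("predict")
    def _predict_epoch(epoch_stack: CovariateStack, tag: str):
        cube, sd = predict_probabilities(model, epoch_stack)
        mov = margin_of_victory(cube)
        hard = hard_classify(cube)
        artifacts.extend(_write_cube(outdir, tag, cube, mov, hard, sd=sd))
        if scheme is not None:
            agg = translate_probabilities(cube, scheme)
            agg_mov = margin_of_victory(agg)
            agg_hard = hard_classify(agg)
            artifacts.extend(_write_cube(outdir, f"{tag}_aggregated", agg, agg_mov, agg_hard))
            return agg_hard, agg_mov
        return hard, mov

    current_hard, current_mov = _predict_epoch(stack, "current")

    areas = pixel_areas(stack.grid)
    change_maps = []
    scenario_totals = {}

    @_stage("transitions")
    def _transitions():
        for s in config.scenarios:
            delta = ScenarioDelta(
                temperature_shift=float(s.get("temperature_shift", 0.0)),
                precipitation_scale=float(s.get("precipitation_scale", 1.0)),
                scenario_tag=str(s["scenario_tag"]),
            )
            future = perturb_scenario(stack, delta)
            fut_hard, fut_mov = _predict_epoch(future, delta.scenario_tag)
            change = detect_transitions(
                (current_hard, current_mov),
                (fut_hard, fut_mov),
                threshold=float(config.mov_threshold),
                filter_mode=config.filter_mode,
            )
            change_maps.append(change)
            table = transition_areas(change, areas)
            tpath = outdir / f"transitions_{delta.scenario_tag}.csv"
            table.to_long().to_csv(tpath, index=False)
            artifacts.append(tpath)
            artifacts.append(
                bio_io.write_ascii_grid(
                    outdir / f"change_{delta.scenario_tag}.asc",
                    change.confident_changed.astype(float),
                    stack.grid,
                )
            )
            scenario_totals[delta.scenario_tag] = table.grand_total
        if change_maps:
            agreement = scenario_agreement(change_maps)
            artifacts.append(
                bio_io.write_ascii_grid(
                    outdir / "scenario_agreement.asc", agreement.astype(float), stack.grid
                )
            )

    _transitions()

    import sklearn
    import xgboost

    manifest = {
        "config": cfg_echo,
        "config_hash": cfg_hash,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
        "metrics_summary": report.summary,
        "scenario_change_km2": scenario_totals,
        "artifacts": [str(p) for p in artifacts],
    }
    bio_io.write_json(outdir / "manifest.json", manifest)
    manifest["manifest_path"] = str(outdir / "manifest.json")
    return manifest


DEMO_CONFIG: dict = {
    "output_dir": "biomeshift_demo",
    "grid": {"n_rows": 48, "n_cols": 48, "lon_min": -6.0, "lat_min": -6.0, "cell_size": 0.25},
    "covariates": {"layer_spec": "standard", "corr_length": 5.0},
    "labels": {
        "K": 4,
        "prevalence_skew": 2.0,
        "latent_layers": ["bio01_mean_annual_temp", "annual_precipitation"],
    },
    "observations": {"n_points": 600, "n_clusters": 25, "label_noise": 0.1},
    "cv": {"k": 5, "repeats": 2},
    "block_size_km": 100.0,
    "mov_threshold": 50.0,
    "aggregation": {"B01": "G1", "B02": "G1", "B03": "G2", "B04": "G2"},
    "scenarios": [
        {"scenario_tag": "RCP2.6", "temperature_shift": 1.0, "precipitation_scale": 0.98},
        {"scenario_tag": "RCP4.5", "temperature_shift": 2.0, "precipitation_scale": 0.95},
        {"scenario_tag": "RCP8.5", "temperature_shift": 4.0, "precipitation_scale": 0.90},
    ],
    "seeds": {"data": 20, "folds": 21, "learners": 22},
}
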