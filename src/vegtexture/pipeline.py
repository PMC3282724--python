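"""End-to-end orchestration and file I/O.

Binds the stages — scene simulation, stand attributes, index layers,
texture extraction, exhaustive model search, permutation nulls and
leave-two-out CV — into one reproducible run driven by a JSON config.
All tabular exchange is CSV; rasters are plain float32 multiband TIFF
(band order BLUE, RED, IR).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .cross_validation import cross_validate
from .model_search import ExhaustiveSearch, select_best, transform_response
from .null_models import null_table
from .spectral_layers import build_layers
from .stand_attributes import (ATTRIBUTE_COLUMNS, attribute_table,
                               validate_attribute_table)
from .synthetic_scene import (ReflectanceScene, ScenarioConfig, generate_scene,
                              generate_stem_table)
from .texture_features import FEATURE_COLUMNS, extract_features

log = logging.getLogger("vegtexture")

BAND_ORDER = ("BLUE", "RED", "IR")

#: attributes modeled against texture and the transform applied to each.
#: H' can be exactly 0 (single-species plots), so it gets the unit offset.
DEFAULT_TRANSFORMS = {
    "Hgt": "log", "BA_T": "log", "BA_U": "log", "CC_T": "log", "CC_U": "log",
    "Dn_T": "log", "Dn_U": "log", "S_T": "log", "S_U": "log",
    "H_T": "log-offset", "H_U": "log-offset", "D_T": "log", "D_U": "log",
    "Age": "log",
}


# ---------------------------------------------------------------------------
# raster / table I/O


def write_scene(scene: ReflectanceScene, image_path, plots_path) -> None:
    stackarr = np.stack([scene.bands[b] for b in BAND_ORDER]).astype(np.float32)
    tifffile.imwrite(image_path, stackarr, photometric="minisblack")
    scene.plot_registry.to_csv(plots_path, index=False)


def read_scene(image_path, plots_path) -> ReflectanceScene:
    arr = tifffile.imread(image_path)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise ValueError("expected a 3-band (BLUE, RED, IR) raster")
    bands = {b: arr[i].astype(float) for i, b in enumerate(BAND_ORDER)}
    plots = pd.read_csv(plots_path)
    return ReflectanceScene(bands=bands, plot_registry=plots)


class SchemaError(ValueError):
    pass


def read_attribute_table(path) -> pd.DataFrame:
    """Read and validate an attribute CSV with the standard 14-column schema."""
    table = pd.read_csv(path)
    missing = [c for c in ATTRIBUTE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"attribute table missing column(s): {missing}")
    problems = validate_attribute_table(table)
    if problems:
        raise SchemaError("; ".join(problems))
    return table


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    output_dir: str = "results"
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    window: int = 15
    levels: int = 64
    distance: int = 1
    model_sizes: tuple[int, ...] = (1, 2, 3)
    transforms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    null_reps: int = 1000
    seed: int = 0
    mature_age: float | None = None  # numeric age for mature plots; None drops Age rows

    def __post_init__(self) -> None:
        if self.window % 2 != 1 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.null_reps < 1:
            raise ValueError("null_reps must be >= 1")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["scenario"]["stand_layout"] = [
            dataclasses.asdict(s) for s in self.scenario.stand_layout]
        Path(path).write_text(json.dumps(d, indent=2, default=list))


def _responses(attrs: pd.DataFrame, transforms: dict[str, str]) -> dict[str, np.ndarray]:
    out = {}
    for name, method in transforms.items():
        out[name] = transform_response(attrs[name].to_numpy(dtype=float), method)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic scene; returns the manifest dict.

    Writes scene.tif, plots.csv, stems.csv, attributes.csv, features.csv,
    models.csv, null.csv, cv.csv and manifest.json under ``output_dir``.
    Identical config and seed reproduce byte-identical CSV payloads.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = dataclasses.replace(config.scenario, seed=config.seed)

    log.info("stage 1/6: simulating scene")
    scene = generate_scene(scenario)
    write_scene(scene, out / "scene.tif", out / "plots.csv")
    stems = generate_stem_table(scenario)
    stems.to_csv(out / "stems.csv", index=False)

    log.info("stage 2/6: stand attributes")
    ages = dict(zip(scene.plot_registry["plot_id"], scene.plot_registry["age"]))
    attrs = attribute_table(stems, ages)
    attrs.to_csv(out / "attributes.csv", index=False, float_format="%.10g")

    log.info("stage 3/6: index layers + texture extraction")
    stack = build_layers(scene.bands)
    features = extract_features(stack, scene.plot_registry, window=config.window,
                                levels=config.levels, distance=config.distance)
    features.to_csv(out / "features.csv", index=False, float_format="%.10g")

    merged = features.merge(attrs, on="plot_id")
    responses = _responses(merged, config.transforms)
    feat = merged[["plot_id", *FEATURE_COLUMNS]]

    log.info("stage 4/6: exhaustive model search (%d candidates/size max)",
             len(FEATURE_COLUMNS))
    search = ExhaustiveSearch(feat)
    model_rows = []
    chosen = {}
    for name, y in responses.items():
        res = select_best(feat, y, name, sizes=config.model_sizes,
                          transform=config.transforms[name], search=search)
        for k, fit in res.best.items():
            chosen[(name, k)] = fit.predictors
            model_rows.append({
                "attribute": name, "k": k,
                "predictors": "+".join(fit.predictors),
                "signs": "".join(fit.signs), "r2": fit.r2, "aicc": fit.aicc,
                "equally_good": k in res.equally_good,
                "candidates": res.n_candidates[k]})
    models = pd.DataFrame(model_rows)
    models.to_csv(out / "models.csv", index=False, float_format="%.10g")

    log.info("stage 5/6: permutation nulls (%d reps)", config.null_reps)
    nulls = null_table(feat, responses, sizes=config.model_sizes,
                       reps=config.null_reps, seed=config.seed)
    nulls.to_csv(out / "null.csv", index=False, float_format="%.10g")

    log.info("stage 6/6: leave-two-out cross-validation")
    cv_rows = []
    for (name, k), predictors in chosen.items():
        res = cross_validate(feat[list(predictors)].to_numpy(dtype=float),
                             responses[name], predictors=predictors,
                             response=name)
        cv_rows.append({"attribute": name, "k": k,
                        "predictors": "+".join(predictors), "ASS": res.ass,
                        "R2_CV": res.r2_cv,
                        "excluded_splits": res.excluded_splits})
    cv = pd.DataFrame(cv_rows)
    cv.to_csv(out / "cv.csv", index=False, float_format="%.10g")

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "window": config.window,
        "levels": config.levels,
        "n_plots": int(len(scene.plot_registry)),
        "n_plots_extracted": int(len(features)),
        "n_feature_columns": len(FEATURE_COLUMNS),
        "n_attributes_modeled": len(responses),
        "candidates_per_size": {
            str(k): int(len(responses)
                        * models.loc[models.k == k, "candidates"].iloc[0])
            for k in config.model_sizes},
        "rows": {"attributes": len(attrs), "features": len(features),
                 "models": len(models), "null": len(nulls), "cv": len(cv)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
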