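"""End-to-end workflow: simulate -> split -> calibrate -> select ->
refit simplified -> evaluate -> map, driven by a single validated config.

Stages communicate only through files in the run directory, and a manifest
records every seed and output digest so a rerun under the same config can
be checked for bit-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .calibration_models import (
    DEFAULT_DEPTH_GRID,
    DEFAULT_WIDTH_GRID,
    CalibratedModel,
    FnnModel,
    PlsrModel,
    save_model,
    search_fnn,
    select_n_latent,
)
from .chemmap import predict_map, render_map
from .evaluation import build_report, write_report_table
from .preprocessing import (
    DEFAULT_SPLIT_RATIO,
    DEFAULT_SPLIT_SEED,
    PreprocessingChain,
    SpectralDataset,
    fit_msc,
    apply_msc,
    fit_normalizer,
    holdout_split,
)
from .synthetic_data import (
    SimulationConfig,
    draw_indicator_means,
    preset_config,
    simulate_sample,
    simulate_spectral_dataset,
    _sample_ids,
)
from .wavelength_selection import (
    WavelengthSubset,
    full_subset,
    restrict_dataset,
    select_extrema,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "train_calibrated", "pipeline_config_schema"]


class SimulationOverrides(BaseModel):
    """Subset of simulator knobs exposed through the pipeline config."""

    n_fish: int = 15
    pieces_per_fish: int = 5
    image_shape: tuple[int, int] = (48, 64)
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    noise_sd: float = 0.01
    edge_elevation: float = 0.2
    seed: int = 20210521


class PipelineConfig(BaseModel):
    """Validated, fully-seeded description of one pipeline run."""

    indicator: Literal["tvbn", "tba"] = "tvbn"
    simulation: SimulationOverrides = Field(default_factory=SimulationOverrides)
    split_ratio: float = DEFAULT_SPLIT_RATIO
    split_seed: int = DEFAULT_SPLIT_SEED
    engines: list[Literal["plsr", "fnn"]] = ["plsr", "fnn"]
    plsr_max_latent: int = 15
    press_folds: int = 10
    cv_seed: int = 1
    fnn_width_grid: list[int] = list(DEFAULT_WIDTH_GRID)
    fnn_depth_grid: list[int] = list(DEFAULT_DEPTH_GRID)
    fnn_folds: int = 3
    fnn_epochs: int = 1500
    fnn_search_epochs: int = 600
    fnn_learning_rate: float = 0.01
    fnn_seed: int = 2
    prominence: float = 0.0
    map_model: str = "fnn_simplified"
    map_full_spectrum: bool = False

    @field_validator("split_ratio")
    @classmethod
    def _ratio_open_interval(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("split_ratio must lie strictly between 0 and 1")
        return v

    @field_validator("engines")
    @classmethod
    def _engines_nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("at least one engine must be enabled")
        return v

    def simulation_config(self) -> SimulationConfig:
        return preset_config(self.indicator, **self.simulation.model_dump())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def pipeline_config_schema() -> dict:
    """JSON schema the YAML config is validated against."""
    return PipelineConfig.model_json_schema()


# ---------------------------------------------------------------------------
# Training helper
# ---------------------------------------------------------------------------


def train_calibrated(
    calibration: SpectralDataset,
    subset: WavelengthSubset,
    engine: Literal["plsr", "fnn"],
    config: PipelineConfig,
    model_id: str,
) -> CalibratedModel:
    """Fit one engine behind a freshly fitted preprocessing chain.

    The chain (MSC reference and z-score statistics) is fitted on the
    calibration set restricted to ``subset``, so simplified models get
    preprocessing statistics native to their reduced band set.
    """
    cal_sub = restrict_dataset(calibration, subset)
    msc = fit_msc(cal_sub)
    corrected = SpectralDataset(
        X=apply_msc(msc, cal_sub.X),
        Y=cal_sub.Y,
        wavelengths=cal_sub.wavelengths,
        sample_ids=cal_sub.sample_ids,
    )
    normalizer = fit_normalizer(corrected)
    normalized = SpectralDataset(
        X=normalizer.apply_x(corrected.X),
        Y=normalizer.apply_y(corrected.Y),
        wavelengths=cal_sub.wavelengths,
        sample_ids=cal_sub.sample_ids,
    )

    model: PlsrModel | FnnModel
    if engine == "plsr":
        max_latent = min(config.plsr_max_latent, normalized.n_samples - 1, normalized.n_bands)
        result = select_n_latent(
            normalized, max_latent, folds=config.press_folds, seed=config.cv_seed
        )
        model = result.chosen_model
        logger.info("%s: chose %d latent variables", model_id, model.n_latent)
    else:
        result = search_fnn(
            normalized,
            width_grid=config.fnn_width_grid,
            depth_grid=config.fnn_depth_grid,
            folds=config.fnn_folds,
            seed=config.fnn_seed,
            epochs=config.fnn_search_epochs,
            learning_rate=config.fnn_learning_rate,
        )
        depth, width = result.candidates[result.chosen_index]
        model = result.chosen_model
        logger.info("%s: chose depth=%d width=%d", model_id, depth, width)

    chain = PreprocessingChain(
        band_indices=subset.indices, msc=msc, normalizer=normalizer
    )
    return CalibratedModel(
        model_id=model_id,
        indicator=calibration_indicator(config),
        chain=chain,
        model=model,
        wavelengths=calibration.wavelengths,
    )


def calibration_indicator(config: PipelineConfig) -> str:
    return config.indicator


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full workflow into ``out_dir`` and return that path.

    Emits, per enabled engine, a full-spectrum and a selected-wavelength
    ("simplified") model, plus the wavelength subset, a comparison report,
    a pixel-wise distribution map for one prediction-set sample, and a
    manifest of seeds and file digests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "models").mkdir(exist_ok=True)
    (out_dir / "maps").mkdir(exist_ok=True)

    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hsifresh")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)

    stage = "simulate"
    try:
        sim_config = config.simulation_config()
        dataset, chemistry = simulate_spectral_dataset(sim_config)
        dataset.to_csv(out_dir / "dataset_full.csv")
        chemistry.to_csv(out_dir / "chemistry.csv", index=False)
        logger.info("simulated %d samples on %d bands", dataset.n_samples, dataset.n_bands)

        stage = "split"
        calibration, prediction = holdout_split(
            dataset, ratio=config.split_ratio, seed=config.split_seed
        )

        stage = "calibrate-full"
        grid = dataset.wavelengths
        subset_all = full_subset(grid)
        models: dict[str, CalibratedModel] = {}
        for engine in config.engines:
            models[f"{engine}_full"] = train_calibrated(
                calibration, subset_all, engine, config, f"{engine}_full"
            )

        stage = "select-wavelengths"
        if "plsr_full" in models:
            selector = models["plsr_full"].model
        else:
            # internal PLSR purely to supply regression coefficients
            selector = train_calibrated(
                calibration, subset_all, "plsr", config, "_selector"
            ).model
        assert isinstance(selector, PlsrModel)
        subset = select_extrema(
            selector.coefficients, grid, min_prominence=config.prominence,
            source="plsr_full",
        )
        subset.to_csv(out_dir / f"subset_{config.indicator}.csv")
        logger.info("selected %d of %d wavelengths", len(subset), grid.size)

        stage = "calibrate-simplified"
        for engine in config.engines:
            models[f"{engine}_simplified"] = train_calibrated(
                calibration, subset, engine, config, f"{engine}_simplified"
            )

        stage = "evaluate"
        reports = [
            build_report(models[name], calibration, prediction)
            for name in sorted(models)
        ]
        write_report_table(reports, out_dir / "report.csv", out_dir / "report.md")
        for name, cm in models.items():
            save_model(cm, out_dir / "models" / f"{name}.json")

        stage = "map"
        map_model_name = config.map_model
        if config.map_full_spectrum:
            map_model_name = map_model_name.replace("_simplified", "_full")
        map_model = models[map_model_name]
        ids = _sample_ids(sim_config)
        values = draw_indicator_means(sim_config, len(ids))
        map_id = prediction.sample_ids[0]
        map_index = ids.index(map_id)
        sample = simulate_sample(
            sim_config, values[map_index], sample_index=map_index, sample_id=map_id
        )
        chem_map = predict_map(sample.hypercube, sample.roi_mask, map_model)
        render_map(chem_map, out=out_dir / "maps" / f"map_{map_id}.png")
        chem_map.to_csv(out_dir / "maps" / f"map_{map_id}.csv")

        stage = "manifest"
        digests = {
            str(p.relative_to(out_dir)): _sha256(p)
            for p in sorted(out_dir.rglob("*"))
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        }
        manifest = {
            "package_version": __version__,
            "config": json.loads(config.model_dump_json()),
            "seeds": {
                "simulation": sim_config.seed,
                "split": config.split_seed,
                "cv": config.cv_seed,
                "fnn": config.fnn_seed,
            },
            "n_samples": dataset.n_samples,
            "n_models": len(models),
            "map_sample": map_id,
            "digests": digests,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(log_handler)
        log_handler.close()

    return out_dir
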