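"""Shared fixtures.

Heavy synthetic datasets are session-scoped: the ``standard_tvbn`` bundle
(n = 397, scatter slope sd 0.05, pixel noise sd 0.01) backs the
parameter-recovery and spatial acceptance tests, while ``small_config``
keeps unit tests fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from hsifresh.calibration_models import CalibratedModel
from hsifresh.pipeline import PipelineConfig, train_calibrated
from hsifresh.preprocessing import SpectralDataset, holdout_split
from hsifresh.synthetic_data import (
    SimulationConfig,
    preset_config,
    simulate_spectral_dataset,
)
from hsifresh.wavelength_selection import full_subset, select_extrema

STANDARD_SEED = 20210521


def make_standard_config(**overrides) -> SimulationConfig:
    defaults = dict(
        n_fish=397,
        pieces_per_fish=1,
        image_shape=(32, 48),
        seed=STANDARD_SEED,
        scatter_slope_sd=0.05,
        noise_sd=0.01,
    )
    defaults.update(overrides)
    return preset_config("tvbn", **defaults)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return preset_config(
        "tvbn", n_fish=3, pieces_per_fish=2, image_shape=(16, 24), seed=42
    )


@dataclass
class StandardBundle:
    config: SimulationConfig
    dataset: SpectralDataset
    calibration: SpectralDataset
    prediction: SpectralDataset
    plsr_full: CalibratedModel
    plsr_simplified: CalibratedModel
    subset_size: int


@pytest.fixture(scope="session")
def standard_tvbn() -> StandardBundle:
    """Full-size synthetic TVB-N study with fitted PLSR models."""
    config = make_standard_config()
    dataset, _ = simulate_spectral_dataset(config)
    calibration, prediction = holdout_split(dataset, 0.85, STANDARD_SEED)
    pc = PipelineConfig(indicator="tvbn")
    plsr_full = train_calibrated(
        calibration, full_subset(dataset.wavelengths), "plsr", pc, "plsr_full"
    )
    subset = select_extrema(
        plsr_full.model.coefficients, dataset.wavelengths, min_prominence=0.0
    )
    plsr_simplified = train_calibrated(calibration, subset, "plsr", pc, "plsr_simplified")
    return StandardBundle(
        config=config,
        dataset=dataset,
        calibration=calibration,
        prediction=prediction,
        plsr_full=plsr_full,
        plsr_simplified=plsr_simplified,
        subset_size=len(subset),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_linear_dataset(
    n: int = 60, k: int = 12, seed: int = 0, noise_sd: float = 0.0
) -> SpectralDataset:
    """Random spectra with an exactly (or nearly) linear target."""
    gen = np.random.default_rng(seed)
    X = gen.normal(size=(n, k))
    beta = gen.normal(size=k)
    y = X @ beta + gen.normal(0.0, noise_sd, n)
    return SpectralDataset(
        X=X,
        Y=y,
        wavelengths=np.linspace(400.0, 1000.0, k),
        sample_ids=[f"s{i:03d}" for i in range(n)],
    )
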