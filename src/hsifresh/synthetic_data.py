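"""Synthetic fillet hypercube generator.

Produces fillet-like reflectance hypercubes, white/black reference cubes,
elliptical ROI masks, and reference chemistry tables with the statistical
structure the downstream chemometrics assumes:

* spectra on a uniform 472-band grid spanning 400-1000 nm, with Gaussian
  absorption features near 417, 553, 836, and 974 nm whose depths are
  linear in the local indicator value (a Beer-Lambert-flavoured mixing
  model that a linear calibration can recover);
* per-pixel multiplicative/additive scatter distortion plus white noise,
  so multiplicative scatter correction has real work to do;
* per-sample indicator means drawn from a truncated normal matched to the
  published summary statistics of each indicator;
* spatial indicator fields in which pixels near the fillet edge carry
  elevated values relative to the interior.

All randomness flows from a single root seed through named substreams, so
identical configurations yield bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .hypercube_io import (
    Hypercube,
    ReferencePair,
    extract_roi,
    write_envi,
    write_mask_png,
)
from .preprocessing import SpectralDataset

__all__ = [
    "ReferenceStats",
    "TVBN_REFERENCE_STATS",
    "TBA_REFERENCE_STATS",
    "SimulationConfig",
    "SyntheticSample",
    "default_wavelength_grid",
    "make_endmember_spectra",
    "mixture_reflectance",
    "simulate_sample",
    "simulate_dataset",
    "simulate_spectral_dataset",
    "iter_samples",
    "draw_indicator_means",
    "summarize_values",
    "BOUNDARY_RHO",
    "write_reference_cubes",
    "encode_raw",
    "preset_config",
    "make_planted_nonlinearity_dataset",
    "write_dataset_files",
]


# ---------------------------------------------------------------------------
# Published reference statistics used as simulator presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceStats:
    """Summary statistics of a reference-chemistry indicator."""

    indicator: str
    units: str
    n_samples: int
    maximum: float
    minimum: float
    mean: float
    sd: float

    @property
    def value_range(self) -> float:
        """Range recomputed as maximum minus minimum."""
        return self.maximum - self.minimum


TVBN_REFERENCE_STATS = ReferenceStats(
    indicator="tvbn", units="mg/100 g", n_samples=397,
    maximum=34.920, minimum=8.176, mean=14.518, sd=5.509,
)
TBA_REFERENCE_STATS = ReferenceStats(
    indicator="tba", units="mg/kg", n_samples=316,
    maximum=3.072, minimum=0.097, mean=0.61, sd=0.48,
)

_PRESETS = {"tvbn": TVBN_REFERENCE_STATS, "tba": TBA_REFERENCE_STATS}


def default_wavelength_grid(
    n_bands: int = 472, low_nm: float = 400.0, high_nm: float = 1000.0
) -> np.ndarray:
    """Uniform instrument wavelength grid (default 472 bands, 400-1000 nm)."""
    if n_bands < 2:
        raise ValueError("need at least 2 bands")
    if not high_nm > low_nm:
        raise ValueError("wavelength range must be increasing")
    return np.linspace(low_nm, high_nm, n_bands)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All knobs of the synthetic fillet generator.

    Defaults mirror the imaging setup being emulated: a 472-band grid over
    400-1000 nm with absorption features at 417/553/836/974 nm, and
    indicator statistics taken from the TVB-N reference table.
    """

    n_fish: int = 15
    pieces_per_fish: int = 5
    image_shape: tuple[int, int] = (48, 64)
    n_bands: int = 472
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    band_centers: tuple[float, ...] = (417.0, 553.0, 836.0, 974.0)
    band_widths: tuple[float, ...] = (30.0, 35.0, 18.0, 14.0)
    indicator: Literal["tvbn", "tba"] = "tvbn"
    indicator_range: tuple[float, float] = (
        TVBN_REFERENCE_STATS.minimum,
        TVBN_REFERENCE_STATS.maximum,
    )
    indicator_mean_sd: tuple[float, float] = (
        TVBN_REFERENCE_STATS.mean,
        TVBN_REFERENCE_STATS.sd,
    )
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    noise_sd: float = 0.003
    assay_noise_sd: float = 0.5
    edge_elevation: float = 0.2
    seed: int = 20210521

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        lo, hi = self.wavelength_range
        if not hi > lo:
            raise ValueError("wavelength_range must be increasing")
        if len(self.band_widths) != len(self.band_centers):
            raise ValueError("band_widths must match band_centers in length")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError("band widths must be positive")
        rlo, rhi = self.indicator_range
        if not rlo < rhi:
            raise ValueError("indicator_range must satisfy min < max")
        for name in ("scatter_slope_sd", "scatter_offset_sd", "noise_sd", "assay_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.edge_elevation < 0:
            raise ValueError("edge_elevation must be >= 0")
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("image_shape must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        return default_wavelength_grid(self.n_bands, *self.wavelength_range)

    @property
    def n_samples(self) -> int:
        return self.n_fish * self.pieces_per_fish


#: Reference-assay repeatability (indicator units); roughly 9% of each
#: indicator's between-sample spread.
_PRESET_ASSAY_SD = {"tvbn": 0.5, "tba": 0.044}


def preset_config(indicator: str, **overrides) -> SimulationConfig:
    """Simulation config whose indicator statistics follow a preset table."""
    stats_ = _PRESETS[indicator.lower()]
    cfg = SimulationConfig(
        indicator=stats_.indicator,  # type: ignore[arg-type]
        indicator_range=(stats_.minimum, stats_.maximum),
        indicator_mean_sd=(stats_.mean, stats_.sd),
        assay_noise_sd=_PRESET_ASSAY_SD[stats_.indicator],
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Spectral forward model
# ---------------------------------------------------------------------------

_BASE_DEPTH = 0.15  # indicator-independent part of each band weight
_GAIN0 = 0.20  # weight gain of the first band over the indicator range
_GAIN_DECAY = 0.85  # geometric decay of gain magnitude across bands
_BAND_DEPTH = 0.60  # reflectance drop of each Gaussian feature at its centre
_BAND_TOP = 0.75  # off-feature reflectance of the band endmembers
_BACKGROUND_REFLECTANCE = 0.02


def make_endmember_spectra(config: SimulationConfig) -> np.ndarray:
    """Endmember matrix: one baseline row plus one row per absorption band.

    Row 0 is a gently sloping baseline; each further row is a Gaussian
    absorption feature whose reflectance minimum sits at the grid
    wavelength nearest its configured centre.  Levels are kept mid-range
    so scatter-distorted mixtures stay inside [0, 1] and clipping stays
    rare.  All values lie in [0, 1].
    """
    wl = config.wavelengths
    lo, hi = config.wavelength_range
    for center in config.band_centers:
        if not lo <= center <= hi:
            raise ValueError(
                f"band center {center} nm lies outside wavelength range [{lo}, {hi}] nm"
            )
    baseline = 0.55 + 0.10 * (wl - lo) / (hi - lo)
    rows = [baseline]
    for center, width in zip(config.band_centers, config.band_widths):
        rows.append(_BAND_TOP - _BAND_DEPTH * np.exp(-0.5 * ((wl - center) / width) ** 2))
    return np.vstack(rows)


def _depth_coefficients(config: SimulationConfig, values: np.ndarray) -> np.ndarray:
    """Per-band mixing weights, linear in the normalized indicator.

    Gains alternate in sign so the indicator changes the spectrum's shape
    rather than its overall level; a pure level change would be absorbed
    by multiplicative scatter correction and leave nothing to calibrate on.
    """
    lo, hi = config.indicator_range
    vn = (np.asarray(values, dtype=float) - lo) / (hi - lo)
    n_bands = len(config.band_centers)
    gains = _GAIN0 * _GAIN_DECAY ** np.arange(n_bands) * (-1.0) ** np.arange(n_bands)
    return _BASE_DEPTH + vn[..., None] * gains  # (..., n_bands)


def mixture_reflectance(config: SimulationConfig, values: np.ndarray) -> np.ndarray:
    """Noiseless, scatter-free reflectance for given indicator value(s).

    A convex combination of the endmembers: baseline weight plus one
    weight per absorption band, the band weights linear in the indicator.
    This is the generator's deterministic core and doubles as the oracle
    for forward/inverse consistency tests.
    """
    endmembers = make_endmember_spectra(config)
    values = np.asarray(values, dtype=float)
    if not config.band_centers:
        return np.broadcast_to(endmembers[0], values.shape + (config.n_bands,)).copy()
    coeff = _depth_coefficients(config, values)  # (..., m)
    c0 = 1.0 - coeff.sum(axis=-1)
    return c0[..., None] * endmembers[0] + coeff @ endmembers[1:]


# ---------------------------------------------------------------------------
# Spatial model
# ---------------------------------------------------------------------------


def _elliptical_radius(image_shape: tuple[int, int]) -> np.ndarray:
    """Normalized elliptical radius of each pixel (<= 1 inside the fillet)."""
    rows, cols = image_shape
    r = np.arange(rows)[:, None] - (rows - 1) / 2.0
    c = np.arange(cols)[None, :] - (cols - 1) / 2.0
    semi_r = 0.42 * rows
    semi_c = 0.46 * cols
    return np.sqrt((r / semi_r) ** 2 + (c / semi_c) ** 2)


#: Elliptical-radius threshold separating the boundary stratum (within 10%
#: of the minor axis from the edge) from the interior.
BOUNDARY_RHO = 0.9


@dataclass
class SyntheticSample:
    """One generated fillet piece with its ground truth."""

    sample_id: str
    hypercube: Hypercube
    roi_mask: np.ndarray
    true_indicator_mean: float
    true_indicator_field: np.ndarray
    boundary_mask: np.ndarray
    interior_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.roi_mask.shape != self.hypercube.spatial_shape:
            raise ValueError("roi_mask shape must equal hypercube spatial shape")


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, 1, sample_index)))


def simulate_sample(
    config: SimulationConfig,
    indicator_value: float,
    sample_index: int = 0,
    sample_id: str | None = None,
) -> SyntheticSample:
    """Generate one fillet piece at a given sample-mean indicator value.

    The ROI is an axis-aligned ellipse on a dark background.  The per-pixel
    indicator field equals the sample mean modulated so boundary pixels are
    elevated by ``edge_elevation`` relative to the interior (the field is
    rescaled so its ROI mean equals ``indicator_value`` exactly).  Pixel
    spectra are the endmember mixture at the local indicator value, then
    per-pixel multiplicative slope ``1 + N(0, scatter_slope_sd)``, additive
    offset ``N(0, scatter_offset_sd)``, and white noise ``N(0, noise_sd)``,
    clipped to [0, 1].

    ``sample_index`` names the random substream, so a sample can be
    regenerated independently of the rest of its dataset.
    """
    lo, hi = config.indicator_range
    if not lo <= indicator_value <= hi:
        raise ValueError(
            f"indicator value {indicator_value} outside configured range [{lo}, {hi}]"
        )
    rows, cols = config.image_shape
    rho = _elliptical_radius(config.image_shape)
    mask = rho <= 1.0
    boundary = mask & (rho >= BOUNDARY_RHO)
    interior = mask & (rho < BOUNDARY_RHO)

    # edge-elevated field, rescaled to hit the sample mean exactly
    profile = 1.0 + config.edge_elevation * rho**2
    profile = np.where(mask, profile, 0.0)
    field = indicator_value * profile / profile[mask].mean()

    mixture = np.where(
        mask[..., None],
        mixture_reflectance(config, field),
        _BACKGROUND_REFLECTANCE,
    )

    rng = _sample_rng(config.seed, sample_index)
    slope = 1.0 + rng.normal(0.0, config.scatter_slope_sd, (rows, cols, 1))
    offset = rng.normal(0.0, config.scatter_offset_sd, (rows, cols, 1))
    noise = rng.normal(0.0, config.noise_sd, (rows, cols, config.n_bands))
    reflectance = np.clip(slope * mixture + offset + noise, 0.0, 1.0)

    cube = Hypercube(reflectance, config.wavelengths, units_flag="reflectance")
    return SyntheticSample(
        sample_id=sample_id if sample_id is not None else f"S{sample_index:04d}",
        hypercube=cube,
        roi_mask=mask,
        true_indicator_mean=float(field[mask].mean()),
        true_indicator_field=np.where(mask, field, np.nan),
        boundary_mask=boundary,
        interior_mask=interior,
    )


# ---------------------------------------------------------------------------
# Dataset-level sampling
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncated normal has the given moments.

    The published tables report the moments of the *observed* (range-limited)
    values, so the parent of the truncated distribution is solved for by
    moment matching; sampling then reproduces the printed mean/sd rather
    than a truncation-shifted version of them.
    """

    def residual(p: np.ndarray) -> list[float]:
        mu, log_sigma = p
        sigma = float(np.exp(log_sigma))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return [float(d.mean()) - mean, float(d.std()) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - presets are solvable
        return mean, sd
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _draw_indicator_means(config: SimulationConfig, n: int) -> np.ndarray:
    mean, sd = config.indicator_mean_sd
    lo, hi = config.indicator_range
    mu, sigma = _truncnorm_parent(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    u = rng.uniform(size=n)
    values = stats.truncnorm(a, b, loc=mu, scale=sigma).ppf(u)
    return np.clip(values, lo, hi)


def _measured_values(config: SimulationConfig, true_values: np.ndarray) -> np.ndarray:
    """Reference-chemistry readings: true means plus seeded assay noise.

    Readings are kept inside the configured indicator range, as the
    published summary tables report range-limited values.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    noisy = np.asarray(true_values) + rng.normal(
        0.0, config.assay_noise_sd, len(true_values)
    )
    return np.clip(noisy, *config.indicator_range)


def draw_indicator_means(config: SimulationConfig, n: int) -> np.ndarray:
    """Draw per-sample indicator means from the moment-matched truncated normal."""
    return _draw_indicator_means(config, n)


def summarize_values(values: np.ndarray) -> dict:
    """Summary statistics in the layout of the reference tables.

    ``sd`` is the sample standard deviation and comes out NaN for a single
    observation (the undefined-variance flag).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("no values to summarize")
    return {
        "n": int(n),
        "max": float(values.max()),
        "min": float(values.min()),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if n > 1 else float("nan"),
        "range": float(values.max() - values.min()),
    }


def _sample_ids(config: SimulationConfig) -> list[str]:
    return [
        f"F{fish:03d}P{piece:02d}"
        for fish in range(1, config.n_fish + 1)
        for piece in range(1, config.pieces_per_fish + 1)
    ]


def _chemistry_table(config: SimulationConfig, ids: Sequence[str], values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": list(ids), "indicator": config.indicator, "value": values}
    )


def iter_samples(config: SimulationConfig) -> Iterator[SyntheticSample]:
    """Yield samples one at a time (cubes are large; avoid keeping them all)."""
    ids = _sample_ids(config)
    values = _draw_indicator_means(config, len(ids))
    for i, (sid, v) in enumerate(zip(ids, values)):
        yield simulate_sample(config, v, sample_index=i, sample_id=sid)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Generate the full sample list plus its chemistry table.

    Per-sample indicator means are drawn from the moment-matched truncated
    normal; the chemistry table is keyed by sample id and carries measured
    values (true means plus seeded assay noise).
    """
    if config.n_samples < 1:
        raise ValueError("need n_fish * pieces_per_fish >= 1")
    samples = list(iter_samples(config))
    values = _measured_values(config, [s.true_indicator_mean for s in samples])
    return samples, _chemistry_table(config, [s.sample_id for s in samples], values)


def simulate_spectral_dataset(
    config: SimulationConfig,
) -> tuple[SpectralDataset, pd.DataFrame]:
    """Stream samples, keep only their ROI mean spectra.

    Equivalent to running ``simulate_dataset`` and then ROI extraction, but
    without retaining hundreds of hypercubes in memory.
    """
    if config.n_samples < 1:
        raise ValueError("need n_fish * pieces_per_fish >= 1")
    ids, spectra, true_means = [], [], []
    for sample in iter_samples(config):
        roi = extract_roi(sample.hypercube, sample.roi_mask, sample.sample_id)
        ids.append(sample.sample_id)
        spectra.append(roi.mean_reflectance)
        true_means.append(sample.true_indicator_mean)
    measured = _measured_values(config, np.array(true_means))
    dataset = SpectralDataset(
        X=np.vstack(spectra),
        Y=measured,
        wavelengths=config.wavelengths,
        sample_ids=ids,
    )
    return dataset, _chemistry_table(config, ids, measured)


# ---------------------------------------------------------------------------
# Reference cubes and raw encoding
# ---------------------------------------------------------------------------

_WHITE_LEVEL = 3500.0
_BLACK_LEVEL = 80.0


def write_reference_cubes(config: SimulationConfig) -> ReferencePair:
    """Near-uniform white and black reference cubes in raw counts.

    White strictly exceeds black at every pixel and band; small seeded
    ripples keep them from being exactly constant.
    """
    rows, cols = config.image_shape
    shape = (rows, cols, config.n_bands)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    white = _WHITE_LEVEL + rng.uniform(0.0, 100.0, shape)
    black = _BLACK_LEVEL + rng.uniform(0.0, 10.0, shape)
    wl = config.wavelengths
    return ReferencePair(
        white=Hypercube(white, wl, units_flag="raw"),
        black=Hypercube(black, wl, units_flag="raw"),
    )


def encode_raw(cube: Hypercube, refs: ReferencePair) -> Hypercube:
    """Invert reflectance calibration: raw = black + R * (white - black)."""
    if cube.units_flag != "reflectance":
        raise ValueError("encode_raw expects a reflectance cube")
    raw = refs.black.values + cube.values * (refs.white.values - refs.black.values)
    return Hypercube(raw, cube.wavelengths, units_flag="raw")


# ---------------------------------------------------------------------------
# Planted-nonlinearity benchmark dataset
# ---------------------------------------------------------------------------


def make_planted_nonlinearity_dataset(
    n: int = 300,
    n_bands: int = 60,
    seed: int = 7,
    noise_sd: float = 0.02,
) -> SpectralDataset:
    """Spectra whose target is quadratic in one latent direction.

    A linear model can only capture the linear terms, so a network with at
    least one hidden layer should outperform it — the benchmark used to
    compare the two calibration engines.
    """
    rng = np.random.default_rng(seed)
    wl = default_wavelength_grid(n_bands)
    centers = np.array([480.0, 650.0, 870.0])
    loadings = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / 60.0) ** 2)
    t = rng.normal(size=(n, 3))
    X = 0.5 + 0.08 * t @ loadings + rng.normal(0.0, 0.005, (n, n_bands))
    y = t[:, 0] + 0.8 * t[:, 0] ** 2 + 0.3 * t[:, 1] + rng.normal(0.0, noise_sd, n)
    ids = [f"P{i:04d}" for i in range(n)]
    return SpectralDataset(X=X, Y=y, wavelengths=wl, sample_ids=ids)


# ---------------------------------------------------------------------------
# File emission (ENVI cubes, PNG masks, CSV chemistry)
# ---------------------------------------------------------------------------


def write_dataset_files(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Write a simulated dataset to disk in exchange formats.

    Emits ``white.hdr``/``black.hdr`` reference cubes, one raw ENVI cube
    and ROI mask PNG per sample, and ``chemistry.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = write_reference_cubes(config)
    write_envi(refs.white, out_dir / "white.hdr")
    write_envi(refs.black, out_dir / "black.hdr")
    ids, true_means = [], []
    for sample in iter_samples(config):
        raw = encode_raw(sample.hypercube, refs)
        write_envi(raw, out_dir / f"{sample.sample_id}.hdr")
        write_mask_png(sample.roi_mask, out_dir / f"{sample.sample_id}_mask.png")
        ids.append(sample.sample_id)
        true_means.append(sample.true_indicator_mean)
    measured = _measured_values(config, np.array(true_means))
    _chemistry_table(config, ids, measured).to_csv(out_dir / "chemistry.csv", index=False)
    return out_dir
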