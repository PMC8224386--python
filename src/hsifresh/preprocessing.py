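"""Spectral preprocessing: multiplicative scatter correction, z-score
normalization, and the calibration/prediction hold-out split.

All statistics (MSC reference, normalization centres/scales) are fitted on
the calibration set only and then applied unchanged to prediction spectra
and to pixel spectra during chemical mapping, so no information leaks from
the held-out data into the model chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "MscModel",
    "Normalizer",
    "PreprocessingChain",
    "fit_msc",
    "apply_msc",
    "holdout_split",
    "fit_normalizer",
    "DEFAULT_SPLIT_SEED",
    "DEFAULT_SPLIT_RATIO",
]

#: Default hold-out seed; an arbitrary but recorded constant.
DEFAULT_SPLIT_SEED = 20210521
#: Calibration fraction of the hold-out split.
DEFAULT_SPLIT_RATIO = 0.85


@dataclass
class SpectralDataset:
    """Aligned spectra and reference values for one indicator.

    Attributes
    ----------
    X : ndarray, shape (n, k)
        One mean-reflectance spectrum per row.
    Y : ndarray, shape (n,)
        Reference indicator values, in indicator units.
    wavelengths : ndarray, shape (k,)
        Band centres in nanometres.
    sample_ids : list of str
    """

    X: np.ndarray
    Y: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.sample_ids = list(self.sample_ids)
        n, k = self.X.shape
        if self.Y.shape != (n,):
            raise ValueError(f"Y shape {self.Y.shape} != ({n},)")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length disagrees with X rows")
        if self.wavelengths.shape != (k,):
            raise ValueError(
                f"wavelength count {self.wavelengths.size} != band count {k}"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, indices: np.ndarray) -> "SpectralDataset":
        indices = np.asarray(indices)
        return SpectralDataset(
            X=self.X[indices],
            Y=self.Y[indices],
            wavelengths=self.wavelengths,
            sample_ids=[self.sample_ids[i] for i in indices],
        )

    def to_csv(self, path: str | Path) -> Path:
        """Serialize as ``sample_id, wl_<nm>..., target`` CSV."""
        cols = {"sample_id": self.sample_ids}
        for j, wl in enumerate(self.wavelengths):
            cols[f"wl_{wl:.4f}"] = self.X[:, j]
        cols["target"] = self.Y
        path = Path(path)
        pd.DataFrame(cols).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralDataset":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.startswith("wl_")]
        wavelengths = np.array([float(c[3:]) for c in wl_cols])
        return cls(
            X=df[wl_cols].to_numpy(float),
            Y=df["target"].to_numpy(float),
            wavelengths=wavelengths,
            sample_ids=[str(s) for s in df["sample_id"]],
        )


# ---------------------------------------------------------------------------
# Multiplicative scatter correction
# ---------------------------------------------------------------------------


@dataclass
class MscModel:
    """MSC reference spectrum (the calibration-set mean)."""

    reference_spectrum: np.ndarray

    def __post_init__(self) -> None:
        self.reference_spectrum = np.asarray(self.reference_spectrum, dtype=float)
        if not np.all(np.isfinite(self.reference_spectrum)):
            raise ValueError("MSC reference spectrum must be finite")


def fit_msc(calibration: SpectralDataset) -> MscModel:
    """Fit MSC on a calibration set: reference = columnwise mean spectrum."""
    if calibration.n_samples < 2:
        raise ValueError("MSC requires at least 2 calibration spectra")
    return MscModel(reference_spectrum=calibration.X.mean(axis=0))


def apply_msc(model: MscModel, X: np.ndarray) -> np.ndarray:
    """Remove per-spectrum affine scatter distortion.

    Each row ``x`` is regressed on the reference, ``x = a + b * ref``, by
    least squares over bands; the corrected row is ``(x - a) / b``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = model.reference_spectrum
    if X.shape[1] != ref.size:
        raise ValueError(f"spectra have {X.shape[1]} bands, reference has {ref.size}")

    ref_centered = ref - ref.mean()
    denom = float(ref_centered @ ref_centered)
    if denom < 1e-24:
        raise ValueError("MSC reference spectrum is constant; slope undefined")
    x_mean = X.mean(axis=1)
    b = (X - x_mean[:, None]) @ ref_centered / denom
    degenerate = np.nonzero(np.abs(b) < 1e-12)[0]
    if degenerate.size:
        raise ValueError(f"degenerate MSC slope (|b| < 1e-12) for row(s) {degenerate.tolist()}")
    a = x_mean - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


# ---------------------------------------------------------------------------
# Hold-out split
# ---------------------------------------------------------------------------


def holdout_split(
    dataset: SpectralDataset,
    ratio: float = DEFAULT_SPLIT_RATIO,
    seed: int = DEFAULT_SPLIT_SEED,
) -> tuple[SpectralDataset, SpectralDataset]:
    """Seeded random hold-out split into (calibration, prediction).

    Calibration receives ``floor(ratio * n)`` samples; the remainder goes
    to prediction.  Row order within each part follows the original
    dataset so results are reproducible sample-id-wise.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = dataset.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_cal = int(np.floor(ratio * n))
    if n_cal == 0 or n_cal == n:
        raise ValueError(f"split {n_cal}/{n - n_cal} leaves one side empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal_idx = np.sort(perm[:n_cal])
    pred_idx = np.sort(perm[n_cal:])
    return dataset.subset_rows(cal_idx), dataset.subset_rows(pred_idx)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass
class Normalizer:
    """Per-band and target z-score parameters, fitted on calibration only."""

    band_center: np.ndarray
    band_scale: np.ndarray
    target_center: float
    target_scale: float

    def __post_init__(self) -> None:
        self.band_center = np.asarray(self.band_center, dtype=float)
        self.band_scale = np.asarray(self.band_scale, dtype=float)
        if np.any(self.band_scale <= 0) or self.target_scale <= 0:
            raise ValueError("all normalization scales must be > 0")

    def apply_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.band_center) / self.band_scale

    def apply_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.target_center) / self.target_scale

    def invert_y(self, y_norm: np.ndarray) -> np.ndarray:
        return np.asarray(y_norm, dtype=float) * self.target_scale + self.target_center


def fit_normalizer(calibration: SpectralDataset) -> Normalizer:
    """Fit per-band and target z-score statistics on the calibration set.

    Raises
    ------
    ValueError
        If any band (or the target) has zero variance; offending band
        indices are listed.
    """
    if calibration.n_samples < 2:
        raise ValueError("normalizer needs at least 2 calibration samples")
    center = calibration.X.mean(axis=0)
    scale = calibration.X.std(axis=0, ddof=1)
    # constant bands can leave a floating-point residue instead of exactly 0
    zero = np.nonzero(scale <= 1e-10 * np.maximum(1.0, np.abs(center)))[0]
    if zero.size:
        raise ValueError(f"zero-variance band(s) at indices {zero.tolist()}")
    t_center = float(calibration.Y.mean())
    t_scale = float(calibration.Y.std(ddof=1))
    if t_scale <= 0:
        raise ValueError("target has zero variance on the calibration set")
    return Normalizer(center, scale, t_center, t_scale)


# ---------------------------------------------------------------------------
# Serializable preprocessing chain (band subset -> MSC -> z-score)
# ---------------------------------------------------------------------------


@dataclass
class PreprocessingChain:
    """The exact transform applied before a calibration model.

    Applied to raw full-grid reflectance spectra in this order: restrict to
    ``band_indices``, MSC against the calibration reference (optional), then
    per-band z-score.  Stored alongside each model so pixel-wise mapping
    replays the identical chain.
    """

    band_indices: np.ndarray
    msc: MscModel | None
    normalizer: Normalizer

    def __post_init__(self) -> None:
        self.band_indices = np.asarray(self.band_indices, dtype=int)

    def transform_x(self, X_full: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X_full, dtype=float))[:, self.band_indices]
        if self.msc is not None:
            X = apply_msc(self.msc, X)
        return self.normalizer.apply_x(X)

    def to_dict(self) -> dict:
        return {
            "band_indices": self.band_indices.tolist(),
            "msc_reference": (
                None if self.msc is None else self.msc.reference_spectrum.tolist()
            ),
            "band_center": self.normalizer.band_center.tolist(),
            "band_scale": self.normalizer.band_scale.tolist(),
            "target_center": self.normalizer.target_center,
            "target_scale": self.normalizer.target_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessingChain":
        msc = None if d["msc_reference"] is None else MscModel(np.array(d["msc_reference"]))
        norm = Normalizer(
            np.array(d["band_center"]),
            np.array(d["band_scale"]),
            float(d["target_center"]),
            float(d["target_scale"]),
        )
        return cls(np.array(d["band_indices"], dtype=int), msc, norm)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessingChain":
        return cls.from_dict(json.loads(Path(path).read_text()))
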