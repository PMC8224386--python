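"""Optimal-wavelength selection from PLSR regression coefficients.

Bands whose regression coefficient is a local extremum carry the most
information about the target; restricting models to those bands shrinks
the input dimension by an order of magnitude at little cost in accuracy.
Two published selections (35 bands for TVB-N, 18 for TBA) ship as package
fixtures for regression tests and as CLI presets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import SpectralDataset

__all__ = [
    "WavelengthSubset",
    "select_extrema",
    "restrict_dataset",
    "reduction_ratio",
    "subset_from_wavelengths",
    "load_published_subset",
    "full_subset",
]


@dataclass
class WavelengthSubset:
    """Ordered band indices retained after selection."""

    indices: np.ndarray
    wavelengths_nm: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.indices.size == 0:
            raise ValueError("wavelength subset may not be empty")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("subset indices must be strictly increasing")
        if self.wavelengths_nm.shape != self.indices.shape:
            raise ValueError("wavelengths and indices must align")

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"index": self.indices, "wavelength_nm": self.wavelengths_nm}
        ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "") -> "WavelengthSubset":
        df = pd.read_csv(path)
        return cls(
            indices=df["index"].to_numpy(int),
            wavelengths_nm=df["wavelength_nm"].to_numpy(float),
            source=source or str(path),
        )


def select_extrema(
    coefficients: np.ndarray,
    wavelengths: np.ndarray,
    min_prominence: float = 0.0,
    source: str = "",
) -> WavelengthSubset:
    """Select bands where the coefficient vector has interior local extrema.

    An interior index is kept when its coefficient strictly exceeds both
    neighbours (local maximum) or is strictly below both (local minimum),
    and its magnitude reaches ``min_prominence * max|coefficients|``.
    Plateaus bounded on both sides by smaller (larger) values contribute
    their leftmost index.  Endpoints are never selected.

    Raises
    ------
    ValueError
        If no interior extremum exists (e.g. monotone or constant input).
    """
    beta = np.asarray(coefficients, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    k = beta.size
    if k < 3:
        raise ValueError("need at least 3 coefficients")
    if beta.shape != wavelengths.shape:
        raise ValueError("coefficients and wavelengths must have equal length")
    if not 0.0 <= min_prominence <= 1.0:
        raise ValueError("min_prominence must lie in [0, 1]")

    selected: list[int] = []
    i = 1
    while i < k - 1:
        # skip forward over any plateau starting at i
        j = i
        while j < k - 1 and beta[j + 1] == beta[i]:
            j += 1
        left, right = beta[i - 1], beta[j + 1] if j < k - 1 else beta[i]
        if j < k - 1:
            if beta[i] > left and beta[i] > right:
                selected.append(i)
            elif beta[i] < left and beta[i] < right:
                selected.append(i)
        i = j + 1

    if not selected:
        raise ValueError("coefficient vector has no interior local extrema")
    amplitude = float(np.max(np.abs(beta)))
    kept = [i for i in selected if abs(beta[i]) >= min_prominence * amplitude]
    if not kept:
        raise ValueError(
            f"no extremum passes min_prominence={min_prominence} "
            f"(threshold {min_prominence * amplitude:.3g})"
        )
    idx = np.array(kept, dtype=int)
    return WavelengthSubset(indices=idx, wavelengths_nm=wavelengths[idx], source=source)


def restrict_dataset(dataset: SpectralDataset, subset: WavelengthSubset) -> SpectralDataset:
    """Keep only the subset's bands; targets and sample ids are untouched."""
    if subset.indices.min() < 0 or subset.indices.max() >= dataset.n_bands:
        raise ValueError(
            f"subset indices span [{subset.indices.min()}, {subset.indices.max()}] "
            f"but dataset has {dataset.n_bands} bands"
        )
    return SpectralDataset(
        X=dataset.X[:, subset.indices],
        Y=dataset.Y,
        wavelengths=dataset.wavelengths[subset.indices],
        sample_ids=dataset.sample_ids,
    )


def reduction_ratio(full_k: int, subset: WavelengthSubset) -> float:
    """Percentage of bands removed: ``100 * (full_k - |subset|) / full_k``."""
    if full_k < len(subset):
        raise ValueError("subset is larger than the full band count")
    return 100.0 * (full_k - len(subset)) / full_k


def subset_from_wavelengths(
    wavelengths_nm: np.ndarray,
    grid: np.ndarray,
    source: str = "",
) -> WavelengthSubset:
    """Map nominal wavelengths onto a grid by nearest band.

    Published lists quote integer nanometres while the instrument grid has
    ~1.27 nm spacing, so two adjacent list entries can round to one band;
    collisions bump the later entry to the next free higher index so the
    subset keeps one band per listed wavelength.
    """
    grid = np.asarray(grid, dtype=float)
    requested = np.sort(np.asarray(wavelengths_nm, dtype=float))
    taken: set[int] = set()
    indices = []
    for wl in requested:
        j = int(np.argmin(np.abs(grid - wl)))
        while j in taken:
            j += 1
        if j >= grid.size:
            raise ValueError(f"cannot place {wl} nm on the grid without collision")
        taken.add(j)
        indices.append(j)
    idx = np.sort(np.array(indices, dtype=int))
    return WavelengthSubset(indices=idx, wavelengths_nm=grid[idx], source=source)


# ---------------------------------------------------------------------------
# Published fixtures
# ---------------------------------------------------------------------------


def load_published_subset(indicator: str, grid: np.ndarray | None = None) -> WavelengthSubset:
    """Load the packaged published wavelength list for an indicator.

    With ``grid`` given, nominal wavelengths are mapped to grid indices via
    :func:`subset_from_wavelengths`; otherwise indices simply number the
    list entries and ``wavelengths_nm`` holds the nominal values.
    """
    name = {"tvbn": "tvbn_selected_wavelengths.csv", "tba": "tba_selected_wavelengths.csv"}[
        indicator.lower()
    ]
    resource = importlib.resources.files("hsifresh.data") / name
    nominal = pd.read_csv(str(resource))["wavelength_nm"].to_numpy(float)
    if grid is not None:
        return subset_from_wavelengths(nominal, grid, source=f"published:{indicator}")
    return WavelengthSubset(
        indices=np.arange(nominal.size),
        wavelengths_nm=nominal,
        source=f"published:{indicator}",
    )


def full_subset(wavelengths: np.ndarray, source: str = "full") -> WavelengthSubset:
    """The identity subset covering every band of a grid."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    return WavelengthSubset(
        indices=np.arange(wavelengths.size), wavelengths_nm=wavelengths, source=source
    )
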