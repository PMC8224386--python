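"""Pixel-wise chemical distribution maps.

Every masked pixel's reflectance spectrum is pushed through a calibrated
model's full preprocessing chain (band restriction, MSC, z-scoring) and
the model itself, yielding an indicator-unit value per pixel.  Maps render
as 8-bit false-colour PNGs on a shared scale so different samples remain
comparable pixel-to-pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps

from .calibration_models import CalibratedModel
from .hypercube_io import Hypercube

logger = logging.getLogger(__name__)

__all__ = ["ChemicalMap", "predict_map", "render_map", "pooled_color_scale"]

_BACKGROUND_RGB = (40, 40, 40)


@dataclass
class ChemicalMap:
    """Per-pixel indicator predictions over an ROI.

    ``values`` is NaN outside the mask; ``color_scale`` fixes the render
    range so multiple maps can share one scale.
    """

    values: np.ndarray
    mask: np.ndarray
    indicator: str
    color_scale: tuple[float, float]

    def __post_init__(self) -> None:
        vmin, vmax = self.color_scale
        if not vmin < vmax:
            raise ValueError("color_scale must satisfy vmin < vmax")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("map values must be finite inside the mask")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.values).to_csv(path, index=False, header=False)
        return path


def pooled_color_scale(predictions: np.ndarray) -> tuple[float, float]:
    """Robust shared scale: 1st/99th percentile of the pooled predictions."""
    finite = predictions[np.isfinite(predictions)]
    vmin, vmax = np.percentile(finite, [1, 99])
    if vmin >= vmax:
        vmin, vmax = float(finite.min()), float(finite.min()) + 1e-9
    return float(vmin), float(vmax)


def predict_map(
    cube: Hypercube,
    mask: np.ndarray,
    model: CalibratedModel,
    color_scale: tuple[float, float] | None = None,
) -> ChemicalMap:
    """Predict the indicator at every masked pixel of a reflectance cube.

    The model's stored preprocessing chain handles band restriction, MSC
    against the calibration reference, and normalization, so the cube must
    be on the same instrument grid the model was trained on.
    """
    if cube.units_flag != "reflectance":
        raise ValueError("predict_map expects a reflectance-calibrated cube")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise ValueError("mask shape does not match cube spatial shape")
    if not mask.any():
        raise ValueError("mask is empty")
    if cube.n_bands != model.wavelengths.size or not np.allclose(
        cube.wavelengths, model.wavelengths, atol=0.05  # nm; survives header rounding
    ):
        raise ValueError("cube wavelength grid does not match the model's grid")

    spectra = cube.values[mask]  # (n_pixels, bands)
    predictions = model.predict(spectra)
    values = np.full(mask.shape, np.nan)
    values[mask] = predictions
    if color_scale is None:
        color_scale = pooled_color_scale(predictions)
    return ChemicalMap(
        values=values, mask=mask, indicator=model.indicator, color_scale=color_scale
    )


def render_map(
    chem_map: ChemicalMap,
    palette: str = "jet",
    out: str | Path = "map.png",
    units: str = "",
) -> Path:
    """Write the map as an 8-bit false-colour PNG plus a colorbar sidecar.

    Out-of-scale predictions clamp to the scale endpoints (counts logged);
    background pixels get a fixed dark colour.  The main PNG is a pure
    array render, so identical inputs produce bit-identical files; the
    colorbar is written alongside as ``<out>_colorbar.png``.
    """
    if not chem_map.mask.any():
        raise ValueError("cannot render a map with an empty mask")
    out = Path(out)
    vmin, vmax = chem_map.color_scale
    values = chem_map.values
    inside = chem_map.mask

    n_low = int(np.count_nonzero(values[inside] < vmin))
    n_high = int(np.count_nonzero(values[inside] > vmax))
    if n_low or n_high:
        logger.info("clamped %d low / %d high pixels to the colour scale", n_low, n_high)

    normed = np.clip((values - vmin) / (vmax - vmin), 0.0, 1.0)
    cmap = colormaps[palette]
    rgba = cmap(np.nan_to_num(normed), bytes=True)  # (r, c, 4) uint8
    rgb = rgba[..., :3].copy()
    rgb[~inside] = _BACKGROUND_RGB
    iio.imwrite(out, rgb, extension=".png")

    fig, ax = plt.subplots(figsize=(1.2, 4))
    sm = plt.cm.ScalarMappable(
        cmap=cmap, norm=matplotlib.colors.Normalize(vmin=vmin, vmax=vmax)
    )
    fig.colorbar(sm, cax=ax, label=units or chem_map.indicator)
    fig.savefig(out.with_name(out.stem + "_colorbar.png"), bbox_inches="tight", dpi=100)
    plt.close(fig)
    return out
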