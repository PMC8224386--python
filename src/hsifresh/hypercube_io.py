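"""ENVI hypercube I/O, reflectance calibration, and ROI spectral extraction.

Hypercubes are held in canonical ``(rows, cols, bands)`` order with an
attached wavelength vector in nanometres.  On disk they follow the ENVI
convention: an ASCII ``.hdr`` next to a raw little-endian float32 binary in
BSQ, BIL, or BIP interleave.

Reflectance calibration divides out the instrument response using a white
and a black reference cube::

    R_c = (R_0 - B) / (W - B)
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocessing import SpectralDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Hypercube",
    "ReferencePair",
    "RoiSpectrum",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "extract_roi",
    "assemble_dataset",
    "read_mask_png",
    "write_mask_png",
]

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class Hypercube:
    """A 3-D spectral image: ``values[row, col, band]`` plus wavelengths.

    Parameters
    ----------
    values : ndarray, shape (rows, cols, bands)
        Raw counts or reflectance, depending on ``units_flag``.
    wavelengths : ndarray, shape (bands,)
        Strictly increasing band centres in nanometres.
    units_flag : {"raw", "reflectance"}
        Whether the cube has been calibrated to reflectance.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    units_flag: Literal["raw", "reflectance"] = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"hypercube values must be 3-D, got shape {self.values.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ValueError(
                f"wavelength vector length {self.wavelengths.size} does not match "
                f"band count {self.values.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.units_flag not in ("raw", "reflectance"):
            raise ValueError(f"unknown units_flag {self.units_flag!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class ReferencePair:
    """White and black reference cubes used for reflectance calibration."""

    white: Hypercube
    black: Hypercube

    def __post_init__(self) -> None:
        if self.white.shape != self.black.shape:
            raise ValueError(
                f"white {self.white.shape} and black {self.black.shape} shapes differ"
            )


@dataclass
class RoiSpectrum:
    """Mean reflectance spectrum over a region of interest."""

    sample_id: str
    mean_reflectance: np.ndarray
    pixel_count: int

    def __post_init__(self) -> None:
        self.mean_reflectance = np.asarray(self.mean_reflectance, dtype=float)
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")


# ---------------------------------------------------------------------------
# ENVI read / write
# ---------------------------------------------------------------------------

# numpy dtype for each ENVI "data type" code we support
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    """Parse ``key = value`` pairs; ``{...}`` values may span lines."""
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        fields[key] = m.group(2).strip()
    return fields


def _header_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace("\n", " ").split(",") if tok.strip()]


def _data_path_for(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for candidate in (stem.with_suffix(".raw"), stem.with_suffix(".img"), stem):
        if candidate.exists() and candidate != header_path:
            return candidate
    raise FileNotFoundError(f"no data file found next to header {header_path}")


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI header/binary pair into a canonical hypercube.

    The on-disk interleave (BSQ, BIL, or BIP) is undone so the returned
    cube is always ``(rows, cols, bands)``.

    Raises
    ------
    ValueError
        If the header lacks a ``wavelength`` field, declares an unknown
        interleave, or its dimensions disagree with the binary file size.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())

    for key in ("samples", "lines", "bands", "interleave"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required field {key!r}")
    if "wavelength" not in fields:
        raise ValueError(f"ENVI header {header_path} has no 'wavelength' field")

    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype_code = int(fields.get("data type", 4))
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    else:
        dtype = dtype.newbyteorder("<")
    offset = int(fields.get("header offset", 0))

    wavelengths = np.array(_header_list(fields["wavelength"]))
    data_path = _data_path_for(header_path)
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = rows * cols * bands
    if raw.size != expected:
        raise ValueError(
            f"binary {data_path} holds {raw.size} elements but header declares "
            f"{rows}x{cols}x{bands} = {expected}"
        )

    if interleave == "bsq":  # (bands, rows, cols)
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":  # (rows, bands, cols)
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip: (rows, cols, bands)
        cube = raw.reshape(rows, cols, bands)

    return Hypercube(np.ascontiguousarray(cube), wavelengths, units_flag="raw")


def write_envi(
    cube: Hypercube,
    header_path: str | Path,
    interleave: str = "bil",
    dtype: np.dtype | type = np.float32,
) -> Path:
    """Write a hypercube as an ENVI ``.hdr`` plus raw ``.raw`` binary.

    Returns the header path.  Data are written little-endian.
    """
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(dtype).newbyteorder("<")
    if np.dtype(dtype.newbyteorder("=")) not in _DTYPE_CODES:
        raise ValueError(f"dtype {dtype} not representable in ENVI")
    rows, cols, bands = cube.shape

    if interleave == "bsq":
        ondisk = cube.values.transpose(2, 0, 1)
    elif interleave == "bil":
        ondisk = cube.values.transpose(0, 2, 1)
    else:
        ondisk = cube.values

    data_path = header_path.with_suffix(".raw")
    np.ascontiguousarray(ondisk, dtype=dtype).tofile(data_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(dtype.newbyteorder('='))]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    return header_path


# ---------------------------------------------------------------------------
# Calibration and extraction
# ---------------------------------------------------------------------------


def _broadcast_reference(ref: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Allow single-row push-broom references to stand in for full cubes."""
    if ref.shape == target_shape:
        return ref
    if ref.shape[0] == 1 and ref.shape[1:] == target_shape[1:]:
        return np.broadcast_to(ref, target_shape)
    raise ValueError(f"reference shape {ref.shape} incompatible with cube {target_shape}")


def calibrate_reflectance(raw: Hypercube, refs: ReferencePair) -> Hypercube:
    """Convert raw counts to relative reflectance via white/black references.

    Computes ``(R_0 - B) / (W - B)`` elementwise and clips the result to
    ``[0, 1]``; clipped-element counts are logged, not raised.

    Raises
    ------
    ValueError
        If ``raw`` is already reflectance, or white <= black anywhere.
    """
    if raw.units_flag != "raw":
        raise ValueError("cube is already calibrated to reflectance")
    white = _broadcast_reference(refs.white.values, raw.shape)
    black = _broadcast_reference(refs.black.values, raw.shape)

    span = white.astype(float) - black.astype(float)
    bad = int(np.count_nonzero(span <= 0))
    if bad:
        raise ValueError(
            f"white reference must exceed black everywhere; {bad} elements violate this"
        )

    reflectance = (raw.values.astype(float) - black) / span
    n_clipped = int(np.count_nonzero((reflectance < 0) | (reflectance > 1)))
    if n_clipped:
        logger.info("clipped %d reflectance values to [0, 1]", n_clipped)
    reflectance = np.clip(reflectance, 0.0, 1.0)
    return Hypercube(reflectance, raw.wavelengths, units_flag="reflectance")


def extract_roi(cube: Hypercube, mask: np.ndarray, sample_id: str = "") -> RoiSpectrum:
    """Mean spectrum over the masked pixels of a reflectance cube."""
    if cube.units_flag != "reflectance":
        raise ValueError("extract_roi expects a reflectance-calibrated cube")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise ValueError(f"mask shape {mask.shape} != cube spatial shape {cube.spatial_shape}")
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise ValueError("ROI mask is empty")
    mean_spectrum = cube.values[mask].mean(axis=0)
    return RoiSpectrum(sample_id=sample_id, mean_reflectance=mean_spectrum, pixel_count=n_pixels)


def assemble_dataset(
    spectra: Sequence[RoiSpectrum],
    chemistry: pd.DataFrame,
    indicator: str,
    wavelengths: np.ndarray,
) -> SpectralDataset:
    """Join ROI spectra with reference chemistry into an aligned dataset.

    ``chemistry`` must have columns ``sample_id``, ``indicator``, ``value``.
    Rows are canonically ordered by ``sample_id`` so the result is
    independent of input ordering.
    """
    if len(spectra) == 0:
        raise ValueError("no spectra to assemble")
    ids = [s.sample_id for s in spectra]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated sample_id(s): {dupes}")

    chem = chemistry[chemistry["indicator"] == indicator]
    lookup = dict(zip(chem["sample_id"], chem["value"]))
    if len(lookup) != len(chem):
        raise ValueError("duplicated sample_id in chemistry table")
    missing = [i for i in ids if i not in lookup]
    if missing:
        raise ValueError(f"chemistry table lacks {indicator} entries for: {missing}")

    order = np.argsort(np.asarray(ids, dtype=object))
    X = np.stack([spectra[i].mean_reflectance for i in order])
    Y = np.array([lookup[spectra[i].sample_id] for i in order], dtype=float)
    sample_ids = [spectra[i].sample_id for i in order]
    return SpectralDataset(
        X=X, Y=Y, wavelengths=np.asarray(wavelengths, dtype=float), sample_ids=sample_ids
    )


# ---------------------------------------------------------------------------
# Mask I/O (8-bit PNG, 255 = inside ROI)
# ---------------------------------------------------------------------------


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)), extension=".png")
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img >= 128
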