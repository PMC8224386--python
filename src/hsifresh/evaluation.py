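"""Model evaluation: the six calibration/prediction metrics and
comparison-table reporting.

For each model the report carries Pearson r, the coefficient of
determination, and the root mean square error on both the calibration and
the prediction set.  r and R-squared are computed independently (R-squared
as ``1 - SS_res / SS_tot`` about the evaluated set's own target mean); no
consistency between them is assumed or enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration_models import CalibratedModel
from .preprocessing import SpectralDataset

__all__ = [
    "EvaluationReport",
    "pearson_r",
    "r_squared",
    "rmse",
    "build_report",
    "report_table",
    "write_report_table",
]


def _check_pair(y: np.ndarray, yhat: np.ndarray, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return y, yhat


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    """Sample Pearson correlation between measured and predicted values."""
    y, yhat = _check_pair(y, yhat, 2)
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    denom = np.sqrt(float(yc @ yc) * float(pc @ pc))
    if denom == 0.0:
        raise ValueError("zero variance in measured or predicted values")
    return float(yc @ pc) / denom


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, ``1 - SS_res / SS_tot``."""
    y, yhat = _check_pair(y, yhat, 2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("target has zero variance; R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error, in indicator units."""
    y, yhat = _check_pair(y, yhat, 1)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class EvaluationReport:
    """Six-metric summary of one model on calibration + prediction sets."""

    model_id: str
    indicator: str
    n_wavelengths: int
    n_latent_or_width: int
    r_c: float
    R2_c: float
    RMSEC: float
    r_p: float
    R2_p: float
    RMSEP: float
    residuals_pred: np.ndarray


def build_report(
    model: CalibratedModel,
    calibration: SpectralDataset,
    prediction: SpectralDataset,
) -> EvaluationReport:
    """Evaluate a calibrated model on its calibration and prediction sets.

    Both datasets must be on the model's full instrument grid; the model's
    own preprocessing chain is applied internally.
    """
    if prediction.n_samples == 0:
        raise ValueError("prediction set is empty")
    yhat_c = model.predict(calibration.X)
    yhat_p = model.predict(prediction.X)
    return EvaluationReport(
        model_id=model.model_id,
        indicator=model.indicator,
        n_wavelengths=model.n_wavelengths,
        n_latent_or_width=model.n_latent_or_width,
        r_c=pearson_r(calibration.Y, yhat_c),
        R2_c=r_squared(calibration.Y, yhat_c),
        RMSEC=rmse(calibration.Y, yhat_c),
        r_p=pearson_r(prediction.Y, yhat_p),
        R2_p=r_squared(prediction.Y, yhat_p),
        RMSEP=rmse(prediction.Y, yhat_p),
        residuals_pred=prediction.Y - yhat_p,
    )


_TABLE_COLUMNS = [
    "indicator", "model", "No. W", "No. LV",
    "r_c", "R2_c", "RMSEC", "r_p", "R2_p", "RMSEP",
]


def report_table(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Stack reports into a comparison table, one row per model/indicator."""
    rows = [
        {
            "indicator": r.indicator,
            "model": r.model_id,
            "No. W": r.n_wavelengths,
            "No. LV": r.n_latent_or_width,
            "r_c": r.r_c,
            "R2_c": r.R2_c,
            "RMSEC": r.RMSEC,
            "r_p": r.r_p,
            "R2_p": r.R2_p,
            "RMSEP": r.RMSEP,
        }
        for r in reports
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_report_table(
    reports: Sequence[EvaluationReport], csv_path: str | Path, md_path: str | Path | None = None
) -> pd.DataFrame:
    """Serialize the comparison table; rounding happens only at presentation."""
    table = report_table(reports)
    table.to_csv(Path(csv_path), index=False, float_format="%.10g")
    if md_path is not None:
        shown = table.copy()
        for col in ("r_c", "R2_c", "RMSEC", "r_p", "R2_p", "RMSEP"):
            shown[col] = shown[col].map(lambda v: f"{v:.3f}")
        Path(md_path).write_text(shown.to_markdown(index=False) + "\n")
    return table
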