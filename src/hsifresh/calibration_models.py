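"""Calibration engines: NIPALS partial least squares regression and a
feed-forward neural network, both with PRESS-driven complexity selection.

Both engines train on preprocessed (scatter-corrected, z-scored) spectra
and predict in normalized target space; the :class:`CalibratedModel`
wrapper bundles a fitted engine with its preprocessing chain and converts
predictions back to indicator units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .preprocessing import PreprocessingChain, SpectralDataset

__all__ = [
    "PlsrModel",
    "FnnModel",
    "ModelSearchResult",
    "CalibratedModel",
    "fit_plsr",
    "select_n_latent",
    "fit_fnn",
    "search_fnn",
    "predict",
    "save_model",
    "load_model",
    "DEFAULT_WIDTH_GRID",
    "DEFAULT_DEPTH_GRID",
]

#: Hidden-width candidates for the network search (22 kept deliberately so
#: that a width matching the published model size is on the grid).
DEFAULT_WIDTH_GRID = (4, 8, 16, 22, 32)
DEFAULT_DEPTH_GRID = (1, 2, 3)

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500
#: Candidates whose PRESS is within this relative slack of the minimum are
#: treated as tied; ties resolve toward the simpler model.
_PRESS_REL_TOL = 0.02


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------


@dataclass
class PlsrModel:
    """NIPALS PLSR fit with its collapsed coefficient vector.

    ``predict(X) = (X - x_mean) @ coefficients + intercept`` reproduces the
    component-wise NIPALS prediction exactly.
    """

    n_latent: int
    x_weights: np.ndarray  # (k, c)
    x_loadings: np.ndarray  # (k, c)
    y_loadings: np.ndarray  # (c,)
    x_mean: np.ndarray  # (k,)
    y_mean: float
    coefficients: np.ndarray  # (k,) in (normalized) band space
    intercept: float

    @property
    def n_bands(self) -> int:
        return self.coefficients.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_bands:
            raise ValueError(f"X has {X.shape[1]} bands, model expects {self.n_bands}")
        return X @ self.coefficients + self.intercept


def _nipals(X: np.ndarray, y: np.ndarray, n_latent: int) -> PlsrModel:
    """NIPALS with X and y deflation; single response column."""
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    n, k = X.shape

    W = np.zeros((k, n_latent))
    P = np.zeros((k, n_latent))
    q = np.zeros(n_latent)
    achieved = 0
    for comp in range(n_latent):
        u = yc.copy()
        w = np.zeros(k)
        for _ in range(_NIPALS_MAX_ITER):
            w_new = Xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm < 1e-14:
                break
            w_new = w_new / norm
            t = Xc @ w_new
            tt = float(t @ t)
            if tt < 1e-14:
                break
            q_comp = float(yc @ t) / tt
            if abs(q_comp) < 1e-300:
                break
            u_next = yc / q_comp
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
            u = u_next
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-14 or not np.any(w):
            break  # residual rank exhausted; keep components found so far
        p = Xc.T @ t / tt
        q_comp = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - q_comp * t
        W[:, comp] = w
        P[:, comp] = p
        q[comp] = q_comp
        achieved += 1

    if achieved == 0:
        raise ValueError("X has no usable variance; cannot extract a PLS component")
    W, P, q = W[:, :achieved], P[:, :achieved], q[:achieved]
    # B = W (P'W)^-1 q collapses the sequential components to one vector
    coefficients = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coefficients)
    return PlsrModel(
        n_latent=achieved,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=coefficients,
        intercept=intercept,
    )


def fit_plsr(calibration: SpectralDataset, n_latent: int) -> PlsrModel:
    """Fit NIPALS PLSR with ``n_latent`` components.

    Expects preprocessed data.  ``n_latent`` must lie in
    ``[1, min(n - 1, k)]``; if the residual matrix runs out of rank early
    the achieved component count is recorded on the model.
    """
    n, k = calibration.X.shape
    max_latent = min(n - 1, k)
    if not 1 <= n_latent <= max_latent:
        raise ValueError(f"n_latent must be in [1, {max_latent}], got {n_latent}")
    if float(np.var(calibration.X)) < 1e-24:
        raise ValueError("X has zero variance")
    return _nipals(calibration.X, calibration.Y, n_latent)


def _kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


@dataclass
class ModelSearchResult:
    """Outcome of a PRESS-based complexity search."""

    chosen_model: "PlsrModel | FnnModel"
    press_curve: np.ndarray
    candidates: list
    chosen_index: int


def _choose_by_press(fold_press: np.ndarray, y: np.ndarray) -> tuple[int, np.ndarray]:
    """Pick a candidate from a (folds x candidates) PRESS matrix.

    Candidates whose total PRESS lies within one standard error of the
    minimum (SE estimated from the fold-to-fold spread at the minimizer),
    or within a small relative slack, count as tied; the first — i.e.
    simplest — tied candidate wins.  Returns (index, total PRESS curve).
    """
    press = fold_press.sum(axis=0)
    best = int(np.argmin(press))
    n_folds = fold_press.shape[0]
    se = float(fold_press[:, best].std(ddof=1)) * np.sqrt(n_folds)
    floor = 1e-10 * float(np.sum((y - y.mean()) ** 2))
    threshold = press[best] + max(se, press[best] * _PRESS_REL_TOL) + floor
    return int(np.nonzero(press <= threshold)[0][0]), press


def select_n_latent(
    calibration: SpectralDataset,
    max_latent: int,
    folds: int = 10,
    seed: int = 0,
) -> ModelSearchResult:
    """Choose the PLSR component count by cross-validated PRESS.

    PRESS(c) sums squared held-out residuals over seeded k-folds for
    ``c = 1..max_latent``.  Component counts whose PRESS ties the minimum
    (one-standard-error / relative-slack rule) resolve toward the smallest
    ``c``, so flat tails of the curve do not inflate the model.
    """
    if max_latent < 1:
        raise ValueError("max_latent must be >= 1")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n = calibration.n_samples
    fold_indices = _kfold_indices(n, folds, seed)
    small = [idx.size for idx in fold_indices if idx.size < 2]
    if small:
        raise ValueError(f"{len(small)} fold(s) have fewer than 2 samples; reduce folds")

    fold_press = np.zeros((folds, max_latent))
    all_idx = np.arange(n)
    for fi, test_idx in enumerate(fold_indices):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train = calibration.subset_rows(train_idx)
        test = calibration.subset_rows(test_idx)
        cap = min(max_latent, train.n_samples - 1, train.n_bands)
        for c in range(1, max_latent + 1):
            model = fit_plsr(train, min(c, cap))
            resid = test.Y - model.predict(test.X)
            fold_press[fi, c - 1] = float(resid @ resid)

    chosen, press = _choose_by_press(fold_press, calibration.Y)
    model = fit_plsr(calibration, chosen + 1)
    return ModelSearchResult(
        chosen_model=model,
        press_curve=press,
        candidates=list(range(1, max_latent + 1)),
        chosen_index=chosen,
    )


# ---------------------------------------------------------------------------
# Feed-forward network
# ---------------------------------------------------------------------------


@dataclass
class FnnModel:
    """Dense feed-forward regressor with LeakyReLU hidden activations."""

    layer_sizes: tuple[int, ...]
    leaky_slope: float
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    training_seed: int

    def __post_init__(self) -> None:
        if self.layer_sizes[-1] != 1:
            raise ValueError("output layer must have size 1")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must lie in (0, 1)")

    @property
    def n_bands(self) -> int:
        return self.layer_sizes[0]

    @property
    def hidden_width(self) -> int:
        """Width of the first hidden layer (0 for a pure linear network)."""
        return self.layer_sizes[1] if len(self.layer_sizes) > 2 else 0

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def _leaky(self, z: np.ndarray) -> np.ndarray:
        return np.where(z >= 0, z, self.leaky_slope * z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_bands:
            raise ValueError(f"X has {X.shape[1]} bands, model expects {self.n_bands}")
        a = X
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            a = z if i == last else self._leaky(z)
        return a[:, 0]


def fit_fnn(
    calibration: SpectralDataset,
    layer_sizes: Sequence[int],
    leaky_slope: float = 0.01,
    epochs: int = 3000,
    learning_rate: float = 0.01,
    seed: int = 0,
) -> FnnModel:
    """Train a dense LeakyReLU network by full-batch gradient descent.

    He-style seeded initialization; adaptive per-parameter step scaling
    (Adam-style first/second moment estimates) keeps the fixed base rate
    usable across input widths from a handful of bands to the full 472
    grid.  Everything is plain numpy and deterministic given the seed.

    Raises
    ------
    FloatingPointError
        If the training loss goes non-finite (reports epoch and rate).
    """
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if any(s <= 0 for s in layer_sizes):
        raise ValueError("all layer sizes must be positive")
    if layer_sizes[0] != calibration.n_bands:
        raise ValueError(
            f"input layer size {layer_sizes[0]} != band count {calibration.n_bands}"
        )
    X = calibration.X
    y = calibration.Y[:, None]
    n = X.shape[0]

    rng = np.random.default_rng(seed)
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:])
    ]
    biases = [np.zeros(fan_out) for fan_out in layer_sizes[1:]]
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    last = len(weights) - 1

    for epoch in range(epochs):
        # forward; overflow surfaces as the explicit non-finite-loss error
        with np.errstate(over="ignore", invalid="ignore"):
            activations = [X]
            zs = []
            a = X
            for i, (w, b) in enumerate(zip(weights, biases)):
                z = a @ w + b
                zs.append(z)
                a = z if i == last else np.where(z >= 0, z, leaky_slope * z)
                activations.append(a)
            resid = activations[-1] - y
            loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} (learning_rate={learning_rate})"
            )
        # backward with moment-scaled updates
        t = epoch + 1
        bias1 = 1.0 - beta1**t
        bias2 = 1.0 - beta2**t
        delta = 2.0 * resid / n
        for i in range(last, -1, -1):
            grad_w = activations[i].T @ delta
            grad_b = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ weights[i].T) * np.where(zs[i - 1] >= 0, 1.0, leaky_slope)
            m_w[i] = beta1 * m_w[i] + (1 - beta1) * grad_w
            v_w[i] = beta2 * v_w[i] + (1 - beta2) * grad_w**2
            m_b[i] = beta1 * m_b[i] + (1 - beta1) * grad_b
            v_b[i] = beta2 * v_b[i] + (1 - beta2) * grad_b**2
            weights[i] = weights[i] - learning_rate * (m_w[i] / bias1) / (
                np.sqrt(v_w[i] / bias2) + eps
            )
            biases[i] = biases[i] - learning_rate * (m_b[i] / bias1) / (
                np.sqrt(v_b[i] / bias2) + eps
            )

    return FnnModel(
        layer_sizes=layer_sizes,
        leaky_slope=leaky_slope,
        weights=weights,
        biases=biases,
        training_seed=seed,
    )


def search_fnn(
    calibration: SpectralDataset,
    width_grid: Sequence[int] = DEFAULT_WIDTH_GRID,
    depth_grid: Sequence[int] = DEFAULT_DEPTH_GRID,
    folds: int = 5,
    seed: int = 0,
    epochs: int = 1500,
    learning_rate: float = 0.01,
    leaky_slope: float = 0.01,
) -> ModelSearchResult:
    """Grid-search network width and depth by cross-validated PRESS.

    Depth counts hidden layers; depth 0 is a pure linear network and its
    width entry is inert.  PRESS ties (one-standard-error / relative-slack
    rule) resolve toward the candidate with fewer parameters.
    """
    width_grid = list(width_grid)
    depth_grid = list(depth_grid)
    if not width_grid or not depth_grid:
        raise ValueError("width and depth grids must be nonempty")
    k = calibration.n_bands
    candidates = [
        (depth, width) for depth in depth_grid for width in width_grid
    ]
    fold_indices = _kfold_indices(calibration.n_samples, folds, seed)
    if any(idx.size < 2 for idx in fold_indices):
        raise ValueError("every fold needs at least 2 samples; reduce folds")
    all_idx = np.arange(calibration.n_samples)

    fold_press = np.zeros((folds, len(candidates)))
    for ci, (depth, width) in enumerate(candidates):
        sizes = (k, *([width] * depth), 1)
        for fi, test_idx in enumerate(fold_indices):
            train = calibration.subset_rows(np.setdiff1d(all_idx, test_idx))
            test = calibration.subset_rows(test_idx)
            model = fit_fnn(
                train, sizes, leaky_slope=leaky_slope, epochs=epochs,
                learning_rate=learning_rate, seed=seed,
            )
            resid = test.Y - model.predict(test.X)
            fold_press[fi, ci] = float(resid @ resid)

    press = fold_press.sum(axis=0)
    best = int(np.argmin(press))
    se = float(fold_press[:, best].std(ddof=1)) * np.sqrt(folds)
    floor = 1e-10 * float(np.sum((calibration.Y - calibration.Y.mean()) ** 2))
    threshold = press[best] + max(se, press[best] * _PRESS_REL_TOL) + floor
    tied = np.nonzero(press <= threshold)[0]

    def n_params(ci: int) -> int:
        depth, width = candidates[ci]
        sizes = (k, *([width] * depth), 1)
        return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))

    chosen = int(min(tied, key=lambda ci: (n_params(ci), ci)))
    depth, width = candidates[chosen]
    model = fit_fnn(
        calibration, (k, *([width] * depth), 1), leaky_slope=leaky_slope,
        epochs=epochs, learning_rate=learning_rate, seed=seed,
    )
    return ModelSearchResult(
        chosen_model=model,
        press_curve=press,
        candidates=candidates,
        chosen_index=chosen,
    )


def predict(model: "PlsrModel | FnnModel", X: np.ndarray) -> np.ndarray:
    """Predict in the model's native (normalized) space."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# Calibrated bundle: preprocessing chain + engine + metadata
# ---------------------------------------------------------------------------


@dataclass
class CalibratedModel:
    """A fitted engine together with the transform that feeds it.

    ``predict`` takes raw full-grid reflectance spectra and returns
    indicator units: band restriction, MSC, and z-scoring are replayed from
    the stored chain and the normalized prediction is back-transformed.
    """

    model_id: str
    indicator: str
    chain: PreprocessingChain
    model: "PlsrModel | FnnModel"
    wavelengths: np.ndarray  # full instrument grid the chain indexes into

    @property
    def n_wavelengths(self) -> int:
        return int(self.chain.band_indices.size)

    @property
    def n_latent_or_width(self) -> int:
        if isinstance(self.model, PlsrModel):
            return self.model.n_latent
        return self.model.hidden_width

    def predict(self, X_full: np.ndarray) -> np.ndarray:
        X_full = np.atleast_2d(np.asarray(X_full, dtype=float))
        if X_full.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"spectra have {X_full.shape[1]} bands; model grid has "
                f"{self.wavelengths.size}"
            )
        y_norm = self.model.predict(self.chain.transform_x(X_full))
        return self.chain.normalizer.invert_y(y_norm)


def save_model(cm: CalibratedModel, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(cm.model, PlsrModel):
        engine = {
            "type": "plsr",
            "n_latent": cm.model.n_latent,
            "x_weights": cm.model.x_weights.tolist(),
            "x_loadings": cm.model.x_loadings.tolist(),
            "y_loadings": cm.model.y_loadings.tolist(),
            "x_mean": cm.model.x_mean.tolist(),
            "y_mean": cm.model.y_mean,
            "coefficients": cm.model.coefficients.tolist(),
            "intercept": cm.model.intercept,
        }
    else:
        engine = {
            "type": "fnn",
            "layer_sizes": list(cm.model.layer_sizes),
            "leaky_slope": cm.model.leaky_slope,
            "weights": [w.tolist() for w in cm.model.weights],
            "biases": [b.tolist() for b in cm.model.biases],
            "training_seed": cm.model.training_seed,
        }
    payload = {
        "model_id": cm.model_id,
        "indicator": cm.indicator,
        "wavelengths": cm.wavelengths.tolist(),
        "chain": cm.chain.to_dict(),
        "engine": engine,
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path: str | Path) -> CalibratedModel:
    payload = json.loads(Path(path).read_text())
    engine = payload["engine"]
    model: PlsrModel | FnnModel
    if engine["type"] == "plsr":
        model = PlsrModel(
            n_latent=engine["n_latent"],
            x_weights=np.array(engine["x_weights"]),
            x_loadings=np.array(engine["x_loadings"]),
            y_loadings=np.array(engine["y_loadings"]),
            x_mean=np.array(engine["x_mean"]),
            y_mean=engine["y_mean"],
            coefficients=np.array(engine["coefficients"]),
            intercept=engine["intercept"],
        )
    else:
        model = FnnModel(
            layer_sizes=tuple(engine["layer_sizes"]),
            leaky_slope=engine["leaky_slope"],
            weights=[np.array(w) for w in engine["weights"]],
            biases=[np.array(b) for b in engine["biases"]],
            training_seed=engine["training_seed"],
        )
    return CalibratedModel(
        model_id=payload["model_id"],
        indicator=payload["indicator"],
        chain=PreprocessingChain.from_dict(payload["chain"]),
        model=model,
        wavelengths=np.array(payload["wavelengths"]),
    )
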