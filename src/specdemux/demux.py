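"""Learned inverses of the forward model: the numerical demultiplexers.

Reconstructing an n-point reflectance spectrum from p = 3 channel intensities
is a severely under-determined inverse problem; it becomes tractable only by
learning the statistics of the spectra one expects to see.  Two families are
implemented:

* **Wiener demultiplexer** — the linear minimum-mean-squared-error estimator.
  With training spectra stacked as columns of A (n x m) and their simulated
  measurements C = S A (p x m), the estimator matrix is

      W = (A C^T) (C C^T + eps I)^{-1}

  i.e. the cross-correlation of spectra with measurements times the inverse
  auto-correlation of measurements (non-centered correlations, the standard
  convention in Wiener spectral estimation).  A small ridge eps guards
  against singular auto-correlation.  Trained on a small fixed prior set this
  is the classical Wiener estimation baseline (WEM); trained on a large
  population generated through the characterized forward model it is the
  Wiener-based demultiplexer (DEMUX-WEM).

* **Random-forest demultiplexer (DEMUX-RFM)** — a non-linear multi-output
  random-forest regression from the 3 measurements to all n wavelengths,
  fit on forward-model-generated pairs.  The full-scale default is 8,000
  trees.  A per-output mode (one forest per wavelength, splitting the tree
  budget) is available.

All demultiplexed spectra are clipped to [0, 1]: reflectance is physically
bounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .errors import (
    ChannelMismatchError,
    GridMismatchError,
    ModelFormatError,
    SingularMatrixError,
    ValidationError,
)
from .forward import ReflectanceSpectrum, SensorMeasurement, SpectralCube
from .sensor import SpectralSensitivity, WavelengthGrid

#: Full-scale tree budget.
DEFAULT_N_TREES = 8000

_MODEL_MAGIC = "specdemux-model"
_MODEL_VERSION = 1


@dataclass(frozen=True)
class WienerDemultiplexer:
    """Linear MMSE inverse: spectrum estimate = clip(W @ measurement)."""

    W: np.ndarray = field(repr=False)  # (n, p)
    grid: WavelengthGrid
    channels: tuple[str, ...]
    training_meta: str = ""

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "channels", tuple(self.channels))
        if W.shape != (len(self.grid), len(self.channels)):
            raise ValidationError(
                f"W shape {W.shape} does not match "
                f"({len(self.grid)}, {len(self.channels)})"
            )
        if not np.all(np.isfinite(W)):
            raise ValidationError("W entries must be finite")
        object.__setattr__(self, "W", W)

    def predict_batch(self, measurements: np.ndarray) -> np.ndarray:
        """(m, p) measurements -> (m, n) clipped spectra."""
        measurements = _check_batch(measurements, len(self.channels))
        return np.clip(measurements @ self.W.T, 0.0, 1.0)


@dataclass(frozen=True)
class ForestDemultiplexer:
    """Non-linear random-forest inverse of the forward model."""

    model: object = field(repr=False)  # one regressor or list of per-output ones
    n_trees: int
    grid: WavelengthGrid
    channels: tuple[str, ...]
    seed: int
    per_output: bool = False
    training_meta: str = ""

    def predict_batch(self, measurements: np.ndarray) -> np.ndarray:
        """(m, p) measurements -> (m, n) clipped spectra."""
        measurements = _check_batch(measurements, len(self.channels))
        if self.per_output:
            cols = [est.predict(measurements) for est in self.model]
            pred = np.column_stack(cols)
        else:
            pred = self.model.predict(measurements)
            if pred.ndim == 1:
                pred = pred[:, None]
        return np.clip(pred, 0.0, 1.0)


Demultiplexer = WienerDemultiplexer | ForestDemultiplexer


def _check_batch(measurements: np.ndarray, p: int) -> np.ndarray:
    measurements = np.asarray(measurements, dtype=float)
    if measurements.ndim != 2 or measurements.shape[1] != p:
        raise ChannelMismatchError(
            f"measurement batch shape {measurements.shape} does not match "
            f"{p} channels"
        )
    return measurements


def _spectra_matrix(
    spectra: Sequence[ReflectanceSpectrum], grid: WavelengthGrid
) -> np.ndarray:
    if not spectra:
        raise ValidationError("training spectra list is empty")
    for s in spectra:
        if s.grid != grid:
            raise GridMismatchError("training spectrum grid differs from sensor grid")
    return np.array([s.values for s in spectra])  # (m, n)


def train_wiener(
    spectra: Sequence[ReflectanceSpectrum],
    sensitivity: SpectralSensitivity,
    ridge_eps: float | None = None,
    training_meta: str = "",
) -> WienerDemultiplexer:
    """Fit the Wiener estimator W = (A C^T)(C C^T + eps I)^{-1}.

    ``ridge_eps=None`` (default) uses 1e-8 of the auto-correlation trace;
    an explicit 0 disables regularization and raises ``SingularMatrixError``
    on rank-deficient auto-correlation.
    """
    if ridge_eps is not None and ridge_eps < 0:
        raise ValidationError(f"ridge_eps must be >= 0, got {ridge_eps}")
    A = _spectra_matrix(spectra, sensitivity.grid).T  # (n, m)
    C = sensitivity.matrix @ A  # (p, m)
    Rcc = C @ C.T
    Rxc = A @ C.T
    p = sensitivity.p
    if ridge_eps is None:
        ridge_eps = 1e-8 * float(np.trace(Rcc))
    if ridge_eps == 0:
        cond = np.linalg.cond(Rcc)
        if not np.isfinite(cond) or cond > 1e12:
            raise SingularMatrixError(
                "measurement auto-correlation C C^T is singular; "
                "pass a positive ridge_eps"
            )
        W = np.linalg.solve(Rcc.T, Rxc.T).T
    else:
        W = np.linalg.solve((Rcc + ridge_eps * np.eye(p)).T, Rxc.T).T
    meta = training_meta or f"wiener: m={A.shape[1]}, ridge_eps={ridge_eps:g}"
    return WienerDemultiplexer(W, sensitivity.grid, sensitivity.channels, meta)


def train_forest(
    pairs: Sequence[tuple[SensorMeasurement, ReflectanceSpectrum]],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
    per_output: bool = False,
    training_meta: str = "",
) -> ForestDemultiplexer:
    """Fit a random-forest regression from measurements to spectra.

    Hyperparameter defaults: unlimited depth, minimum leaf size 1, bootstrap
    resampling, all p features considered at every split (p is tiny).
    ``per_output=True`` trains one forest per wavelength, dividing the
    ``n_trees`` budget evenly across outputs.
    """
    if not pairs:
        raise ValidationError("training pairs list is empty")
    if n_trees < 1:
        raise ValidationError(f"n_trees must be >= 1, got {n_trees}")
    grid = pairs[0][1].grid
    channels = pairs[0][0].channels
    X = np.array([c.values for c, _ in pairs])
    Y = np.array([s.values for _, s in pairs])
    if X.ndim != 2 or Y.shape != (X.shape[0], len(grid)):
        raise ValidationError("inconsistent training pairs")

    def _make(n_estimators: int, rs: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=n_estimators,
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            max_features=None,
            bootstrap=True,
            random_state=rs,
            n_jobs=1,
        )

    if per_output:
        n_out = Y.shape[1]
        per = max(1, n_trees // n_out)
        models = []
        for k in range(n_out):
            est = _make(per, seed + k)
            est.fit(X, Y[:, k])
            models.append(est)
        total = per * n_out
        model: object = models
    else:
        est = _make(n_trees, seed)
        est.fit(X, Y)
        model = est
        total = n_trees
    meta = training_meta or (
        f"forest: m={X.shape[0]}, trees={total}, per_output={per_output}"
    )
    return ForestDemultiplexer(
        model, total, grid, channels, seed, per_output, meta
    )


def _check_measurement(
    model: Demultiplexer, measurement: SensorMeasurement
) -> np.ndarray:
    if len(measurement.channels) != len(model.channels):
        raise ChannelMismatchError(
            f"measurement has {len(measurement.channels)} channels, "
            f"model expects {len(model.channels)}"
        )
    return measurement.values[None, :]


def demultiplex_wiener(
    model: WienerDemultiplexer, measurement: SensorMeasurement
) -> ReflectanceSpectrum:
    """Linear reconstruction clip(W @ C) of one measurement."""
    row = _check_measurement(model, measurement)
    return ReflectanceSpectrum(model.grid, model.predict_batch(row)[0])


def demultiplex_forest(
    model: ForestDemultiplexer, measurement: SensorMeasurement
) -> ReflectanceSpectrum:
    """Ensemble-mean reconstruction of one measurement."""
    row = _check_measurement(model, measurement)
    return ReflectanceSpectrum(model.grid, model.predict_batch(row)[0])


def demultiplex(
    model: Demultiplexer, measurement: SensorMeasurement
) -> ReflectanceSpectrum:
    """Reconstruct one spectrum with either demultiplexer family."""
    if isinstance(model, WienerDemultiplexer):
        return demultiplex_wiener(model, measurement)
    if isinstance(model, ForestDemultiplexer):
        return demultiplex_forest(model, measurement)
    raise TypeError(f"not a demultiplexer: {type(model).__name__}")


def demultiplex_image(model: Demultiplexer, rgb_image: np.ndarray) -> SpectralCube:
    """Demultiplex every pixel of an (h, w, p) image into a spectral cube.

    Batched internally; numerically identical to per-pixel calls.
    """
    rgb_image = np.asarray(rgb_image, dtype=float)
    p = len(model.channels)
    if rgb_image.ndim != 3 or rgb_image.shape[2] != p:
        raise ChannelMismatchError(
            f"image shape {rgb_image.shape} does not match {p} channels"
        )
    h, w, _ = rgb_image.shape
    flat = model.predict_batch(rgb_image.reshape(h * w, p))
    return SpectralCube(model.grid, flat.reshape(h, w, len(model.grid)))


def extract_band(cube: SpectralCube, wavelength_nm: float) -> np.ndarray:
    """The (h, w) slice of the cube at an exact grid wavelength."""
    k = cube.grid.index_of(wavelength_nm)
    return cube.data[:, :, k]


def save_model(model: Demultiplexer, path: str | Path) -> None:
    """Serialize a demultiplexer to a single versioned container file."""
    if isinstance(model, WienerDemultiplexer):
        payload = {
            "magic": _MODEL_MAGIC,
            "version": _MODEL_VERSION,
            "kind": "wiener",
            "W": model.W,
            "grid": (model.grid.start_nm, model.grid.end_nm, model.grid.step_nm),
            "channels": model.channels,
            "training_meta": model.training_meta,
        }
    elif isinstance(model, ForestDemultiplexer):
        payload = {
            "magic": _MODEL_MAGIC,
            "version": _MODEL_VERSION,
            "kind": "forest",
            "model": model.model,
            "n_trees": model.n_trees,
            "grid": (model.grid.start_nm, model.grid.end_nm, model.grid.step_nm),
            "channels": model.channels,
            "seed": model.seed,
            "per_output": model.per_output,
            "training_meta": model.training_meta,
        }
    else:
        raise TypeError(f"not a demultiplexer: {type(model).__name__}")
    joblib.dump(payload, path)


def load_model(path: str | Path) -> Demultiplexer:
    """Load a demultiplexer saved by :func:`save_model`."""
    from .sensor import make_wavelength_grid

    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt / truncated / not a joblib file
        raise ModelFormatError(f"{path}: cannot read model file ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("magic") != _MODEL_MAGIC:
        raise ModelFormatError(f"{path}: not a specdemux model file")
    if payload.get("version") != _MODEL_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format version {payload.get('version')!r}"
        )
    grid = make_wavelength_grid(*payload["grid"])
    if payload["kind"] == "wiener":
        return WienerDemultiplexer(
            payload["W"], grid, tuple(payload["channels"]),
            payload.get("training_meta", ""),
        )
    if payload["kind"] == "forest":
        return ForestDemultiplexer(
            payload["model"], payload["n_trees"], grid,
            tuple(payload["channels"]), payload["seed"],
            payload.get("per_output", False), payload.get("training_meta", ""),
        )
    raise ModelFormatError(f"{path}: unknown model kind {payload['kind']!r}")


def write_wiener_csv(model: WienerDemultiplexer, path: str | Path) -> None:
    """Export the W matrix as CSV (wavelength row labels, channel columns)."""
    header = "wavelength_nm," + ",".join(model.channels)
    table = np.column_stack([model.grid.values, model.W])
    np.savetxt(path, table, delimiter=",", header=header, comments="", fmt="%.15g")
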