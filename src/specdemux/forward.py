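"""Linear measurement formation: C = S * Lambda.

A pixel's p-channel measurement is the spectral sensitivity matrix applied to
the radiance spectrum arriving at that pixel, Lambda = R * E, where R is the
object's reflectance (a fraction in [0, 1] per wavelength) and E the
illuminant's relative spectral power.  The simulation experiments use E == 1
so the target quantity is the reflectance itself, matching the convention of
working with spectra detrended by a white reference.

Measurements are continuous by default (no quantization); optional k-bit
quantization is available via :func:`quantize`.  Sensor responses are treated
as linear (gamma-free) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, ValidationError
from .sensor import SpectralSensitivity, WavelengthGrid


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Per-wavelength reflected fraction on a grid; values in [0, 1]."""

    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValidationError(
                f"spectrum length {v.shape} does not match grid ({len(self.grid)},)"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("reflectance values must be finite")
        if np.any(v < 0) or np.any(v > 1):
            raise ValidationError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class RadianceSpectrum:
    """Reflectance folded with an illuminant: nonnegative, may exceed 1."""

    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValidationError(
                f"spectrum length {v.shape} does not match grid ({len(self.grid)},)"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValidationError("radiance values must be finite and >= 0")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class IlluminantSpectrum:
    """Relative spectral power of the light source; nonnegative."""

    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValidationError(
                f"illuminant length {v.shape} does not match grid ({len(self.grid)},)"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValidationError("illuminant values must be finite and >= 0")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SensorMeasurement:
    """One pixel's p channel intensities, in (relative) sensor units."""

    channels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "channels", tuple(self.channels))
        if v.shape != (len(self.channels),):
            raise ValidationError(
                f"measurement length {v.shape} does not match "
                f"{len(self.channels)} channels"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("measurement values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SpectralCube:
    """Height x width x n array of per-pixel spectra on one grid."""

    grid: WavelengthGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != len(self.grid):
            raise ValidationError(
                f"cube shape {d.shape} must be (height, width, {len(self.grid)})"
            )
        if not np.all(np.isfinite(d)):
            raise ValidationError("cube values must be finite")
        object.__setattr__(self, "data", d)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


def scene_radiance(
    reflectance: ReflectanceSpectrum, illuminant: IlluminantSpectrum
) -> RadianceSpectrum:
    """Element-wise product Lambda = R * E on a shared grid."""
    if reflectance.grid != illuminant.grid:
        raise GridMismatchError("reflectance and illuminant grids differ")
    return RadianceSpectrum(reflectance.grid, reflectance.values * illuminant.values)


def detrend_by_illuminant(
    measured: RadianceSpectrum | ReflectanceSpectrum,
    white_target: RadianceSpectrum | ReflectanceSpectrum,
    white_reflectance: float = 0.99,
) -> ReflectanceSpectrum:
    """Recover reflectance by dividing out the illuminant.

    ``white_target`` is the spectrum measured off a near-perfect diffuse
    white reference of known nominal reflectance (default 0.99), so
    ``measured / white_target * white_reflectance`` cancels the illuminant.
    The result is clipped to [0, 1].
    """
    if measured.grid != white_target.grid:
        raise GridMismatchError("measured and white-target grids differ")
    w = np.asarray(white_target.values, dtype=float)
    zeros = np.nonzero(w == 0)[0]
    if zeros.size:
        wl = measured.grid.values[zeros[0]]
        raise ZeroDivisionError(
            f"white target spectrum is zero at {wl:g} nm; cannot detrend"
        )
    out = np.clip(measured.values / w * white_reflectance, 0.0, 1.0)
    return ReflectanceSpectrum(measured.grid, out)


def forward(
    sensitivity: SpectralSensitivity,
    spectrum: ReflectanceSpectrum | RadianceSpectrum,
) -> SensorMeasurement:
    """Form the p-channel measurement C = S * Lambda for one spectrum."""
    if sensitivity.grid != spectrum.grid:
        raise GridMismatchError("sensitivity and spectrum grids differ")
    return SensorMeasurement(
        sensitivity.channels, sensitivity.matrix @ spectrum.values
    )


def forward_matrix(sensitivity: SpectralSensitivity, spectra: np.ndarray) -> np.ndarray:
    """Vectorized forward model: (m, n) spectra -> (m, p) measurements."""
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[1] != len(sensitivity.grid):
        raise GridMismatchError(
            f"spectra shape {spectra.shape} does not match grid length "
            f"{len(sensitivity.grid)}"
        )
    return spectra @ sensitivity.matrix.T


def forward_image(sensitivity: SpectralSensitivity, cube: SpectralCube) -> np.ndarray:
    """Render a spectral cube to an (height, width, p) channel image.

    Every pixel carries all p channels (a post-demosaic view); the Bayer
    mosaic's spatial subsampling is not modeled.
    """
    if sensitivity.grid != cube.grid:
        raise GridMismatchError("sensitivity and cube grids differ")
    h, w, n = cube.data.shape
    flat = cube.data.reshape(h * w, n) @ sensitivity.matrix.T
    return flat.reshape(h, w, sensitivity.p)


def add_measurement_noise(
    measurement: SensorMeasurement, sigma: float, seed: int
) -> SensorMeasurement:
    """Add zero-mean Gaussian read noise of std ``sigma`` per channel.

    Deterministic for a fixed seed; sigma = 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return measurement
    rng = np.random.default_rng(seed)
    noisy = measurement.values + rng.normal(0.0, sigma, size=measurement.values.shape)
    return SensorMeasurement(measurement.channels, noisy)


def quantize(values: np.ndarray, bits: int) -> np.ndarray:
    """Quantize values in [0, 1] to k-bit levels and map back to [0, 1]."""
    if not 1 <= bits <= 16:
        raise ValidationError(f"bits must be in [1, 16], got {bits}")
    levels = 2**bits - 1
    return np.round(np.clip(values, 0.0, 1.0) * levels) / levels
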