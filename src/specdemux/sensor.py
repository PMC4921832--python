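"""Wavelength grids and sensor spectral sensitivity.

A color image sensor behind a Bayer color filter array returns, at every
pixel, p channel intensities (p = 3 for R/G/B).  Its spectral sensitivity is
the p x n matrix S whose row c gives the relative response of channel c to
unit-intensity narrowband light at each of the n grid wavelengths.  One
sensitivity vector per channel is assumed to hold across the whole sensor
(pixels under the same filter respond alike).

This module provides the shared wavelength grid, a parametric Gaussian
filter-bank generator standing in for measured RGB response curves, the
narrowband characterization procedure (probe the sensor one wavelength at a
time and average the readings), and CSV persistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import CharacterizationError, InvalidGridError, ValidationError

DEFAULT_START_NM = 410.0
DEFAULT_END_NM = 710.0
DEFAULT_STEP_NM = 5.0

#: Default Gaussian filter-bank: (peak nm, width nm, peak amplitude) per
#: channel, chosen so green > red ~ blue in peak response, qualitatively
#: matching consumer RGB sensors.
DEFAULT_CHANNEL_SPECS: Mapping[str, tuple[float, float, float]] = {
    "R": (600.0, 35.0, 0.9),
    "G": (530.0, 35.0, 1.0),
    "B": (460.0, 35.0, 0.8),
}


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniformly spaced discrete wavelength axis, in nanometres."""

    start_nm: float
    end_nm: float
    step_nm: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise InvalidGridError("grid values must be a non-empty 1-D array")
        if v.size > 1:
            d = np.diff(v)
            if not np.all(d > 0):
                raise InvalidGridError("grid wavelengths must be strictly increasing")
            if not np.allclose(d, self.step_nm, rtol=0, atol=1e-9):
                raise InvalidGridError(
                    f"grid spacing is not uniform at step {self.step_nm} nm"
                )
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=0, atol=1e-9
        )

    def __hash__(self) -> int:
        return hash((self.start_nm, self.end_nm, self.step_nm, len(self.values)))

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an exact grid wavelength; raises ``OffGridError`` otherwise."""
        from .errors import OffGridError

        hits = np.nonzero(np.isclose(self.values, wavelength_nm, rtol=0, atol=1e-9))[0]
        if hits.size == 0:
            below = self.values[self.values < wavelength_nm]
            above = self.values[self.values > wavelength_nm]
            lo = f"{below[-1]:g}" if below.size else "none"
            hi = f"{above[0]:g}" if above.size else "none"
            raise OffGridError(
                f"{wavelength_nm:g} nm is not on the grid; nearest grid "
                f"wavelengths are {lo} and {hi} nm"
            )
        return int(hits[0])


def make_wavelength_grid(
    start_nm: float = DEFAULT_START_NM,
    end_nm: float = DEFAULT_END_NM,
    step_nm: float = DEFAULT_STEP_NM,
) -> WavelengthGrid:
    """Build a uniform grid covering [start_nm, end_nm] in steps of step_nm.

    The default grid has 61 points from 410 to 710 nm, the range over which
    the demultiplexers reconstruct reflectance.
    """
    if step_nm <= 0:
        raise ValidationError(f"step_nm must be > 0, got {step_nm}")
    if end_nm < start_nm:
        raise InvalidGridError(f"end_nm {end_nm} < start_nm {start_nm}")
    span = end_nm - start_nm
    k = span / step_nm
    if abs(k - round(k)) > 1e-9:
        raise InvalidGridError(
            f"range {start_nm}-{end_nm} nm is not an integer multiple of {step_nm} nm"
        )
    count = int(round(k)) + 1
    values = start_nm + step_nm * np.arange(count, dtype=float)
    return WavelengthGrid(start_nm, end_nm, step_nm, values)


@dataclass(frozen=True)
class SpectralSensitivity:
    """Per-channel relative spectral response: the p x n matrix S.

    Entries are dimensionless (relative response per unit spectral
    intensity); absolute radiometric calibration is out of scope.
    """

    grid: WavelengthGrid
    channels: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "channels", tuple(self.channels))
        if m.ndim != 2:
            raise ValidationError("sensitivity matrix must be 2-D (p x n)")
        if m.shape != (len(self.channels), len(self.grid)):
            raise ValidationError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.channels)} channels x {len(self.grid)} wavelengths"
            )
        if not np.all(np.isfinite(m)):
            raise ValidationError("sensitivity entries must be finite")
        if np.any(m < 0):
            raise ValidationError("sensitivity entries must be >= 0")
        if np.any(np.all(m == 0, axis=1)):
            dead = [c for c, row in zip(self.channels, m) if not row.any()]
            raise ValidationError(f"channel(s) with all-zero sensitivity: {dead}")
        object.__setattr__(self, "matrix", m)

    @property
    def p(self) -> int:
        return len(self.channels)


def synth_sensitivity(
    grid: WavelengthGrid,
    channel_specs: Mapping[str, tuple[float, float, float]] | None = None,
) -> SpectralSensitivity:
    """Synthesize a Gaussian filter-bank sensitivity.

    ``channel_specs`` maps channel label -> (peak_nm, width_nm, amplitude);
    row c is ``amplitude * exp(-(lambda - peak)^2 / (2 width^2))`` on the
    grid.  Defaults give a three-channel R/G/B bank peaking at 600/530/460 nm.
    """
    if channel_specs is None:
        channel_specs = DEFAULT_CHANNEL_SPECS
    if not channel_specs:
        raise ValidationError("channel_specs must name at least one channel")
    rows = []
    for label, (peak, width, amplitude) in channel_specs.items():
        if width <= 0:
            raise ValidationError(f"channel {label!r}: width must be > 0, got {width}")
        if amplitude <= 0:
            raise ValidationError(
                f"channel {label!r}: amplitude must be > 0, got {amplitude}"
            )
        rows.append(amplitude * np.exp(-((grid.values - peak) ** 2) / (2.0 * width**2)))
    return SpectralSensitivity(grid, tuple(channel_specs), np.vstack(rows))


def characterize_from_narrowband(
    responses: Mapping[float, Sequence[np.ndarray] | np.ndarray],
    grid: WavelengthGrid,
    channels: Sequence[str] = ("R", "G", "B"),
) -> SpectralSensitivity:
    """Recover S from narrowband probe readings.

    ``responses`` maps each grid wavelength to one or more p-vector sensor
    readings taken under unit-intensity narrowband light at that wavelength.
    Column k of the recovered matrix is the per-channel mean of the readings
    at grid wavelength k (under the forward model, the response to the unit
    impulse spectrum e_k is exactly column k of S).  Negative means, which
    can arise from noisy readings, are clipped to zero: sensitivities are
    physically nonnegative.
    """
    p = len(channels)
    keys = np.array(sorted(responses), dtype=float)
    missing = [
        f"{w:g}"
        for w in grid.values
        if not np.any(np.isclose(keys, w, rtol=0, atol=1e-9))
    ]
    if missing:
        raise CharacterizationError(
            f"no readings for {len(missing)} grid wavelength(s): "
            + ", ".join(missing[:10])
            + (" ..." if len(missing) > 10 else "")
        )
    cols = np.empty((p, len(grid)))
    for k, w in enumerate(grid.values):
        key = keys[np.isclose(keys, w, rtol=0, atol=1e-9)][0]
        reads = np.atleast_2d(np.asarray(responses[key], dtype=float))
        if reads.shape[1] != p:
            raise CharacterizationError(
                f"readings at {w:g} nm have {reads.shape[1]} channels, expected {p}"
            )
        cols[:, k] = reads.mean(axis=0)
    np.clip(cols, 0.0, None, out=cols)
    return SpectralSensitivity(grid, tuple(channels), cols)


def write_sensitivity_csv(sens: SpectralSensitivity, path: str | Path) -> None:
    """Write S as ``wavelength_nm,<ch>,...`` with one row per wavelength."""
    path = Path(path)
    header = "wavelength_nm," + ",".join(sens.channels)
    table = np.column_stack([sens.grid.values, sens.matrix.T])
    np.savetxt(path, table, delimiter=",", header=header, comments="", fmt="%.15g")


def read_sensitivity_csv(path: str | Path) -> SpectralSensitivity:
    """Read a sensitivity CSV written by :func:`write_sensitivity_csv`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if not header or header[0] != "wavelength_nm":
        raise ValidationError(f"{path}: first column must be 'wavelength_nm'")
    channels = tuple(header[1:])
    if not channels:
        raise ValidationError(f"{path}: no channel columns found")
    table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    wl = table[:, 0]
    if wl.size > 1:
        steps = np.diff(wl)
        if not (np.all(steps > 0) and np.allclose(steps, steps[0], rtol=0, atol=1e-9)):
            raise InvalidGridError(f"{path}: wavelengths are not uniformly spaced")
        step = float(steps[0])
    else:
        step = DEFAULT_STEP_NM
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), step, wl)
    return SpectralSensitivity(grid, channels, table[:, 1:].T)
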