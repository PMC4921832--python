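"""Synthetic reflectance spectra and test fixtures.

Real reflectance spectra of natural and man-made surfaces are smooth, broad
curves.  The generator emulates that with a clipped Gaussian-bump mixture:
each spectrum is a flat baseline plus 1-3 Gaussian bumps with random centers,
widths and amplitudes, clipped to [0, 1].  With the defaults, a population of
a few thousand spectra covers every wavelength well, which is what the
demultiplexer training set needs.

Also provided: a block test icon (a few uniform patches of distinct spectra,
used for the spatial end-to-end experiment) and a fixed 24-spectrum prior
set — a synthetic stand-in for the Macbeth ColorChecker patch reflectances
used to train the classical Wiener estimation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GridMismatchError, ValidationError
from .forward import ReflectanceSpectrum, SensorMeasurement, forward_matrix
from .sensor import SpectralSensitivity, WavelengthGrid, make_wavelength_grid


@dataclass(frozen=True)
class SpectraGenConfig:
    """Parameters of the Gaussian-bump spectra generator.

    Defaults: 1-3 bumps per spectrum, widths 20-80 nm, amplitudes 0.2-1.0,
    baselines 0-0.2 — smooth unimodal-to-trimodal curves spanning most of the
    reflectance range.
    """

    n_spectra: int
    seed: int
    grid: WavelengthGrid = field(default_factory=make_wavelength_grid)
    modes_min: int = 1
    modes_max: int = 3
    width_range_nm: tuple[float, float] = (20.0, 80.0)
    amplitude_range: tuple[float, float] = (0.2, 1.0)
    baseline_range: tuple[float, float] = (0.0, 0.2)

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise ValidationError(f"n_spectra must be >= 1, got {self.n_spectra}")
        if not 1 <= self.modes_min <= self.modes_max:
            raise ValidationError(
                f"need 1 <= modes_min <= modes_max, got {self.modes_min}, {self.modes_max}"
            )
        for name, (lo, hi) in (
            ("width_range_nm", self.width_range_nm),
            ("amplitude_range", self.amplitude_range),
            ("baseline_range", self.baseline_range),
        ):
            if lo > hi:
                raise ValidationError(f"{name} must be ordered low <= high")
        if not (0 <= self.amplitude_range[0] and self.amplitude_range[1] <= 1):
            raise ValidationError("amplitude_range bounds must lie in [0, 1]")
        if not (0 <= self.baseline_range[0] and self.baseline_range[1] <= 1):
            raise ValidationError("baseline_range bounds must lie in [0, 1]")
        if self.width_range_nm[0] <= 0:
            raise ValidationError("widths must be positive")


def _bump_mixture(
    rng: np.random.Generator, config: SpectraGenConfig
) -> np.ndarray:
    """One baseline-plus-bumps spectrum, clipped to [0, 1]."""
    lam = config.grid.values
    baseline = rng.uniform(*config.baseline_range)
    m = rng.integers(config.modes_min, config.modes_max + 1)
    values = np.full(lam.shape, baseline)
    for _ in range(m):
        center = rng.uniform(lam[0], lam[-1])
        width = rng.uniform(*config.width_range_nm)
        amplitude = rng.uniform(*config.amplitude_range)
        values += amplitude * np.exp(-((lam - center) ** 2) / (2.0 * width**2))
    return np.clip(values, 0.0, 1.0)


def generate_random_spectra(config: SpectraGenConfig) -> list[ReflectanceSpectrum]:
    """Draw ``config.n_spectra`` random spectra; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    return [
        ReflectanceSpectrum(config.grid, _bump_mixture(rng, config))
        for _ in range(config.n_spectra)
    ]


def generate_training_pairs(
    sensitivity: SpectralSensitivity, config: SpectraGenConfig
) -> list[tuple[SensorMeasurement, ReflectanceSpectrum]]:
    """Generate (measurement, spectrum) supervision pairs via the forward model."""
    if sensitivity.grid != config.grid:
        raise GridMismatchError("sensitivity grid differs from generator grid")
    spectra = generate_random_spectra(config)
    A = np.array([s.values for s in spectra])
    C = forward_matrix(sensitivity, A)
    return [
        (SensorMeasurement(sensitivity.channels, c), s)
        for c, s in zip(C, spectra)
    ]


@dataclass(frozen=True)
class TestIcon:
    """A block image of uniform patches, each with its own true spectrum."""

    sections: tuple[tuple[str, ReflectanceSpectrum], ...]
    layout: np.ndarray = field(repr=False)  # (h, w) int label map

    def __post_init__(self) -> None:
        layout = np.asarray(self.layout, dtype=int)
        labels = np.unique(layout)
        if labels.min() < 0 or labels.max() >= len(self.sections):
            raise ValidationError("layout labels must index into sections")
        grids = {id(s.grid) for _, s in self.sections}
        if len({tuple(s.grid.values) for _, s in self.sections}) != 1:
            raise ValidationError("all section spectra must share one grid")
        del grids
        object.__setattr__(self, "layout", layout)

    @property
    def grid(self) -> WavelengthGrid:
        return self.sections[0][1].grid

    def to_cube(self):
        """Expand the label map to a full spectral cube."""
        from .forward import SpectralCube

        spectra = np.array([s.values for _, s in self.sections])
        return SpectralCube(self.grid, spectra[self.layout])


def make_test_icon(
    grid: WavelengthGrid,
    n_sections: int = 5,
    seed: int = 0,
    section_px: int = 8,
) -> TestIcon:
    """Build an icon of ``n_sections`` vertical strips, ``section_px`` wide.

    Section spectra come from the same generator as the random populations,
    restricted to 1-2 bumps so they look like typical colored patches.
    """
    if n_sections < 1:
        raise ValidationError(f"n_sections must be >= 1, got {n_sections}")
    if section_px < 1:
        raise ValidationError(f"section_px must be >= 1, got {section_px}")
    config = SpectraGenConfig(
        n_spectra=n_sections, seed=seed, grid=grid, modes_min=1, modes_max=2
    )
    spectra = generate_random_spectra(config)
    sections = tuple(
        (f"section_{i}", s) for i, s in enumerate(spectra)
    )
    layout = np.repeat(
        np.arange(n_sections)[None, :], section_px, axis=0
    )
    layout = np.repeat(layout, section_px, axis=1)
    return TestIcon(sections, layout)


# Fixed parameter table for the 24-spectrum prior set: (center nm, width nm,
# amplitude, baseline) for 18 chromatic patches, then 6 neutral flats.  A
# synthetic stand-in for the Macbeth ColorChecker patch reflectances.
_PRIOR_CHROMATIC = [
    (440, 40, 0.55, 0.05), (460, 55, 0.65, 0.08), (480, 45, 0.50, 0.10),
    (500, 60, 0.60, 0.05), (520, 40, 0.55, 0.12), (540, 50, 0.70, 0.06),
    (560, 65, 0.60, 0.10), (580, 45, 0.75, 0.08), (600, 55, 0.65, 0.05),
    (620, 40, 0.80, 0.10), (640, 60, 0.70, 0.06), (660, 50, 0.60, 0.12),
    (680, 45, 0.55, 0.08), (470, 80, 0.45, 0.15), (550, 90, 0.50, 0.10),
    (630, 85, 0.55, 0.12), (430, 70, 0.40, 0.20), (590, 75, 0.45, 0.18),
]
_PRIOR_NEUTRALS = [0.95, 0.75, 0.55, 0.35, 0.18, 0.05]


def prior_spectra(grid: WavelengthGrid) -> list[ReflectanceSpectrum]:
    """The fixed 24-spectrum prior set used to train the WEM baseline.

    Synthetic: 18 single-bump chromatic patches plus 6 neutral flats,
    emulating the broad shape statistics of a ColorChecker chart without
    reproducing any measured data.
    """
    lam = grid.values
    out = []
    for center, width, amp, base in _PRIOR_CHROMATIC:
        v = base + amp * np.exp(-((lam - center) ** 2) / (2.0 * width**2))
        out.append(ReflectanceSpectrum(grid, np.clip(v, 0.0, 1.0)))
    for level in _PRIOR_NEUTRALS:
        out.append(ReflectanceSpectrum(grid, np.full(lam.shape, level)))
    return out


def write_spectra_csv(
    spectra: Sequence[ReflectanceSpectrum], path: str | Path
) -> None:
    """Write spectra as rows; the header row lists the grid wavelengths."""
    if not spectra:
        raise ValidationError("cannot write an empty spectra list")
    grid = spectra[0].grid
    header = ",".join(f"{w:g}" for w in grid.values)
    rows = np.array([s.values for s in spectra])
    np.savetxt(path, rows, delimiter=",", header=header, comments="", fmt="%.15g")


def read_spectra_csv(
    path: str | Path, grid: WavelengthGrid
) -> list[ReflectanceSpectrum]:
    """Read spectra written by :func:`write_spectra_csv`, validating the grid."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header:
        return []
    wl = np.array([float(x) for x in header.split(",")])
    if wl.size != len(grid) or not np.allclose(wl, grid.values, rtol=0, atol=1e-9):
        raise GridMismatchError(
            f"{path}: header wavelengths do not match the expected grid"
        )
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if rows.size == 0:
        return []
    return [ReflectanceSpectrum(grid, row) for row in rows]
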