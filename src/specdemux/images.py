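"""Image and spectral-cube file I/O.

RGB images are stored as 8- or 16-bit unsigned PNG/TIFF; pixel values map
linearly to [0, 1] on read (divide by 2^bits - 1) and back on write.  Images
are treated as linear throughout — no gamma or color management.

Spectral cubes are stored as a multi-band 32-bit-float TIFF (band order =
grid order) with a sidecar CSV listing the band wavelengths.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import InvalidGridError, ValidationError
from .forward import SpectralCube
from .sensor import WavelengthGrid


def write_image(path: str | Path, image: np.ndarray, bits: int = 16) -> None:
    """Write a float image in [0, 1] as an unsigned 8- or 16-bit PNG/TIFF."""
    if bits not in (8, 16):
        raise ValidationError(f"bits must be 8 or 16, got {bits}")
    image = np.asarray(image, dtype=float)
    scale = 2**bits - 1
    data = np.round(np.clip(image, 0.0, 1.0) * scale)
    data = data.astype(np.uint8 if bits == 8 else np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        # PNG: 8-bit any layout, 16-bit grayscale only (PNG codec limit);
        # use TIFF for 16-bit multi-channel images
        if bits == 16 and data.ndim == 3:
            raise ValidationError(
                "16-bit multi-channel PNG is not supported; write a TIFF instead"
            )
        iio.imwrite(path, data)


def read_image(path: str | Path) -> np.ndarray:
    """Read an unsigned-integer image and map it linearly to float [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if data.dtype == np.uint8:
        scale = 255.0
    elif data.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValidationError(f"{path}: unsupported pixel dtype {data.dtype}")
    return data.astype(float) / scale


def write_cube(path: str | Path, cube: SpectralCube) -> None:
    """Write a cube as multi-band float32 TIFF plus a wavelength sidecar CSV."""
    path = Path(path)
    bands = np.moveaxis(cube.data.astype(np.float32), 2, 0)  # (n, h, w)
    tifffile.imwrite(path, bands)
    sidecar = path.with_suffix(path.suffix + ".wavelengths.csv")
    np.savetxt(
        sidecar, cube.grid.values, delimiter=",", header="wavelength_nm",
        comments="", fmt="%.15g",
    )


def read_cube(path: str | Path) -> SpectralCube:
    """Read a cube written by :func:`write_cube`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".wavelengths.csv")
    if not sidecar.exists():
        raise ValidationError(f"missing wavelength sidecar {sidecar}")
    wl = np.atleast_1d(np.loadtxt(sidecar, delimiter=",", skiprows=1))
    if wl.size > 1:
        steps = np.diff(wl)
        if not (np.all(steps > 0) and np.allclose(steps, steps[0], rtol=0, atol=1e-9)):
            raise InvalidGridError(f"{sidecar}: wavelengths are not uniformly spaced")
        step = float(steps[0])
    else:
        step = 1.0
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), step, wl)
    bands = tifffile.imread(path)
    if bands.ndim != 3 or bands.shape[0] != wl.size:
        raise ValidationError(
            f"{path}: band count {bands.shape} does not match {wl.size} wavelengths"
        )
    return SpectralCube(grid, np.moveaxis(bands.astype(float), 0, 2))
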