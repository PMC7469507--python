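"""Core raster and calibration types shared by every measurement mode.

Histology regions of interest arrive as TIFF/PNG/JPEG rasters.  All
downstream processing works on a single-channel, float64 intensity grid
normalised to [0, 1]; pixel coordinates are 0-based ``(row, col)`` with the
row index increasing downward.  Physical scaling is carried separately as a
microns-per-pixel calibration so that areas measured in px² can be reported
in μm².
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ImageGrid",
    "ScaleCalibration",
    "SeedPoint",
    "load_image",
    "image_from_array",
    "area_px_to_um2",
]

# ITU-R BT.601 luminance weights, the standard RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D grayscale intensity raster with values in [0, 1]."""

    values: np.ndarray  # float64, shape (height, width)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError(f"ImageGrid requires a 2-D array, got shape {v.shape}")
        if v.size < 1:
            raise ValueError("ImageGrid must contain at least one pixel")
        if not np.issubdtype(v.dtype, np.floating):
            raise ValueError("ImageGrid values must be floating point")
        if np.nanmin(v) < 0.0 or np.nanmax(v) > 1.0 or np.isnan(v).any():
            raise ValueError("ImageGrid values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ScaleCalibration:
    """Physical scale of the image: microns per pixel edge.

    Area conversion uses the square of this factor.  Calibration is always
    user-supplied; it cannot be inferred from the raster.
    """

    microns_per_pixel: float

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0):
            raise ValueError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel}"
            )

    @property
    def area_factor(self) -> float:
        """μm² per px²."""
        return self.microns_per_pixel**2


@dataclass(frozen=True)
class SeedPoint:
    """A clicked pixel inside a cell, 0-based (row, col)."""

    row: int
    col: int

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValueError(f"seed coordinates must be >= 0, got {self}")

    def in_bounds(self, height: int, width: int) -> bool:
        return self.row < height and self.col < width


def _normalize_array(arr: np.ndarray) -> np.ndarray:
    """Convert a raw decoded image array to float64 grayscale in [0, 1]."""
    a = np.asarray(arr)
    if a.ndim == 3:
        if a.shape[2] >= 3:  # RGB(A): luminance of the first three channels
            a = a[..., :3].astype(np.float64) @ _LUMA
        else:  # single channel stored with a trailing axis
            a = a[..., 0]
    if a.ndim != 2:
        raise ValueError(f"unsupported image dimensionality: {np.asarray(arr).shape}")

    dtype = np.asarray(arr).dtype
    if np.issubdtype(dtype, np.integer):
        out = a.astype(np.float64) / float(np.iinfo(dtype).max)
    elif np.issubdtype(dtype, np.floating):
        out = a.astype(np.float64)
        if out.size and out.max() > 1.0:  # float image stored on a 0-255 scale
            out = out / 255.0
    else:
        raise ValueError(f"unsupported image dtype: {dtype}")
    return np.clip(out, 0.0, 1.0)


def load_image(path: str | os.PathLike) -> ImageGrid:
    """Read a TIFF/PNG/JPEG file and return a normalised grayscale grid.

    RGB inputs are converted by BT.601 luminance weighting; integer
    intensities are divided by their dtype maximum (255 for 8-bit, 65535
    for 16-bit).

    Raises
    ------
    IOError
        If the file is missing or cannot be decoded (message names the path).
    ValueError
        If the decoded image has zero area.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError as exc:
        raise IOError(f"cannot read image file: {path!s}") from exc
    except Exception as exc:  # corrupt / truncated / unsupported
        raise IOError(f"cannot decode image file: {path!s} ({exc})") from exc
    if raw.size == 0:
        raise ValueError(f"image has zero area: {path!s}")
    return ImageGrid(_normalize_array(raw))


def image_from_array(arr: np.ndarray) -> ImageGrid:
    """Build an :class:`ImageGrid` from an in-memory array (any supported dtype)."""
    a = np.asarray(arr)
    if a.size == 0:
        raise ValueError("image has zero area")
    return ImageGrid(_normalize_array(a))


def area_px_to_um2(area_px: float, calib: ScaleCalibration) -> float:
    """Convert an area in square pixels to μm² using the calibration.

    ``area_um2 = area_px * microns_per_pixel**2``.
    """
    if area_px < 0:
        raise ValueError(f"area_px must be >= 0, got {area_px}")
    return float(area_px) * calib.area_factor
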