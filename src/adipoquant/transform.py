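"""Three-step image transformation applied before trace-mode measurement.

H&E adipose tissue shows bright lipid lumens separated by thin dark
membrane ridges.  Before the one-click tracer can run, the image is pushed
through a fixed three-step pipeline that separates lumen from membrane:

1. **Levels/shadows adjustment** — a linear contrast stretch mapping
   intensities at or below ``shadows`` to 0 and at or above ``low_level_in``
   to 1, saturating lumens against membranes.
2. **Binarisation** — global threshold; pixels at or above the threshold
   become foreground (candidate cell interior).
3. **Despeckling** — an iterated binary majority filter over a disc
   neighbourhood, removing small speckle artefacts from the mask.

The default parameters are ``shadows=0.15, low_level_in=0.9,
binary_threshold=0.8, despeckle_radius=5, despeckle_passes=5``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import ImageGrid

__all__ = [
    "TransformParams",
    "BinaryMask",
    "adjust_levels",
    "binarize",
    "despeckle",
    "transform_pipeline",
]


@dataclass(frozen=True)
class TransformParams:
    """Knobs of the three-step transform; defaults are the tool's standard values."""

    low_level_in: float = 0.9
    shadows: float = 0.15
    binary_threshold: float = 0.8
    despeckle_radius: int = 5
    despeckle_passes: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.low_level_in <= 1.0):
            raise ValueError(f"low_level_in must be in (0, 1], got {self.low_level_in}")
        if not (0.0 <= self.shadows < 1.0):
            raise ValueError(f"shadows must be in [0, 1), got {self.shadows}")
        if self.shadows >= self.low_level_in:
            raise ValueError(
                f"shadows ({self.shadows}) must be < low_level_in ({self.low_level_in})"
            )
        if not (0.0 < self.binary_threshold < 1.0):
            raise ValueError(
                f"binary_threshold must be in (0, 1), got {self.binary_threshold}"
            )
        if self.despeckle_radius < 0:
            raise ValueError("despeckle_radius must be >= 0")
        if self.despeckle_passes < 1:
            raise ValueError("despeckle_passes must be >= 1")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground mask; True = candidate cell interior (bright lumen)."""

    values: np.ndarray  # bool, shape (height, width)

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("BinaryMask requires a 2-D array")
        if self.values.dtype != np.bool_:
            raise ValueError("BinaryMask values must be boolean")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def adjust_levels(img: ImageGrid, shadows: float = 0.15, low_level_in: float = 0.9) -> ImageGrid:
    """Linear contrast stretch: ``shadows -> 0``, ``low_level_in -> 1``.

    Values at or below ``shadows`` clamp to 0, at or above ``low_level_in``
    clamp to 1, and ramp linearly in between.
    """
    if not (0.0 <= shadows < low_level_in <= 1.0):
        raise ValueError(
            f"require 0 <= shadows < low_level_in <= 1, got ({shadows}, {low_level_in})"
        )
    out = (img.values - shadows) / (low_level_in - shadows)
    return ImageGrid(np.clip(out, 0.0, 1.0))


def binarize(img: ImageGrid, threshold: float = 0.8) -> BinaryMask:
    """Global threshold; a pixel is foreground iff its intensity >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return BinaryMask(img.values >= threshold)


def _disc_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr * dr + dc * dc) <= r * r


def despeckle(mask: BinaryMask, radius: int = 5, passes: int = 5) -> BinaryMask:
    """Iterated binary majority filter over a disc neighbourhood.

    Each pass recomputes every pixel as the majority vote of the mask over
    the disc of the given pixel radius centred on it; at the image edge the
    vote runs over the intersection of the disc with the image.  Exact ties
    resolve to foreground.  ``radius=0`` is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if radius == 0:
        return BinaryMask(mask.values.copy())

    foot = _disc_footprint(radius).astype(np.int64)
    # Per-pixel neighbourhood size: constant in the interior, smaller at edges.
    total = ndimage.correlate(
        np.ones(mask.values.shape, dtype=np.int64), foot, mode="constant", cval=0
    )
    cur = mask.values
    for _ in range(passes):
        count = ndimage.correlate(
            cur.astype(np.int64), foot, mode="constant", cval=0
        )
        cur = (2 * count) >= total  # ties -> True
    return BinaryMask(cur)


def transform_pipeline(img: ImageGrid, params: TransformParams | None = None) -> BinaryMask:
    """Run the full transform: adjust_levels -> binarize -> despeckle.

    Deterministic: identical inputs yield bit-identical masks.
    """
    p = params if params is not None else TransformParams()
    leveled = adjust_levels(img, p.shadows, p.low_level_in)
    binary = binarize(leveled, p.binary_threshold)
    return despeckle(binary, p.despeckle_radius, p.despeckle_passes)
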