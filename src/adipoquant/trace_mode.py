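"""Semi-automated "one click" measurement of a cell from a seed point.

The operator clicks once anywhere inside a cell.  Starting from that seed,
an iterative flood fill collects the 4-connected component of foreground
(lumen) pixels, a Moore-neighbour contour walk orders the interior boundary
clockwise, and the cell's area is the exact count of interior pixels.

Because the region is a deterministic function of the mask and of *which
component* the seed lands in — not of where inside the component it lands —
repeated measurements of the same cell from different interior clicks are
identical, which is the defining precision property of this mode.

The fill uses an explicit queue, never call-stack recursion, so arbitrarily
large regions cannot overflow.  A configurable area guard converts
membrane-gap "leaks" (the fill escaping through a broken membrane into a
huge region) into a loud error, signalling that the cell should be measured
by hand trace or ellipse approximation instead.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .image_model import ScaleCalibration, SeedPoint, area_px_to_um2
from .measurements import CellMeasurement
from .transform import BinaryMask

__all__ = [
    "TracedRegion",
    "SeedNotInCellError",
    "RegionLeakError",
    "fill_from_seed",
    "trace_boundary",
    "boundary_pixels",
    "measure_cell_tm",
]


class SeedNotInCellError(ValueError):
    """The seed landed on a background/membrane pixel, not inside a cell."""


class RegionLeakError(RuntimeError):
    """The filled region exceeded the area guard.

    This usually indicates a gap in the cell membrane through which the fill
    escaped; the cell should be measured with hand trace or ellipse
    approximation instead.
    """


@dataclass(frozen=True)
class TracedRegion:
    """The geometry of one traced cell.

    ``pixels`` is the 4-connected interior set; ``boundary`` is the ordered
    clockwise outer contour (a closed cycle of region pixels, each having at
    least one 4-neighbour outside the region or outside the image).
    ``perimeter_px`` measures the contour length: 1 per axial step, sqrt(2)
    per diagonal step, 0 for a single-pixel region.
    """

    pixels: frozenset[tuple[int, int]]
    boundary: tuple[tuple[int, int], ...]
    area_px: int
    perimeter_px: float
    label: str
    touches_border: bool

    def __post_init__(self) -> None:
        if self.area_px != len(self.pixels) or self.area_px < 1:
            raise ValueError("area_px must equal the interior pixel count (>= 1)")
        if not set(self.boundary) <= self.pixels:
            raise ValueError("boundary must be a subset of the region pixels")


def fill_from_seed(
    mask: BinaryMask, seed: SeedPoint, max_area_px: int | None = None
) -> frozenset[tuple[int, int]]:
    """Return the 4-connected foreground component containing the seed.

    Iterative breadth-first frontier expansion from the seed over True
    pixels, using 4-neighbour adjacency.

    Raises
    ------
    SeedNotInCellError
        If the seed is out of bounds or lies on a False (membrane/background)
        pixel.
    RegionLeakError
        If the component grows beyond ``max_area_px`` (None = unlimited).
    """
    h, w = mask.height, mask.width
    if not seed.in_bounds(h, w):
        raise SeedNotInCellError(
            f"seed ({seed.row}, {seed.col}) is outside the {h}x{w} image"
        )
    grid = mask.values
    if not grid[seed.row, seed.col]:
        raise SeedNotInCellError(
            f"seed ({seed.row}, {seed.col}) is not inside a cell "
            "(it lies on a membrane/background pixel)"
        )

    visited = np.zeros((h, w), dtype=bool)
    visited[seed.row, seed.col] = True
    queue: deque[tuple[int, int]] = deque([(seed.row, seed.col)])
    out: list[tuple[int, int]] = []
    count = 0
    while queue:
        r, c = queue.popleft()
        out.append((r, c))
        count += 1
        if max_area_px is not None and count > max_area_px:
            raise RegionLeakError(
                f"region from seed ({seed.row}, {seed.col}) exceeds the "
                f"{max_area_px} px area guard — likely a membrane gap; "
                "consider hand trace or ellipse approximation for this cell"
            )
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < h and 0 <= nc < w and grid[nr, nc] and not visited[nr, nc]:
                visited[nr, nc] = True
                queue.append((nr, nc))
    return frozenset(out)


def boundary_pixels(pixels: frozenset[tuple[int, int]] | set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Pixels of the set having at least one 4-neighbour outside the set."""
    s = set(pixels)
    return {
        (r, c)
        for (r, c) in s
        if any(n not in s for n in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)))
    }


# Clockwise Moore neighbourhood, starting due west, in image coordinates
# (row increases downward): W, NW, N, NE, E, SE, S, SW.
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def trace_boundary(
    pixels: frozenset[tuple[int, int]] | set[tuple[int, int]],
) -> tuple[tuple[int, int], ...]:
    """Order the outer boundary of a 4-connected pixel set clockwise.

    Moore-neighbour contour following, starting from the topmost-then-
    leftmost pixel and terminating by Jacob's stopping criterion (the start
    pixel is re-entered with the same backtrack as initially).  A single
    pixel yields a cycle of length 1.  For regions with interior holes only
    the outer contour is returned.
    """
    region = set(pixels)
    if not region:
        raise ValueError("cannot trace the boundary of an empty pixel set")
    start = min(region)  # topmost, then leftmost
    if len(region) == 1:
        return (start,)

    start_back = (start[0], start[1] - 1)  # west of start: outside by construction

    def step(cur: tuple[int, int], back: tuple[int, int]):
        """Next contour pixel clockwise from the backtrack, plus new backtrack."""
        i = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        back_cand = back  # stays valid if the very first candidate is in-region
        for k in range(1, 9):
            off = _MOORE[(i + k) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if cand in region:
                return cand, back_cand
            back_cand = cand
        return None, back_cand  # isolated pixel

    first, back = step(start, start_back)
    if first is None:  # defensive; single pixels are handled above
        return (start,)

    # Jacob's stopping criterion: terminate when the walk is at the start
    # pixel and about to repeat its first move (position AND direction match).
    contour: list[tuple[int, int]] = [start]
    cur = first
    max_steps = 4 * len(region) + 8
    for _ in range(max_steps):
        if cur == start:
            nxt, nback = step(cur, back)
            if nxt == first:
                break  # cycle closed
            contour.append(cur)  # passing through start along a spur
            cur, back = nxt, nback
            continue
        contour.append(cur)
        cur, back = step(cur, back)
    return tuple(contour)


def _perimeter(contour: tuple[tuple[int, int], ...]) -> float:
    if len(contour) < 2:
        return 0.0
    total = 0.0
    for a, b in zip(contour, contour[1:] + contour[:1]):
        total += math.sqrt(2.0) if (a[0] != b[0] and a[1] != b[1]) else 1.0
    return total


def measure_cell_tm(
    mask: BinaryMask,
    seed: SeedPoint,
    label: str,
    calib: ScaleCalibration,
    max_area_px: int | None = None,
    run_index: int = 1,
) -> CellMeasurement:
    """One-click trace-mode measurement of the cell containing ``seed``.

    Composes :func:`fill_from_seed` and :func:`trace_boundary`; the area in
    px² is the exact interior pixel count, converted to μm² via the
    calibration.  ``max_area_px`` defaults to 25% of the image area as a
    leak guard.  Deterministic: any interior seed of the same cell yields an
    identical measurement.
    """
    if max_area_px is None:
        max_area_px = (mask.height * mask.width) // 4
    pixels = fill_from_seed(mask, seed, max_area_px=max_area_px)
    contour = trace_boundary(pixels)
    rows = [r for r, _ in pixels]
    cols = [c for _, c in pixels]
    touches = (
        min(rows) == 0
        or min(cols) == 0
        or max(rows) == mask.height - 1
        or max(cols) == mask.width - 1
    )
    region = TracedRegion(
        pixels=frozenset(pixels),
        boundary=contour,
        area_px=len(pixels),
        perimeter_px=_perimeter(contour),
        label=label,
        touches_border=touches,
    )
    flags = ["touches_border"] if touches else []
    return CellMeasurement(
        cell_id=label,
        method="TM",
        run_index=run_index,
        area_px=float(region.area_px),
        area_um2=area_px_to_um2(region.area_px, calib),
        geometry=region,
        flags=tuple(flags),
    )
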