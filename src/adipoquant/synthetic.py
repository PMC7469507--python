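"""Synthetic adipose-histology generator with pixel-exact ground truth.

Emulates the appearance that drives the measurement pipeline: bright lipid
lumens (intensity ~0.95) ringed by thin dark membranes (~0.10) on a mid-grey
background (~0.55), with three controllable degradations mimicking
intra-sample heterogeneity seen in real slides:

* **membrane gaps** — an angular arc of a cell's membrane is painted at
  lumen intensity, so a seed fill can escape ("deteriorated membranes");
* **speckles** — 1–3 px bright/dark debris blobs in the background
  ("cellular or foreign artefacts"), which despeckling must remove;
* **intensity noise** — additive Gaussian noise, clipped to [0, 1].

Cells are star-convex: each has a radial profile ``r(θ)`` around its
centre.  ``generate`` uses constant profiles (discs); ``irregular_cell_shapes``
perturbs the radius with random low-order harmonics scaled by an
``irregularity`` knob in [0, 1].  A pixel belongs to a cell's interior iff
its distance from the centre is below ``r(θ)``, so irregularity 0 reduces
exactly to the disc generator.  Membrane thickness is measured radially.

Default geometry: radii 35–55 px, which at the default calibration of
1 μm/px give interior areas of roughly 3.8–9.5 × 10³ μm², the range over
which adipocyte size distributions are conventionally plotted.

Everything is reproducible from ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_model import ImageGrid
from .manual_modes import EllipseApprox, PolygonTrace

__all__ = [
    "SyntheticSpec",
    "GroundTruthCell",
    "GroundTruth",
    "GenerationError",
    "generate",
    "irregular_cell_shapes",
    "ht_polygon_for_cell",
    "ea_for_cell",
]

BACKGROUND = 0.55
LUMEN = 0.95
MEMBRANE = 0.10
_N_THETA = 720  # angular resolution of the stored radial profiles


class GenerationError(RuntimeError):
    """Cell placement failed; try fewer or smaller cells."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic image."""

    height: int = 512
    width: int = 512
    n_cells: int = 12
    radius_range: tuple[float, float] = (35.0, 55.0)
    membrane_thickness: int = 4
    gap_probability: float = 0.0
    gap_arc_degrees: float = 60.0
    speckle_count: int = 25
    noise_sd: float = 0.02
    background_intensity: float = BACKGROUND
    rng_seed: int = 0

    def __post_init__(self) -> None:
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise ValueError(f"radii must be positive and ordered, got {self.radius_range}")
        if self.membrane_thickness < 1:
            raise ValueError("membrane_thickness must be >= 1 px")
        if not (0.0 <= self.gap_probability <= 1.0):
            raise ValueError("gap_probability must be in [0, 1]")
        if self.speckle_count < 0 or self.noise_sd < 0:
            raise ValueError("speckle_count and noise_sd must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        need = 2 * (rmax + self.membrane_thickness)
        if self.height < need or self.width < need:
            raise ValueError(
                f"image ({self.height}x{self.width}) too small for max radius "
                f"{rmax} + membrane {self.membrane_thickness}: need >= {need} per side"
            )
        if not (0.0 <= self.background_intensity <= 1.0):
            raise ValueError("background_intensity must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruthCell:
    """One cell's ground truth: interior pixel set plus its radial profile.

    ``radius_profile`` holds r(θ) at ``_N_THETA`` uniform angles starting at
    θ=0 (pointing along +col); it lets annotation emulators (hand-trace
    polygons, ellipse axes) be derived from the same geometry that was
    rasterised.
    """

    label: str
    center: tuple[float, float]  # (row, col)
    interior: frozenset[tuple[int, int]]
    true_area_px: int
    has_gap: bool
    radius_profile: tuple[float, ...]
    membrane_thickness: float = 4.0

    def __post_init__(self) -> None:
        if self.true_area_px != len(self.interior):
            raise ValueError("true_area_px must equal |interior|")

    def radius_at(self, theta: float) -> float:
        """Linear interpolation of the radial profile at angle theta (rad)."""
        prof = self.radius_profile
        t = (theta % (2 * math.pi)) / (2 * math.pi) * _N_THETA
        i = int(t) % _N_THETA
        frac = t - int(t)
        return prof[i] * (1 - frac) + prof[(i + 1) % _N_THETA] * frac


@dataclass(frozen=True)
class GroundTruth:
    cells: tuple[GroundTruthCell, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for cell in self.cells:
            if seen & cell.interior:
                raise ValueError("ground-truth interiors must be pairwise disjoint")
            seen |= cell.interior


def _radial_profiles(
    rng: np.random.Generator, spec: SyntheticSpec, irregularity: float
) -> list[np.ndarray]:
    """One r(θ) profile per cell: base radius times (1 + irregularity·p(θ))."""
    theta = np.linspace(0.0, 2 * math.pi, _N_THETA, endpoint=False)
    rmin, rmax = spec.radius_range
    profiles = []
    for _ in range(spec.n_cells):
        base = rng.uniform(rmin, rmax)
        if irregularity > 0:
            # smooth perturbation from low-order harmonics, normalised to max |p| = 1
            p = np.zeros(_N_THETA)
            for k in range(2, 6):
                p += rng.uniform(0.3, 1.0) * np.cos(k * theta + rng.uniform(0, 2 * math.pi))
            p /= np.max(np.abs(p))
            prof = base * (1.0 + irregularity * p)
        else:
            prof = np.full(_N_THETA, base)
        profiles.append(prof)
    return profiles


def _place_cells(
    rng: np.random.Generator, spec: SyntheticSpec, extents: list[float]
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping centres; extents include the membrane."""
    centers: list[tuple[float, float]] = []
    clearance = 3.0  # background gap between neighbouring membranes
    max_attempts = 400 * spec.n_cells
    attempts = 0
    for i, ext in enumerate(extents):
        placed = False
        while attempts < max_attempts:
            attempts += 1
            r = rng.uniform(ext + 1, spec.height - ext - 1)
            c = rng.uniform(ext + 1, spec.width - ext - 1)
            ok = all(
                math.hypot(r - rc, c - cc) >= ext + extents[j] + clearance
                for j, (rc, cc) in enumerate(centers)
            )
            if ok:
                centers.append((r, c))
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place cell {i + 1}/{spec.n_cells} after {attempts} "
                "attempts; use fewer or smaller cells or a larger image"
            )
    return centers


def _rasterize(
    spec: SyntheticSpec,
    centers: list[tuple[float, float]],
    profiles: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, GroundTruth]:
    img = np.full((spec.height, spec.width), spec.background_intensity, dtype=np.float64)
    cells: list[GroundTruthCell] = []
    theta_step = 2 * math.pi / _N_THETA

    for idx, ((cy, cx), prof) in enumerate(zip(centers, profiles)):
        rmax_cell = float(prof.max()) + spec.membrane_thickness
        r0 = max(0, int(math.floor(cy - rmax_cell - 1)))
        r1 = min(spec.height, int(math.ceil(cy + rmax_cell + 2)))
        c0 = max(0, int(math.floor(cx - rmax_cell - 1)))
        c1 = min(spec.width, int(math.ceil(cx + rmax_cell + 2)))
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dy = rr - cy
        dx = cc - cx
        dist = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx) % (2 * math.pi)
        # nearest-sample lookup of the radial profile
        tindex = np.minimum((theta / theta_step).astype(int), _N_THETA - 1)
        r_theta = prof[tindex]

        interior = dist < r_theta
        membrane = (~interior) & (dist < r_theta + spec.membrane_thickness)

        has_gap = bool(rng.random() < spec.gap_probability)
        gap_mask = np.zeros_like(membrane)
        if has_gap:
            gap_start = rng.uniform(0, 2 * math.pi)
            gap_width = math.radians(spec.gap_arc_degrees)
            ang = (theta - gap_start) % (2 * math.pi)
            gap_mask = membrane & (ang < gap_width)

        img[r0:r1, c0:c1][membrane] = MEMBRANE
        img[r0:r1, c0:c1][gap_mask] = LUMEN  # broken membrane: lumen shows through
        img[r0:r1, c0:c1][interior] = LUMEN

        pix = frozenset(
            (int(r), int(c)) for r, c in zip(rr[interior].ravel(), cc[interior].ravel())
        )
        cells.append(
            GroundTruthCell(
                label=f"cell_{idx + 1:02d}",
                center=(cy, cx),
                interior=pix,
                true_area_px=len(pix),
                has_gap=has_gap,
                radius_profile=tuple(float(v) for v in prof),
                membrane_thickness=float(spec.membrane_thickness),
            )
        )

    # speckles: 1-3 px debris blobs in the background, away from any cell
    extents = [p.max() + spec.membrane_thickness + 2 for p in profiles]
    placed = 0
    guard = 0
    while placed < spec.speckle_count and guard < 200 * max(spec.speckle_count, 1):
        guard += 1
        sr = int(rng.integers(1, spec.height - 1))
        sc = int(rng.integers(1, spec.width - 1))
        if any(
            math.hypot(sr - cy, sc - cx) < ext
            for (cy, cx), ext in zip(centers, extents)
        ):
            continue
        val = LUMEN if rng.random() < 0.5 else MEMBRANE
        img[sr, sc] = val
        for _ in range(int(rng.integers(0, 3))):  # grow to a 1-3 px blob
            dr, dc = rng.choice([(-1, 0), (1, 0), (0, -1), (0, 1)])
            nr, nc = sr + int(dr), sc + int(dc)
            if 0 <= nr < spec.height and 0 <= nc < spec.width:
                img[nr, nc] = val
        placed += 1

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), GroundTruth(tuple(cells))


def irregular_cell_shapes(
    spec: SyntheticSpec, irregularity: float
) -> tuple[ImageGrid, GroundTruth]:
    """Generate star-convex cells with radial perturbation ∝ ``irregularity``.

    ``irregularity=0`` reduces exactly to :func:`generate` (discs).
    """
    if not (0.0 <= irregularity <= 1.0):
        raise ValueError("irregularity must be in [0, 1]")
    if irregularity >= 1.0:
        raise ValueError("irregularity must be < 1 so radii stay positive")
    rng = np.random.default_rng(spec.rng_seed)
    profiles = _radial_profiles(rng, spec, irregularity)
    extents = [float(p.max()) + spec.membrane_thickness for p in profiles]
    centers = _place_cells(rng, spec, extents)
    values, truth = _rasterize(spec, centers, profiles, rng)
    return ImageGrid(values), truth


def generate(spec: SyntheticSpec) -> tuple[ImageGrid, GroundTruth]:
    """Generate disc-shaped cells (zero irregularity) per the spec."""
    return irregular_cell_shapes(spec, 0.0)


# ---------------------------------------------------------------------------
# Annotation emulators: derive the manual-mode inputs an operator would click
# from the ground-truth geometry, so the three methods can be compared on the
# same synthetic cells without a human in the loop.
# ---------------------------------------------------------------------------


def ht_polygon_for_cell(
    cell: GroundTruthCell,
    n_vertices: int = 24,
    on_outer_edge: bool = True,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PolygonTrace:
    """Emulate a hand trace: vertices at equal angles on the membrane edge.

    ``on_outer_edge=True`` places vertices on the outer membrane edge (the
    conventional operator habit of clicking the visible dark ring), so the
    polygon circumscribes the interior; ``jitter_sd`` adds radial click
    noise in px to emulate operator variability across repeat runs.
    """
    if n_vertices < 3:
        raise ValueError("need >= 3 vertices")
    cy, cx = cell.center
    verts = []
    for i in range(n_vertices):
        theta = 2 * math.pi * i / n_vertices
        r = cell.radius_at(theta)
        # membrane thickness is radial: outer edge sits one ring further out
        if on_outer_edge:
            r += cell.membrane_thickness
        if jitter_sd > 0:
            if rng is None:
                raise ValueError("jitter requires an rng")
            r += float(rng.normal(0.0, jitter_sd))
        verts.append((cy + r * math.sin(theta), cx + r * math.cos(theta)))
    return PolygonTrace(vertices=tuple(verts), label=cell.label)


def ea_for_cell(
    cell: GroundTruthCell,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EllipseApprox:
    """Emulate an ellipse approximation on the cell's "true" axes.

    The major axis is the diameter direction maximising
    ``r(θ) + r(θ+π)`` over the radial profile; endpoints sit on the interior
    boundary at that angle and its opposite.  The semi-minor length is the
    mean of the two perpendicular radii.  ``jitter_sd`` adds radial click
    noise (px) to each of the three clicked lengths.
    """
    prof = np.asarray(cell.radius_profile)
    half = _N_THETA // 2
    diam = prof[:half] + prof[half : 2 * half]
    k = int(np.argmax(diam))
    theta = 2 * math.pi * k / _N_THETA
    cy, cx = cell.center

    def _j() -> float:
        if jitter_sd <= 0:
            return 0.0
        if rng is None:
            raise ValueError("jitter requires an rng")
        return float(rng.normal(0.0, jitter_sd))

    r1 = cell.radius_at(theta) + _j()
    r2 = cell.radius_at(theta + math.pi) + _j()
    p1 = (cy + r1 * math.sin(theta), cx + r1 * math.cos(theta))
    p2 = (cy - r2 * math.sin(theta), cx - r2 * math.cos(theta))
    perp = theta + math.pi / 2
    b = (cell.radius_at(perp) + cell.radius_at(perp + math.pi)) / 2.0 + _j()
    a = math.dist(p1, p2) / 2.0
    b = min(max(b, 1e-6), a)  # clicked semi-minor cannot exceed the semi-major
    return EllipseApprox(p1=p1, p2=p2, b=b, label=cell.label)
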