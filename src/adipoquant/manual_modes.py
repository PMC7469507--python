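"""Manual benchmark measurement modes: hand-trace polygon and ellipse approximation.

Hand trace (HT) is the conventional reference method: the operator clicks
the cell perimeter vertex by vertex and the enclosed polygonal area is the
measurement.  Ellipse approximation (EA) instead records the major-axis
endpoints and a semi-minor length; the area is π·A·B with A, B the
semi-major and semi-minor axes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .image_model import ScaleCalibration, area_px_to_um2
from .measurements import CellMeasurement

__all__ = [
    "PolygonTrace",
    "EllipseApprox",
    "polygon_area",
    "make_ellipse",
    "ellipse_area",
    "measure_cell_ht",
    "measure_cell_ea",
]

Coord = tuple[float, float]


@dataclass(frozen=True)
class PolygonTrace:
    """A hand-traced cell outline: >= 3 (row, col) vertices, implicitly closed.

    A duplicated final vertex equal to the first (the "double-click to
    close" convention) is tolerated and dropped.
    """

    vertices: tuple[Coord, ...]
    label: str

    def __post_init__(self) -> None:
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        if len(verts) >= 2 and verts[-1] == verts[0]:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError(
                f"polygon {self.label!r} needs >= 3 distinct vertices, got {len(verts)}"
            )
        for a, b in zip(verts, verts[1:]):
            if a == b:
                raise ValueError(
                    f"polygon {self.label!r} has consecutive duplicate vertex {a}"
                )
        object.__setattr__(self, "vertices", verts)


@dataclass(frozen=True)
class EllipseApprox:
    """Ellipse defined by major-axis endpoints p1, p2 and semi-minor length b.

    A = |p2 − p1| / 2 is the semi-major axis; the semi-minor axis is
    perpendicular to p1p2 through the midpoint (the ellipse centre).
    B > A is rejected outright — it means the axes were mislabelled.
    """

    p1: Coord
    p2: Coord
    b: float
    label: str

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise ValueError(f"ellipse {self.label!r}: axis endpoints coincide")
        if not (self.b > 0):
            raise ValueError(f"ellipse {self.label!r}: semi-minor length must be > 0")
        if self.b > self.semi_major + 1e-12:
            raise ValueError(
                f"ellipse {self.label!r}: semi-minor b={self.b} exceeds semi-major "
                f"A={self.semi_major} — axes mislabelled"
            )

    @property
    def semi_major(self) -> float:
        return math.dist(self.p1, self.p2) / 2.0

    @property
    def semi_minor(self) -> float:
        return float(self.b)

    @property
    def center(self) -> Coord:
        return ((self.p1[0] + self.p2[0]) / 2.0, (self.p1[1] + self.p2[1]) / 2.0)

    @property
    def minor_direction(self) -> Coord:
        """Unit vector of the semi-minor axis (perpendicular to p1p2)."""
        dr = self.p2[0] - self.p1[0]
        dc = self.p2[1] - self.p1[1]
        norm = math.hypot(dr, dc)
        return (-dc / norm, dr / norm)


def polygon_area(poly: PolygonTrace) -> float:
    """Shoelace area of the closed vertex cycle, in px².

    Orientation-independent (absolute value).  A self-intersecting trace is
    accepted with a warning; the reported value is still the shoelace sum,
    which for a crossed polygon is the signed net area.
    """
    verts = poly.vertices
    if _self_intersects(verts):
        warnings.warn(
            f"polygon {poly.label!r} self-intersects; shoelace area is the "
            "signed net area and may under-represent the traced region",
            stacklevel=2,
        )
    s = 0.0
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        s += c1 * r2 - c2 * r1
    return abs(s) / 2.0


def _segments_cross(a: Coord, b: Coord, c: Coord, d: Coord) -> bool:
    def orient(p: Coord, q: Coord, r: Coord) -> float:
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    return (o1 * o2 < 0) and (o3 * o4 < 0)


def _self_intersects(verts: tuple[Coord, ...]) -> bool:
    n = len(verts)
    edges = [(verts[i], verts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:  # closing edge shares the first vertex
                continue
            if _segments_cross(*edges[i], *edges[j]):
                return True
    return False


def make_ellipse(p1: Coord, p2: Coord, b: float, label: str) -> EllipseApprox:
    """Build an ellipse from the two major-axis endpoints and semi-minor length."""
    return EllipseApprox(p1=tuple(p1), p2=tuple(p2), b=float(b), label=label)


def ellipse_area(e: EllipseApprox) -> float:
    """Area in px²: π·A·B with A, B the semi-major and semi-minor axes."""
    return math.pi * e.semi_major * e.semi_minor


def measure_cell_ht(
    poly: PolygonTrace, calib: ScaleCalibration, run_index: int = 1
) -> CellMeasurement:
    """Hand-trace measurement: shoelace area of the traced polygon."""
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        area = polygon_area(poly)
    if caught:
        flags.append("self_intersecting")
    return CellMeasurement(
        cell_id=poly.label,
        method="HT",
        run_index=run_index,
        area_px=area,
        area_um2=area_px_to_um2(area, calib),
        geometry=poly,
        flags=tuple(flags),
    )


def measure_cell_ea(
    ellipse: EllipseApprox, calib: ScaleCalibration, run_index: int = 1
) -> CellMeasurement:
    """Ellipse-approximation measurement: π·A·B."""
    area = ellipse_area(ellipse)
    return CellMeasurement(
        cell_id=ellipse.label,
        method="EA",
        run_index=run_index,
        area_px=area,
        area_um2=area_px_to_um2(area, calib),
        geometry=ellipse,
        flags=(),
    )
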