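"""Measurement records, size histograms, repeatability and method concordance.

A :class:`CellMeasurement` is one cell × one method × one run.  Summaries:

* **Size histogram** — counts of per-cell areas (μm²) over half-open bins
  ``[e_i, e_{i+1})`` with the last bin closed, the convention of
  :func:`numpy.histogram`; the default six equal-width bins follow the
  conventional adipocyte size-distribution display.
* **Repeatability** — per (cell, method) mean and sample (n−1) standard
  deviation of area over repeated runs.  The trace mode is expected to show
  zero run-to-run variation, since the traced region depends only on which
  cell was clicked, not on where inside it.
* **Concordance** — pairwise method agreement by ordinary least squares of
  method-2 area on method-1 area, summarised by slope, intercept and R²
  (squared Pearson correlation, which for simple OLS equals the coefficient
  of determination).  Note concordance is directional: slope(y|x) differs
  from slope(x|y) in general.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellMeasurement",
    "SizeHistogram",
    "ConcordanceResult",
    "RepeatabilityRow",
    "histogram",
    "repeatability",
    "concordance",
    "pair_by_cell",
]

METHODS = ("TM", "HT", "EA")


@dataclass(frozen=True)
class CellMeasurement:
    """One cell measured by one method in one run."""

    cell_id: str
    method: str  # "TM" | "HT" | "EA"
    run_index: int
    area_px: float
    area_um2: float
    geometry: object = None
    flags: tuple[str, ...] = ()
    timestamp: float | None = None  # optional wall-clock seconds, logged only

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.run_index < 1:
            raise ValueError("run_index must be >= 1")
        if self.area_px < 0:
            raise ValueError("area_px must be >= 0")


@dataclass(frozen=True)
class SizeHistogram:
    """Counts of areas (μm²) over ascending bin edges (n+1 edges, n bins)."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.size < 2 or not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing with >= 2 edges")
        if len(self.counts) != edges.size - 1:
            raise ValueError("need exactly one count per bin")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_um2": self.bin_edges[:-1],
                "bin_right_um2": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass(frozen=True)
class ConcordanceResult:
    """OLS fit y = slope·x + intercept of paired per-cell areas, plus R²."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("concordance requires at least 2 pairs")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class RepeatabilityRow:
    """Per-cell, per-method mean and sample SD of area over repeated runs."""

    cell_id: str
    method: str
    mean_area_um2: float
    sd_area_um2: float | None  # None when only one run exists
    n_runs: int


def histogram(
    areas: list[float] | np.ndarray,
    edges: list[float] | np.ndarray | int = 6,
) -> SizeHistogram:
    """Bin areas (μm²) into a size distribution.

    ``edges`` is either an explicit ascending edge sequence or a bin count
    ``k`` (default 6), in which case k equal-width bins span [min, max] of
    the data.  Bins are half-open ``[e_i, e_{i+1})`` with the last bin
    closed; areas outside the edge span are not counted.
    """
    a = np.asarray(areas, dtype=float)
    if a.size == 0:
        raise ValueError("histogram requires at least one area")
    if isinstance(edges, (int, np.integer)):
        if edges < 1:
            raise ValueError("bin count must be >= 1")
        counts, bin_edges = np.histogram(a, bins=int(edges))
    else:
        e = np.asarray(edges, dtype=float)
        if e.size < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("bin edges must be strictly increasing with >= 2 edges")
        counts, bin_edges = np.histogram(a, bins=e)
    return SizeHistogram(tuple(map(float, bin_edges)), tuple(map(int, counts)))


def repeatability(measurements: list[CellMeasurement]) -> list[RepeatabilityRow]:
    """Per (cell_id, method) mean and sample (n−1) SD of area (μm²).

    Methods are never pooled.  Groups with a single run report ``sd=None``
    rather than 0, since a one-point SD is undefined.
    """
    if not measurements:
        return []
    df = pd.DataFrame(
        {
            "cell_id": [m.cell_id for m in measurements],
            "method": [m.method for m in measurements],
            "area_um2": [m.area_um2 for m in measurements],
        }
    )
    rows: list[RepeatabilityRow] = []
    for (cell_id, method), grp in df.groupby(["cell_id", "method"], sort=True):
        n = len(grp)
        sd = float(grp["area_um2"].std(ddof=1)) if n >= 2 else None
        rows.append(
            RepeatabilityRow(
                cell_id=str(cell_id),
                method=str(method),
                mean_area_um2=float(grp["area_um2"].mean()),
                sd_area_um2=sd,
                n_runs=n,
            )
        )
    return rows


def pair_by_cell(
    meas_x: list[CellMeasurement], meas_y: list[CellMeasurement]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pair per-cell mean areas of two measurement sets by cell_id.

    Cells present in only one set are dropped with a warning.  Returns
    (x areas, y areas, shared cell ids) with x/y averaged over runs.
    """

    def _means(ms: list[CellMeasurement]) -> dict[str, float]:
        acc: dict[str, list[float]] = {}
        for m in ms:
            acc.setdefault(m.cell_id, []).append(m.area_um2)
        return {k: float(np.mean(v)) for k, v in acc.items()}

    mx, my = _means(meas_x), _means(meas_y)
    shared = sorted(set(mx) & set(my))
    dropped = (set(mx) | set(my)) - set(shared)
    if dropped:
        warnings.warn(
            f"{len(dropped)} cell(s) present in only one method were dropped: "
            f"{sorted(dropped)}",
            stacklevel=2,
        )
    x = np.array([mx[c] for c in shared])
    y = np.array([my[c] for c in shared])
    return x, y, shared


def concordance(x: np.ndarray | list[float], y: np.ndarray | list[float]) -> ConcordanceResult:
    """OLS fit of y on x for paired per-cell areas from two methods.

    Returns slope, intercept, R² (squared Pearson r) and the pair count.
    Requires >= 2 pairs and nonzero variance in x.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if xa.size < 2:
        raise ValueError("concordance requires at least 2 paired cells")
    if np.ptp(xa) == 0:
        raise ValueError("x areas have zero variance; slope is undefined")
    fit = stats.linregress(xa, ya)
    r2 = float(fit.rvalue**2)
    if math.isnan(r2):  # y constant: no linear association explained
        r2 = 0.0
    return ConcordanceResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        n=int(xa.size),
    )
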