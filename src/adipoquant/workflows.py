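"""Reproducible measurement runs: file readers/writers and orchestration.

These functions are the scripting surface of the package: load an image,
apply the transform where needed, measure every annotated cell with one of
the three methods, and write results tables, overlays, histograms and a
machine-readable run log.  A second entry point compares results files
across methods (pairwise concordance plus per-cell repeatability).

Annotation file formats (CSV, UTF-8, header row, 0-based coordinates):

* seeds (trace mode):      ``cell_id,row,col``
* vertices (hand trace):   ``cell_id,vertex_index,row,col``
* ellipses (approximation):``cell_id,p1_row,p1_col,p2_row,p2_col,b``

Results CSV columns: ``cell_id,method,run_index,area_px,area_um2,flags``.
Reruns with identical config and inputs produce byte-identical results
files; wall-clock per-cell timings go to the run log only.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .image_model import ImageGrid, ScaleCalibration, SeedPoint, load_image
from .manual_modes import (
    EllipseApprox,
    PolygonTrace,
    measure_cell_ea,
    measure_cell_ht,
)
from .measurements import (
    CellMeasurement,
    concordance,
    histogram,
    repeatability,
)
from .trace_mode import TracedRegion, measure_cell_tm
from .transform import TransformParams, transform_pipeline

__all__ = [
    "RunConfig",
    "MeasureRunResult",
    "CompareRunResult",
    "read_seeds",
    "read_vertices",
    "read_ellipses",
    "write_seeds",
    "write_vertices",
    "write_ellipses",
    "run_measure",
    "run_compare",
    "save_mask_png",
    "write_results_csv",
]

# Overlay outline colours by method (RGB): trace mode blue, hand trace red,
# ellipse approximation yellow.
METHOD_COLORS = {"TM": (0, 90, 255), "HT": (220, 30, 30), "EA": (240, 210, 0)}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one measurement run."""

    image_path: str
    method: str  # "tm" | "ht" | "ea"
    annotations_path: str
    microns_per_pixel: float
    out_dir: str
    transform_params: TransformParams = field(default_factory=TransformParams)
    overlay: bool = True
    write_xlsx: bool = False
    max_area_fraction: float = 0.25  # leak guard for trace mode
    run_index: int = 1
    histogram_bins: int = 6

    def __post_init__(self) -> None:
        if self.method not in ("tm", "ht", "ea"):
            raise ValueError(f"method must be tm/ht/ea, got {self.method!r}")
        if not (self.microns_per_pixel > 0):
            raise ValueError("microns_per_pixel must be > 0")
        if not (0 < self.max_area_fraction <= 1):
            raise ValueError("max_area_fraction must be in (0, 1]")


@dataclass
class MeasureRunResult:
    measurements: list[CellMeasurement]
    errors: list[dict]
    results_csv: Path
    run_log: Path
    success: bool


@dataclass
class CompareRunResult:
    concordance_csv: Path
    repeatability_csv: Path
    concordance_table: pd.DataFrame
    repeatability_table: pd.DataFrame


# ---------------------------------------------------------------------------
# annotation readers (line numbers reported on malformed rows)
# ---------------------------------------------------------------------------


def _read_rows(path: str | Path, required: tuple[str, ...]) -> list[tuple[int, dict]]:
    p = Path(path)
    if not p.exists():
        raise IOError(f"annotation file not found: {p}")
    with open(p, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(required) <= set(reader.fieldnames):
            raise ValueError(
                f"{p}: header must contain columns {', '.join(required)}; "
                f"found {reader.fieldnames}"
            )
        return [(lineno, row) for lineno, row in enumerate(reader, start=2)]


def read_seeds(path: str | Path) -> list[tuple[str, SeedPoint]]:
    """Read a trace-mode seed file: ``cell_id,row,col`` (0-based ints)."""
    out = []
    for lineno, row in _read_rows(path, ("cell_id", "row", "col")):
        try:
            out.append((row["cell_id"], SeedPoint(int(row["row"]), int(row["col"]))))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed seed row at line {lineno}: {exc}") from exc
    return out


def read_vertices(path: str | Path) -> list[PolygonTrace]:
    """Read hand-trace vertices: ``cell_id,vertex_index,row,col``."""
    acc: dict[str, list[tuple[int, float, float]]] = {}
    for lineno, row in _read_rows(path, ("cell_id", "vertex_index", "row", "col")):
        try:
            acc.setdefault(row["cell_id"], []).append(
                (int(row["vertex_index"]), float(row["row"]), float(row["col"]))
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: malformed vertex row at line {lineno}: {exc}"
            ) from exc
    polys = []
    for cell_id, verts in acc.items():
        verts.sort()
        polys.append(
            PolygonTrace(vertices=tuple((r, c) for _, r, c in verts), label=cell_id)
        )
    return polys


def read_ellipses(path: str | Path) -> list[EllipseApprox]:
    """Read ellipse annotations: ``cell_id,p1_row,p1_col,p2_row,p2_col,b``."""
    cols = ("cell_id", "p1_row", "p1_col", "p2_row", "p2_col", "b")
    out = []
    for lineno, row in _read_rows(path, cols):
        try:
            out.append(
                EllipseApprox(
                    p1=(float(row["p1_row"]), float(row["p1_col"])),
                    p2=(float(row["p2_row"]), float(row["p2_col"])),
                    b=float(row["b"]),
                    label=row["cell_id"],
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: malformed ellipse row at line {lineno}: {exc}"
            ) from exc
    return out


def write_seeds(seeds: list[tuple[str, SeedPoint]], path: str | Path) -> Path:
    """Write a trace-mode seed file (``cell_id,row,col``)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "row", "col"])
        for cell_id, s in seeds:
            w.writerow([cell_id, s.row, s.col])
    return p


def write_vertices(polys: list[PolygonTrace], path: str | Path) -> Path:
    """Write hand-trace polygons at full float precision (``repr``)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "vertex_index", "row", "col"])
        for poly in polys:
            for i, (r, c) in enumerate(poly.vertices):
                w.writerow([poly.label, i, repr(float(r)), repr(float(c))])
    return p


def write_ellipses(ellipses: list[EllipseApprox], path: str | Path) -> Path:
    """Write ellipse annotations at full float precision.

    Full precision matters: rounding the semi-minor length can push it past
    the semi-major length for near-circular cells, which the reader rejects
    as mislabelled axes.
    """
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "p1_row", "p1_col", "p2_row", "p2_col", "b"])
        for e in ellipses:
            w.writerow(
                [e.label]
                + [repr(float(v)) for v in (*e.p1, *e.p2, e.b)]
            )
    return p


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_results_csv(measurements: list[CellMeasurement], path: str | Path) -> Path:
    """Write the canonical results table (deterministic, no timestamps)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "method", "run_index", "area_px", "area_um2", "flags"])
        for m in measurements:
            w.writerow(
                [
                    m.cell_id,
                    m.method,
                    m.run_index,
                    f"{m.area_px:.6f}",
                    f"{m.area_um2:.6f}",
                    ";".join(m.flags),
                ]
            )
    return p


def _write_xlsx(measurements: list[CellMeasurement], path: Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [m.cell_id for m in measurements],
            "method": [m.method for m in measurements],
            "run_index": [m.run_index for m in measurements],
            "area_px": [m.area_px for m in measurements],
            "area_um2": [m.area_um2 for m in measurements],
            "flags": [";".join(m.flags) for m in measurements],
        }
    )
    df.to_excel(path, index=False)


def save_mask_png(mask_values: np.ndarray, path: str | Path) -> Path:
    """Save a boolean mask as an 8-bit PNG (white foreground)."""
    import imageio.v3 as iio

    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(p, (mask_values.astype(np.uint8) * 255))
    return p


def _paint(rgb: np.ndarray, rows: np.ndarray, cols: np.ndarray, color: tuple) -> None:
    h, w = rgb.shape[:2]
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    rgb[rows[ok], cols[ok]] = color


def render_overlay(img: ImageGrid, measurements: list[CellMeasurement]) -> np.ndarray:
    """Grayscale image as RGB with each cell's outline in its method colour."""
    rgb = np.repeat((img.values * 255).astype(np.uint8)[..., None], 3, axis=2)
    for m in measurements:
        color = METHOD_COLORS[m.method]
        g = m.geometry
        if isinstance(g, TracedRegion):
            rows = np.array([r for r, _ in g.boundary])
            cols = np.array([c for _, c in g.boundary])
            _paint(rgb, rows, cols, color)
        elif isinstance(g, PolygonTrace):
            rr = [v[0] for v in g.vertices]
            cc = [v[1] for v in g.vertices]
            rows, cols = skdraw.polygon_perimeter(rr, cc, shape=rgb.shape[:2], clip=True)
            _paint(rgb, np.asarray(rows), np.asarray(cols), color)
        elif isinstance(g, EllipseApprox):
            cy, cx = g.center
            dr = g.p2[0] - g.p1[0]
            dc = g.p2[1] - g.p1[1]
            # skimage measures orientation from the column axis, anticlockwise
            orientation = float(np.arctan2(dr, dc))
            rows, cols = skdraw.ellipse_perimeter(
                int(round(cy)),
                int(round(cx)),
                int(round(g.semi_minor)),
                int(round(g.semi_major)),
                orientation=orientation,
                shape=rgb.shape[:2],
            )
            _paint(rgb, np.asarray(rows), np.asarray(cols), color)
    return rgb


def _write_histogram(
    measurements: list[CellMeasurement], out_dir: Path, bins: int
) -> None:
    areas = [m.area_um2 for m in measurements]
    if not areas or len(set(areas)) < 2:
        return
    h = histogram(areas, bins)
    h.to_frame().to_csv(out_dir / "histogram.csv", index=False)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    edges = np.asarray(h.bin_edges)
    ax.bar(
        edges[:-1],
        h.counts,
        width=np.diff(edges),
        align="edge",
        edgecolor="black",
        color="#6699cc",
    )
    ax.set_xlabel("cell area (μm²)")
    ax.set_ylabel("count")
    ax.set_title("Cell size distribution")
    fig.tight_layout()
    fig.savefig(out_dir / "histogram.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_measure(config: RunConfig) -> MeasureRunResult:
    """Measure every annotated cell in an image with one method.

    Partial failures never corrupt outputs: each cell's row is either
    complete in the results CSV or absent, with the reason recorded in the
    run log and in the returned ``errors``.  ``success`` is True iff every
    cell measured cleanly.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calib = ScaleCalibration(config.microns_per_pixel)
    img = load_image(config.image_path)

    measurements: list[CellMeasurement] = []
    errors: list[dict] = []
    timings: dict[str, float] = {}

    if config.method == "tm":
        mask = transform_pipeline(img, config.transform_params)
        guard = int(config.max_area_fraction * mask.height * mask.width)
        for cell_id, seed in read_seeds(config.annotations_path):
            t0 = time.perf_counter()
            try:
                measurements.append(
                    measure_cell_tm(
                        mask,
                        seed,
                        label=cell_id,
                        calib=calib,
                        max_area_px=guard,
                        run_index=config.run_index,
                    )
                )
            except Exception as exc:
                errors.append({"cell_id": cell_id, "error": str(exc)})
            timings[cell_id] = time.perf_counter() - t0
    elif config.method == "ht":
        for poly in read_vertices(config.annotations_path):
            t0 = time.perf_counter()
            try:
                measurements.append(
                    measure_cell_ht(poly, calib, run_index=config.run_index)
                )
            except Exception as exc:
                errors.append({"cell_id": poly.label, "error": str(exc)})
            timings[poly.label] = time.perf_counter() - t0
    else:  # ea
        for ell in read_ellipses(config.annotations_path):
            t0 = time.perf_counter()
            try:
                measurements.append(
                    measure_cell_ea(ell, calib, run_index=config.run_index)
                )
            except Exception as exc:
                errors.append({"cell_id": ell.label, "error": str(exc)})
            timings[ell.label] = time.perf_counter() - t0

    results_csv = write_results_csv(measurements, out_dir / "results.csv")
    if config.write_xlsx:
        _write_xlsx(measurements, out_dir / "results.xlsx")
    if config.overlay and measurements:
        import imageio.v3 as iio

        iio.imwrite(out_dir / "overlay.png", render_overlay(img, measurements))
    if len(measurements) >= 2:
        _write_histogram(measurements, out_dir, config.histogram_bins)

    run_log = out_dir / "run_log.json"
    log = {
        "config": {
            "image_path": str(config.image_path),
            "method": config.method,
            "annotations_path": str(config.annotations_path),
            "microns_per_pixel": config.microns_per_pixel,
            "transform_params": {
                "low_level_in": config.transform_params.low_level_in,
                "shadows": config.transform_params.shadows,
                "binary_threshold": config.transform_params.binary_threshold,
                "despeckle_radius": config.transform_params.despeckle_radius,
                "despeckle_passes": config.transform_params.despeckle_passes,
            },
            "max_area_fraction": config.max_area_fraction,
            "run_index": config.run_index,
        },
        "n_measured": len(measurements),
        "per_cell_seconds": timings,
        "errors": errors,
    }
    run_log.write_text(json.dumps(log, indent=2), encoding="utf-8")
    return MeasureRunResult(
        measurements=measurements,
        errors=errors,
        results_csv=results_csv,
        run_log=run_log,
        success=not errors,
    )


def _load_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str})
    needed = {"cell_id", "method", "run_index", "area_um2"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: results file missing columns {needed - set(df.columns)}")
    return df


def run_compare(
    results_paths: list[str | Path], out_dir: str | Path, scatter: bool = True
) -> CompareRunResult:
    """Compare two or three methods' results files.

    Writes a pairwise concordance table (one OLS fit per method pair, x =
    first method alphabetically in the pair ordering HT, TM, EA as plotted
    conventionally), a per-cell repeatability table, and scatter plots with
    fitted trendlines.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.concat([_load_results(p) for p in results_paths], ignore_index=True)

    # per-cell mean area per method (mean over repeat runs)
    pivot = df.groupby(["cell_id", "method"])["area_um2"].mean().unstack()
    methods = [m for m in ("HT", "TM", "EA") if m in pivot.columns]
    if len(methods) < 2:
        raise ValueError("run_compare needs results from at least two methods")

    rows = []
    for mx, my in combinations(methods, 2):
        sub = pivot[[mx, my]].dropna()
        if len(sub) < 2:
            raise ValueError(
                f"no (or too few) overlapping cell_ids between {mx} and {my}"
            )
        res = concordance(sub[mx].to_numpy(), sub[my].to_numpy())
        rows.append(
            {
                "x_method": mx,
                "y_method": my,
                "slope": res.slope,
                "intercept_um2": res.intercept,
                "r_squared": res.r_squared,
                "n_cells": res.n,
            }
        )
        if scatter:
            fig, ax = plt.subplots(figsize=(4.2, 4.2))
            ax.scatter(sub[mx], sub[my], s=22, facecolors="none", edgecolors="black")
            xs = np.linspace(sub[mx].min(), sub[mx].max(), 50)
            ax.plot(xs, res.slope * xs + res.intercept, "k-", lw=1)
            ax.set_xlabel(f"{mx} area (μm²)")
            ax.set_ylabel(f"{my} area (μm²)")
            ax.set_title(
                f"{my} vs {mx}: slope {res.slope:.3f}, R² {res.r_squared:.3f}"
            )
            fig.tight_layout()
            fig.savefig(out / f"concordance_{mx}_{my}.png", dpi=120)
            plt.close(fig)
    conc_df = pd.DataFrame(rows)
    conc_csv = out / "concordance.csv"
    conc_df.to_csv(conc_csv, index=False)

    meas = [
        CellMeasurement(
            cell_id=str(r.cell_id),
            method=str(r.method),
            run_index=int(r.run_index),
            area_px=float(getattr(r, "area_px", r.area_um2)),
            area_um2=float(r.area_um2),
        )
        for r in df.itertuples()
    ]
    rep_rows = repeatability(meas)
    rep_df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in rep_rows],
            "method": [r.method for r in rep_rows],
            "mean_area_um2": [r.mean_area_um2 for r in rep_rows],
            "sd_area_um2": [r.sd_area_um2 for r in rep_rows],
            "n_runs": [r.n_runs for r in rep_rows],
        }
    )
    rep_csv = out / "repeatability.csv"
    rep_df.to_csv(rep_csv, index=False)
    return CompareRunResult(
        concordance_csv=conc_csv,
        repeatability_csv=rep_csv,
        concordance_table=conc_df,
        repeatability_table=rep_df,
    )
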