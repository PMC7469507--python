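# Methods

## The measurement problem

In H&E sections, adipocytes appear as large, bright lipid vacuoles separated
by thin dark membrane ridges. A cell's "size" is its cross-sectional lumen
area. The package measures it three ways on the same raster: a
semi-automated trace mode driven by one seed click per cell, and two manual
benchmarks (perimeter polygon, ellipse approximation). All modes report px²
and μm²; calibration (μm/px) must be supplied by the user because it cannot
be recovered from the raster.

Coordinates are 0-based `(row, col)` with row increasing downward,
everywhere. RGB inputs are converted with BT.601 luminance weights
(0.299, 0.587, 0.114); 8-/16-bit integers are divided by their dtype
maximum. These conventions are fixed so results are reproducible
bit-for-bit.

## Trace mode

1. **Levels/shadows adjustment** — linear contrast stretch
   `v ↦ clip((v − shadows)/(low_level_in − shadows), 0, 1)`. `shadows` and
   `low_level_in` are interpreted as the input-range endpoints of the
   stretch (shadows → 0, low_level_in → 1); with the defaults (0.15, 0.9)
   this saturates lipid lumens against membranes. The original semantics of
   these two controls were not documented; the endpoint interpretation is
   the package's design choice, consistent with the defaults' ordering.
2. **Binarisation** — `v ≥ binary_threshold` (default 0.8). The comparison
   is inclusive so fully saturated pixels stay foreground.
3. **Despeckling** — iterated binary majority (median) filter over a disc
   of `despeckle_radius` pixels (default 5), repeated `despeckle_passes`
   times (default 5). At image edges the vote runs over the disc∩image;
   exact ties resolve to foreground; radius 0 is the identity. Majority
   filtering is the canonical despeckle that uses both a radius and a pass
   count.

Measurement from a seed: the 4-connected foreground component containing
the clicked pixel is collected by an explicit-queue breadth-first flood
fill (never call-stack recursion, so region size cannot overflow). The
interior boundary is ordered clockwise by Moore-neighbour contour
following from the topmost-then-leftmost boundary pixel, terminated by
Jacob's criterion (the walk re-enters the start pixel and repeats its
first move). Area is the exact interior pixel count — boundary pixels are
part of the region; perimeter sums 1 per axial step and √2 per diagonal
step along the contour (0 for a single pixel). For regions with interior
holes only the outer contour is traced; hole pixels are excluded from the
component by construction.

**Precision.** The traced region is a function of the mask and the
component identity only, so any interior click returns the identical pixel
set: run-to-run variance is exactly zero. This is asserted exhaustively in
the tests (every interior pixel of every cell of a fixture used as seed).

**Leak guard.** A membrane gap lets the fill escape into neighbouring
bright tissue. `measure_cell_tm` bounds the region at `max_area_px`
(default 25% of the image) and raises a `RegionLeakError` naming the seed,
so the operator can fall back to the manual modes for that cell. Regions
touching the image border are measured but flagged `touches_border`, since
their true extent is unknown.

## Manual modes

* **Hand trace**: shoelace area of the implicitly closed vertex cycle,
  orientation-independent. A duplicated final vertex (double-click-to-close)
  is dropped. Self-intersecting traces are accepted with a warning and the
  measurement is flagged — the shoelace value is then a signed net area.
* **Ellipse approximation**: `A = |p₂ − p₁|/2`, centre at the midpoint,
  semi-minor axis perpendicular through the centre. `B > A` is rejected
  ("axes mislabelled") rather than silently swapped, preserving the
  semantic that the first click pair is the major axis.

## Summaries

* **Histogram**: half-open bins `[eᵢ, eᵢ₊₁)`, last bin closed (the
  `numpy.histogram` convention); a bin count k (default 6) spans
  [min, max] of the data with equal widths. Out-of-range areas are not
  counted.
* **Repeatability**: per (cell, method), mean and sample SD (n−1) of μm²
  areas; single-run groups report SD as absent, not 0. Methods are never
  pooled.
* **Concordance**: OLS of y on x for per-cell mean areas paired by cell id
  (cells present in only one method are dropped with a warning). R² is the
  squared Pearson correlation, which equals the OLS coefficient of
  determination for a simple regression. Concordance is directional:
  slope(y|x) ≠ 1/slope(x|y) unless R² = 1.

## Synthetic generator

`SyntheticSpec` describes a stated world: background 0.55, lumen 0.95,
membrane 0.10 intensities — chosen so the default transform parameters
separate lumen from membrane; cell radii 35–55 px, which at the default
1 μm/px give areas ≈ 3.8–9.5 × 10³ μm², the conventional plotting range for
adipocyte size distributions; membrane thickness 4 px; mild defaults of
25 background speckles and intensity noise SD 0.02. Cells are star-convex:
a pixel is interior iff its distance from the centre is below a radial
profile r(θ) (720 samples). `generate` uses constant profiles (discs);
`irregular_cell_shapes` perturbs the radius with random harmonics of order
2–5 scaled by an irregularity knob in [0, 1), so irregularity 0 reduces
exactly to discs. Centres are rejection-sampled so that cells (including
membranes, +3 px clearance) never overlap; infeasible packings raise a
`GenerationError`. Everything is reproducible from `rng_seed`.

Degradations: `gap_probability` opens an angular membrane arc
(`gap_arc_degrees`, default 60°) at lumen intensity; speckles are 1–3 px
bright/dark blobs placed in the background away from cells (foreign debris
that despeckling must remove); Gaussian noise is added and clipped to
[0, 1]. One deliberate extension: with the default mid-grey background, a
membrane gap opens into *background* that binarises to False, so a leak
cannot occur; leak scenarios are therefore emulated with
`background_intensity` raised (e.g. 0.85), representing densely packed
tissue where everything around a broken membrane is bright. Thin membranes
next to a bright surround are themselves erased by majority filtering, so
leak fixtures use thick (≈12 px) membranes.

Annotation emulators derive manual-mode inputs from ground truth so the
three methods can be compared without a human: `ht_polygon_for_cell`
samples n vertices at equal angles on the membrane edge (outer by default,
i.e. the polygon circumscribes the interior); `ea_for_cell` takes the
diameter direction maximising r(θ) + r(θ+π) as the major axis and the mean
perpendicular radius as B. Both accept Gaussian radial click jitter to
emulate operator variability. What a green test on these fixtures does
**not** establish: performance on real stain variability, out-of-focus
regions, touching membranes without any background between cells, or
whole-slide illumination gradients — none of which the generator models.

## Numerical choices and known limitations

* **Despeckle rim erosion.** An iterated majority filter moves boundaries
  by local curvature: a convex rim pixel sees slightly less than half of
  its disc neighbourhood inside the region, so rasterised discs lose a thin
  boundary rim (~0.2–2.2% of area over 5 passes for radii 35–55; worst for
  the smallest cells). This is a property of median filtering, not an
  implementation artefact, and it does not depend on membrane thickness.
  Consequently trace-mode areas sit slightly *below* ground truth on clean
  fixtures — recovery is within 3% on the default geometry, within 5% at
  noise SD 0.05 — and exact pixel-for-pixel recovery through the full
  pipeline is not attainable; the test suite carries one intentionally
  failing assertion documenting this. (Trace mode applied to an untouched
  mask, without despeckling, is exact: area equals the component size by
  construction.)
* Majority-filter ties resolve to foreground; thresholds are inclusive
  (≥); both must be fixed one way and are asserted in tests.
* The flood fill uses 4-connectivity for the interior and the contour walk
  uses 8-connectivity, the standard duality that avoids paradoxical
  boundaries.
* Histogram bin edges, when given explicitly, silently exclude
  out-of-range areas (conservation is asserted only over in-range data).
* Results CSVs contain no timestamps, so identical inputs yield
  byte-identical files; per-cell wall-clock timings go to `run_log.json`
  only and are never analysed (hardware-dependent).
* Overlay rendering colours outlines by method (TM blue, HT red, EA
  yellow) and rounds ellipse parameters to integer pixels for drawing;
  measurements themselves are never rounded.
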