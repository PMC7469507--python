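"""Hand-trace and ellipse-approximation measurements.

Hand trace: the operator clicks perimeter vertices; the area is the shoelace
sum of the closed polygon.  Ellipse approximation: the operator clicks the
major-axis endpoints and a semi-minor length; the area is pi*A*B.  Both are
shown on simple shapes with known areas, then on an emulated cell.
"""

import math

import adipoquant as aq

calib = aq.ScaleCalibration(microns_per_pixel=0.5)

# --- hand trace on a 3-4-5 right triangle ----------------------------------
tri = aq.PolygonTrace(vertices=((0, 0), (0, 40), (30, 0)), label="triangle")
area_px = aq.polygon_area(tri)
print(f"triangle: {area_px:.1f} px^2 (expect 600), "
      f"{aq.area_px_to_um2(area_px, calib):.1f} um^2 at 0.5 um/px")

# --- ellipse approximation ---------------------------------------------------
ell = aq.make_ellipse(p1=(50, 20), p2=(50, 80), b=20, label="cell_x")
print(f"ellipse:  A={ell.semi_major}, B={ell.semi_minor}, "
      f"area {aq.ellipse_area(ell):.1f} px^2 (pi*30*20 = {math.pi*600:.1f})")

# --- both modes on the same emulated cell -----------------------------------
spec = aq.SyntheticSpec(n_cells=1, noise_sd=0.0, speckle_count=0, rng_seed=3)
_, truth = aq.irregular_cell_shapes(spec, irregularity=0.3)
cell = truth.cells[0]

ht = aq.measure_cell_ht(aq.ht_polygon_for_cell(cell, n_vertices=24), calib)
ea = aq.measure_cell_ea(aq.ea_for_cell(cell), calib)
true_um2 = aq.area_px_to_um2(cell.true_area_px, calib)
print(f"\nirregular cell, truth {true_um2:.0f} um^2:")
print(f"  hand trace (24 vertices, outer membrane edge): {ht.area_um2:.0f} um^2")
print(f"  ellipse approximation on the longest axis:     {ea.area_um2:.0f} um^2")
print(
    "\nThe polygon circumscribes the membrane, so it sits above the interior"
    "\narea; the ellipse's error depends on how elliptical the cell really is."
)
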