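"""One-click trace-mode measurement on a synthetic adipose image.

Builds a clean synthetic H&E-like image (bright lipid lumens, thin dark
membranes), runs the three-step transform (levels/shadows -> binarise ->
despeckle) and measures each cell from a single seed click at its centre.
Printed per cell: the measured interior area next to the generator's ground
truth — the small deficit is the despeckle filter smoothing the cell rim.
"""

import adipoquant as aq

spec = aq.SyntheticSpec(n_cells=6, gap_probability=0.0, noise_sd=0.02, rng_seed=7)
image, truth = aq.generate(spec)

mask = aq.transform_pipeline(image, aq.TransformParams())  # standard defaults
calib = aq.ScaleCalibration(microns_per_pixel=1.0)

print(f"{'cell':<9}{'TM area (um^2)':>16}{'truth (um^2)':>14}{'error':>8}")
for cell in truth.cells:
    seed = aq.SeedPoint(int(round(cell.center[0])), int(round(cell.center[1])))
    m = aq.measure_cell_tm(mask, seed, cell.label, calib)
    err = (m.area_um2 - cell.true_area_px) / cell.true_area_px
    print(f"{cell.label:<9}{m.area_um2:>16.0f}{cell.true_area_px:>14}{err:>8.1%}")

print(
    "\nAreas are interior pixel counts scaled by (um/px)^2; any interior click"
    "\nof the same cell returns the identical region, so repeat runs have zero"
    "\nvariance."
)
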