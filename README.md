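# filotrack

Quantitative morphology and motility analysis for fluorescently labeled
lymphoma cells.

Classical Hodgkin lymphoma (cHL) and anaplastic large cell lymphoma
(ALCL) tumor cells look alike under the microscope but disseminate very
differently.  One way to probe why is to compare, across cell lines
embedded in collagen: 3-D cell size and polarity, the filopodia-like
actin protrusions on the cell surface (how many per µm of cell
perimeter, how long, and how radially they point), basal motility
(velocity and straightness of tracked cells), transwell migration
efficiency, and the size of the T-cell rosettes tumor cells nucleate in
co-culture.  `filotrack` implements that entire measurement chain as a
tested Python library plus CLI, together with a synthetic-microscopy
generator that renders ground-truth data for every stage — so each
measurement can be validated against known geometry before it is
trusted on real images.

## What it computes

| Stage | Input | Output |
| --- | --- | --- |
| `segmentation` | actin-reporter OME-TIFF z-stack | labels; per cell: volume, equivalent diameter d = (6V/π)^⅓, main-body perimeter, principal axes, polarity; Gaussian size fit; sub-10-µm fragments excluded |
| `filopodia` | stack + labels | per protrusion: base, tip, geodesic length, radial angle θ ∈ [0°, 90°] (0° = pointing straight out of the cell); per cell: count / perimeter |
| `motility` | track tables (t, x, y) | accumulated & Euclidean distance, straightness = d_euclid / d_accum, velocity; condition summaries |
| `transwell` | count tables | efficiency = 100 · migrated / input, with replicate SEM and viability |
| `clusters` | two-channel (green tumor / red T cell) images | dual-population connected components: count and exact pixel-count areas |
| `stats` | any condition table | Shapiro-Wilk-gated comparison: t-test / Mann-Whitney (2 groups), ANOVA + Bonferroni / Kruskal-Wallis (>2), with the decision path recorded |

The protrusion pipeline follows the standard recipe for thin bright
structures: difference-of-Gaussians band-pass (σ = 0.3 / 1.0 µm),
global threshold, 3-D skeletonization, then branch classification — a
skeleton branch is a filopodium when it emerges from the cell membrane.
All geometry is computed in physical units on anisotropic voxel grids
(default 0.3 µm z-interval, 0.25 µm lateral).

## Worked example

Render one cell with four 5-µm filopodia at a 35° deviation angle,
recover them, and summarize:

```python
import numpy as np
import filotrack as ft
from filotrack.studies import single_cell_spec, analyze_single_cell_stack

rng = np.random.default_rng(0)
dirs = []
while len(dirs) < 4:
    d = rng.normal(size=3); d /= np.linalg.norm(d)
    if all(np.degrees(np.arccos(np.clip(d @ e, -1, 1))) > 40 for e in dirs):
        dirs.append(d)
filopodia = tuple(
    ft.FilopodiumSpec(base_direction=tuple(d), deviation_angle=35.0,
                      length=5.0, azimuth=float(rng.uniform(0, 360)))
    for d in dirs
)
spec = single_cell_spec(filopodia, body_radius=6.0, gaussian_sd=2.0, seed=0)
cells, detected, labels, image = analyze_single_cell_stack(spec)

cell = cells[0]
print(f"equivalent diameter: {cell.equivalent_diameter:.2f} um")
print(f"main-body perimeter: {cell.main_body_perimeter:.2f} um")
print(f"polarity: {cell.polarity_class}")
metrics = ft.summarize_filopodia(detected, cells)[0]
print(f"filopodia: {metrics.count} "
      f"({metrics.count_per_perimeter:.4f} per um of perimeter)")
print(f"mean length: {metrics.mean_length:.2f} um")
print(f"mean radial angle: {metrics.mean_radial_angle:.1f} deg")
```

prints

```
equivalent diameter: 12.04 um
main-body perimeter: 39.09 um
polarity: unpolarized
filopodia: 4 (0.1023 per um of perimeter)
mean length: 4.76 um
mean radial angle: 36.5 deg
```

The 12-µm-diameter sphere is recovered to within a voxel (12.04 µm; a
perfect sphere projects to a 37.7-µm circle, measured 39.09 µm on the
voxelized mask), all four protrusions are found, their lengths are
within 5 % of the rendered 5 µm, and the mean angle lands 1.5° from the
constructed 35°.

## Command line

```sh
filotrack simulate segment filopodia tracks transwell clusters stats --out run1 --seed 0
# or:  filotrack all --out run1 --seed 0
```

`simulate` writes a demonstration scene (an OME-TIFF stack of three
cells plus fragments with its ground truth, two track conditions, and
two cluster conditions); the later stages analyze whatever matching
files are in the output directory, so real stacks / track tables /
cluster images can be dropped in instead.  Every output CSV starts with
provenance comments (software version, config hash, seed), and a fixed
config + seed reproduces every file byte for byte.  Parameters live in
a YAML config (`--config`); CLI flags override the file.

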