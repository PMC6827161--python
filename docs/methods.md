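# Methods

`filotrack` quantifies how lymphoma cell lines differ in shape, actin
protrusions and motility, using the kind of data a spinning-disc
time-lapse / z-stack study of Life-Act-GFP-labeled cells produces.  The
pipeline has six analysis stages and a synthetic-data generator that
provides ground-truth inputs for every stage.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## 3-D cell segmentation

Cell bodies are segmented by a two-stage thresholding scheme: a global
threshold over the whole stack proposes candidate objects, then a local
threshold inside each candidate's bounding box (2-voxel margin) refines
its mask.  Both stages default to Otsu's criterion; the method is a
config parameter (`threshold_method`, `local_threshold_method`).

Otsu's threshold is known to drift between two *foreground* intensity
classes when background dominates the histogram, which silently deletes
dim cells.  The global stage is therefore iterated: after removing the
first foreground class, the remainder is re-thresholded, and the new
class is accepted as additional candidates only while it covers less
than `max_foreground_fraction` (default 0.25) of the remaining voxels —
once a split looks like a noise bisection (roughly half/half), iteration
stops.  Up to 3 passes are attempted.  Each candidate's refinement floor
is the threshold of the pass that found it, so every refined mask is a
subset of its candidate region (the mask-nesting invariant).

Touching cells are separated by a watershed on the inverted Euclidean
distance transform, computed with physical voxel sampling so anisotropic
stacks (0.3 µm z-interval, 0.25 µm lateral by default) are handled
correctly.  Seeds are distance-map maxima that dominate a physical
neighborhood of radius `min_peak_separation` (default 5 µm); requiring
dominance over that wide a window keeps quantization maxima along the
medial ridge of a single elongated cell from triggering a spurious
split.  Splitting preserves the voxel-set union exactly and never
decreases the label count.

Per-cell measurements are all in physical units: volume is the exact
voxel count times the voxel volume; the equivalent diameter is that of
the equal-volume sphere; the main-body perimeter is the marching-squares
contour length of the z-projection after a morphological opening with a
1-µm ellipsoidal footprint (`opening_radius`) removes protrusions, so
filopodia do not inflate the denominator of the count-per-perimeter
metric.  Principal axis lengths come from the second moments of the
voxel coordinates (a solid ellipsoid of semi-axis *a* has coordinate
variance *a²/5*, so each full axis is 2·√(5λ)).

Objects with equivalent diameter below `fragment_threshold` (default
10 µm) are excluded as vesicle-like fragments (oncosomes); the threshold
is inclusive on the kept side.  The size measure for the cut is the
equivalent spherical diameter — a deliberate operationalization, since
"size" could also mean a projected diameter.  The size distribution of
the kept cells is fitted by Gaussian maximum likelihood (sample mean,
population SD); distribution-width comparisons between conditions use
the SD.

Polarity: a cell is called polarized when its longest/shortest principal
axis ratio exceeds `elongation_threshold` (default 1.5).  This is our
own operational definition — axis-ratio rules are the standard fallback
when no reference rule is given — and the threshold is exposed in the
config.  Degenerate (zero) axes classify as unpolarized with a warning.

## Filopodia extraction and morphometry

Thin actin protrusions are enhanced with a difference-of-Gaussians
filter, G(σ_small)∗I − G(σ_large)∗I, with σ_small = 0.3 µm and
σ_large = 1.0 µm by default — a band-pass matched to sub-micron tubes
(tube radius ≈ 0.4 µm ≈ σ_small·√2).  Sigmas are specified in µm and
converted per axis, so the filter is physically isotropic on anisotropic
grids.  The enhanced image is thresholded globally (Otsu over the
positive response values), closed with a 0.3-µm footprint to bridge
voxel-scale gaps near protrusion bases, and skeletonized in 3-D.  The
skeleton becomes a 26-connected graph whose edge weights are physical
step lengths; spur branches shorter than `prune_length` (default 1 µm)
are removed as skeletonization artifacts.

A branch is a filopodium when it *emerges from the membrane*: at least
one node outside the main cell body (the opened mask, not the raw label,
so protrusions themselves are not "body") and its innermost node within
a membrane shell (`membrane_shell`, default 1 µm).  Branches entirely
interior to a body are discarded.  Branches are assigned to the nearest
body at their base.

Three numerical details matter for unbiased morphometry, all discovered
on rendered ground truth:

* **Lattice zigzag.**  Summing raw voxel steps overestimates the length
  of a straight tube by a few percent along non-lattice directions; path
  lengths are computed on the polyline resampled at every 3rd node.
* **Base fillet.**  Where a protrusion joins the body, the skeleton
  curls into the body/filament fillet.  The raw membrane-crossing point
  is therefore displaced — dramatically so for near-tangential
  protrusions.  The protrusion axis is instead fitted by PCA to the
  branch nodes outside the body, excluding nodes within 0.6 µm of the
  body surface (the fillet zone), and the base is found by marching this
  axis line inward against the body distance map: the entry point into
  the body, the middle of a short grazing run for tangential
  protrusions, or the closest-approach point if the line never touches
  the body.  A chord (base→tip) estimator is available via
  `direction_method="tip"`.
* **Tip position.**  The DoG response extends past the physical tip by
  roughly one filament radius, which cancels the usual skeleton endpoint
  retraction; skeleton endpoints of DoG-derived masks track the true tip
  well, so no tip-radius correction is applied by default
  (`tip_correction` re-enables it for raw binary masks).

The radial angle of a filopodium is the acute angle between its axis and
the radial direction from the cell centroid through its base: 0° means
pointing straight out of the cell ("orthogonal to the membrane"), 90°
tangential.  Angles are measured in 3-D.  On rendered ground truth the
estimator is unbiased to within ~1–2° for deviation angles up to ~70°;
exactly tangential protrusions (≈ 90°) are geometrically degenerate on
the voxel grid — any sub-voxel error in the base position rotates the
radial reference at ≈ 10°/µm — and recover only to within ~10–25°.  The
tangential contract is therefore validated on constructed geometry,
where it is exact.  This limitation is immaterial for condition-level
medians in the 30–55° range, where recovery is within ~2°.

Per-cell metrics are count, count per main-body perimeter (1/µm), mean
length and mean radial angle; cells without filopodia contribute a
count-per-perimeter of 0 and are excluded from length/angle aggregates.
Condition-level summaries report medians (the robust statistic used for
angle comparisons) and means with n.

## Migration tracks

Per track: accumulated distance (sum of step lengths), Euclidean
distance (start→end), straightness = Euclidean/accumulated (0 when the
cell never moved), duration, and velocity = accumulated distance /
duration (mean path speed).  "Velocity" of a tracked cell is ambiguous
— mean path speed and mean instantaneous speed differ when frames are
missing — so the mean instantaneous speed (step length over actual Δt)
is reported alongside.  Tracks are 2-D; a z column is used in distances
when present.  Frame gaps are tolerated.  All statistics are invariant
under translation and rotation, and straightness is non-decreasing
under temporal subsampling (removing intermediate points can only
shorten the accumulated path).

Transwell migration efficiency is 100 · migrated/input per replicate,
reported as the replicate mean with its standard error; trypan-blue
(viable, dead) pairs pool into a viable fraction.  A migrated count
exceeding the input is rejected as a miscount.

## Co-culture clusters

A cluster ("rosette") is a connected component of the union of the two
thresholded channels (Otsu per channel) that contains both tumor (green,
CFSE-like) and T-cell (red) foreground within an adjacency distance
(default 2 µm) and exceeds a minimum area — by default the footprint of
three 10-µm cell profiles, since a meaningful aggregate involves several
cells.  The dual-population rule is symmetric, so swapping channels
changes nothing.  Areas are exact pixel counts times pixel area.
Condition summaries report the mean cluster area with the SEM over
clusters pooled across a condition's images.

## Statistical test selection

Every condition-level comparison runs through one gate: Shapiro-Wilk on
each group at `gate_alpha` (default 0.05; all groups must pass).  Two
normal groups → paired/unpaired t-test; any non-normal → Mann-Whitney U.
More than two groups → one-way ANOVA with Bonferroni-adjusted pairwise
t-tests (adjusted p = min(1, m·p)), else Kruskal-Wallis.  Groups smaller
than 3 skip the gate and force the nonparametric branch, flagged in the
recorded decision path.  The underlying tests are scipy's; the content
here is the gate itself and its validation: under Gaussian nulls the
gated procedure's empirical type-I error is within the binomial band
around α (measured at 2000 replicates), and the family-wise error of
the Bonferroni branch stays at or below α.

## Synthetic data: what it emulates and what it does not

The generator renders, in physical coordinates sampled onto the
(anisotropic) voxel grid:

* ellipsoidal cell bodies (default radii ≈ 5–6.5 µm, matching ~10–13 µm
  lymphoma cells) with capsule-shaped filopodia (cylinder +
  hemispherical cap, default radius 0.4 µm — thin enough to read as a
  skeleton, thick enough to survive voxelization at a 0.3 µm
  z-interval) attached at controlled surface positions, deviation
  angles and lengths;
* spherical fragments with diameters in (0, 10) µm, the population the
  fragment filter must remove;
* constant background (default 5 a.u. against cell intensity 100) plus
  Gaussian read noise (default studies use SD 2, i.e. SNR ≈ 50 for the
  body and ≈ 20 for the DoG tube response) and optional Poisson shot
  noise;
* persistent random walks for tracks: fixed step length speed·dt (so
  the ensemble mean speed is controlled exactly), headings evolving by
  wrapped-Gaussian turns with E[cos Δθ] equal to the persistence
  parameter (1 → straight lines, 0 → uniform redraw);
* two-channel cluster images: a tumor disk core (radius 7.5 µm) ringed
  by touching T-cell disks (radius 3.5 µm), with dispersed single cells
  placed by rejection sampling at guaranteed gaps.

Fixed spec + seed gives bit-identical output, and every rendered
object's recorded size is voxel/pixel-counted, so downstream size
measurements can be checked exactly.

Deliberately **not** modeled: optical blur (a single optional Gaussian,
not a PSF), depth-dependent attenuation, collagen-fiber background,
filopodium curvature and dynamics, intensity heterogeneity within a
cell, and segmentation-relevant cell crowding beyond pairwise contact.
Passing the validation suite therefore shows the measurement chain is
correct on geometrically faithful, modestly noisy data; it does not
show robustness to uncorrected optics or dense tissue-like clutter.

## Validation studies and problem sizes

The package ships condition-level recovery studies
(`filotrack.studies`) used by the test suite and by
`scripts/acceptance.py`:

* geometry oracles: three oriented tubes (8 µm) for geodesic length,
  rendered single-filopodium cells at 0° and 30°;
* four filopodia conditions (two "cHL-like": angle median 38°, count
  mean 6, length 6 µm; two "ALCL-like": 50°, 3, 3 µm) × 40 cells each,
  mirroring the 36–56 cells per cell line a spinning-disc experiment
  yields; each cell rendered in its own compact stack;
* 20 random two-cell + fragment stacks for the conservation suite;
* 200 tracks × 500 frames per speed condition;
* 2000 null replicates for the type-I-error measurement.

These sizes keep the whole suite in the minutes range on a single CPU
while leaving Monte-Carlo error well inside the tolerances being
checked.

## Known limitations

* The polarity rule and the cluster minimum-area rule are this
  package's operationalizations; absolute polarized fractions and
  cluster counts shift with their thresholds (orderings between
  conditions are stable in the studied regimes).
* Near-tangential filopodia angles are biased low (see above).
* Filopodia shorter than ~2 µm or closer together than ~2 µm can merge
  or vanish at the default DoG scales.
* The iterative global threshold assumes cells of roughly comparable
  intensity within a factor of a few; a cell dimmer than the accepted
  foreground fraction allows will still be missed.
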