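# Methods

This note records how `leafmosaic` computes what it computes: the raster
model, the metric definitions, the reconstructed algorithms where only
the desired behaviour (not a formula) was fixed, the numerical choices,
what the synthetic generator does and does not emulate, and the known
accuracy limits.

## Input model

A tracing is a single-channel 8-bit raster in which walls, each cell
class (pavement, stomate, subsidiary, arbitrary extras) and an optional
NA mask each carry one value. Pixel (r, c) owns the half-open square
[c, c+1) × [r, r+1); origin is the top-left corner, y runs down. All
angles are axial (θ ≡ θ + 180°) and reported in degrees. If no scale is
supplied, every scale-dependent quantity is in pixels (a warning is
logged once per image). Anti-aliased tracings are rejected rather than
snapped: an intermediate grey value is more often a tracing error than a
legitimate class, and silent snapping would hide it.

## From raster to mosaic

* **Connectivity.** Cell interiors are 4-connected, walls 8-connected,
  so a one-pixel 8-connected wall always separates two cells and corner
  leaks are impossible. Regions below `min_region_px` (default 4) are
  dropped with a warning.
* **Vectorization.** Each region's pixel-boundary polygon is traced by
  chaining the exposed pixel edges (holes become interior rings); the
  coordinates are multiplied by the scale.
* **Adjacency.** Two cells are neighbours iff at least `m` wall pixels
  (default 3) see both in their 8-neighbourhood. The default rejects
  single-corner contacts; the threshold is a config knob because
  "sharing a wall" has no canonical pixel-level definition.
  While counting, each wall pixel's area is split equally among the
  regions it touches; `CellPolygon.area_with_walls` adds that share to
  the interior area, so interiors + walls tile the image exactly. The
  plain `area` deliberately excludes the shared wall (the consistent
  under-estimate cancels in ratios).
* **Junctions.** Junction pixels are wall pixels whose 8-neighbourhood
  touches ≥ 3 regions, or ≥ 2 regions plus the image border or NA mask.
  At shallow wall angles (common in Voronoi-like tissue) the third
  cell's interior can lie 2 px from every wall pixel of a genuine
  meeting, so a 5×5-window test backs the rule up; wide-window clusters
  are accepted only ≥ 4 px away from every strict cluster, otherwise
  undulating walls grazing a neighbour would smear real junctions.
  8-connected junction pixels are clustered and replaced by their
  centroid (ties broken by lowest row, then column). A cell with < 3
  junctions is flagged unsimplifiable and excluded from undulation
  metrics.
* **Smoothing.** Each outline is densified to ~1-px vertex spacing,
  passed through an anchored circular moving average (window 5 px, 2
  passes), then Chaikin corner cutting (default 3 iterations), with the
  junction-anchored vertices held fixed throughout. The moving-average
  pre-pass exists because corner cutting alone cannot remove the
  ±half-pixel staircase of rasterized boundaries: without it, perfectly
  straight diagonal walls read `complexity` ≈ 1.09; with it ≤ 1.007.
  Straight axis-aligned walls are exact. If smoothing ever produced a
  self-intersection the raw outline is used with a warning.
* **Simplified cell.** The polygon through a cell's junctions in
  boundary order — the cell's shape if every shared wall were straight.

## Trait definitions

* `complexity` = smoothed perimeter / simplified perimeter. The ratio is
  oriented so that larger = more undulated (≥ 1); users of the
  reciprocal convention can invert it.
* `undulation_amp` = max over walls of the maximum distance from the
  smoothed wall arc to its baseline segment (the straight simplified
  edge between consecutive junctions). Distances are to the segment, so
  lobes beyond the ends measure to the nearest endpoint; lobes that
  double back are therefore measured conservatively.
* `undulation_freq` = total wall/baseline crossings divided by the
  simplified perimeter — a crossing rate per unit baseline, which keeps
  the metric dimensionally a 1/length (divide-by-s under scaling). With
  a micrometre scale, multiply by 1000 for a per-mm rate. Crossings are
  sign changes of the perpendicular offset sampled at every wall vertex
  plus midpoints (≥ 64 samples per wall); tangency does not count. On
  rasterized outlines a half-pixel dead band suppresses residual
  staircase noise; vector-level uses a near-zero tolerance.
* Gross shape (aspect ratio, orientation, endwall angles) comes from the
  *simplified* outline: a direct least-squares ellipse fit (the
  conic-constrained 4AC − B² = 1 problem, solved in the numerically
  stable block-decomposed form) on the outline resampled to 64 points
  uniform in arc length. Endwalls are the two simplified edges whose
  midpoints lie furthest apart along the fitted major axis; the
  reported angle is the mean acute angle between those edges and the
  axis. This construction is one reasonable reading of "endwall angle";
  it is exact for rectangles (90°).
* Stomatal length/width are extents of the guard outline(s) projected
  on the fitted major/minor axes — from the cells directly, not the
  fitted ellipse's own axis lengths, which systematically shrink on
  non-elliptical guards. In paired-guard mode the complex angle is that
  of the dividing wall (principal axis of the wall pixels both guards
  touch) and `symmetry` = smaller/larger guard area.
* Stomatal north = axial mean (angle-doubling method) of the per-complex
  angles; a resultant length below 1e-9 flags an isotropic arrangement
  and per-cell angles stay absolute. An override short-circuits the
  estimate when the leaf axis is known.
* Stomatal index = 100·S/(S+E) counting interior cells plus cells
  clipped by the top or left image border only — the unbiased counting
  frame. Subsidiary and extra-class cells count in E (a flag restricts
  to pavement only). Cells clipped by the NA mask are treated like
  bottom/right-clipped cells (not counted): an NA boundary has no
  orientation, so the unbiased-frame argument cannot be applied to it.
* Per-image aggregation: median for sizes/shapes/undulation (robust to
  tracing errors), axial mean for angles. Densities are whole
  (unclipped) complexes/cells per measured (non-NA) area, per mm² when
  the scale units are um or mm.

## Arrangement

* **Zones**: pavement cells abutting a complex are `polar` if their
  centroid lies within ±45° (config) of the complex's major axis seen
  from the complex centroid, else `stomatal`; everything else is
  `pavezone`. Cells abutting several complexes are classified against
  the nearest.
* **Cells between stomata**: BFS on the adjacency graph with each
  complex contracted to one source; the path length counts intervening
  non-complex cells (0 when complexes share a wall). Subsidiaries of a
  terminal complex are not intervening.
* **Rows**: complex centroids are rotated so north runs along +x and the
  across-row coordinates single-linkage clustered, cutting at 1.5 × the
  median stomatal width. The result carries a low-confidence flag when
  the row count changes under a ±20% perturbed cut (isotropic fields).
* **Row metrics** (reconstructions — the behaviour, not the formulas,
  was fixed in advance): per row, a total-least-squares line through the
  centroids; `row_wiggliness` = RMS perpendicular residual ÷ mean
  along-row gap, averaged over rows with ≥ 3 stomata — dimensionless,
  invariant under uniform scaling, and ≈ σ/d for Gaussian jitter σ on
  spacing d (within 2% at 50 stomata/row; the n-point TLS fit biases it
  low by √((n−2)/n)); `row_spacing` = mean offset between adjacent rows'
  fitted lines; `row_consistency` = n_observed / (1 + extent / median
  gap), capped at 1 — exactly 1 for continuous evenly spaced rows and
  lower for gappy rows.

## Sampling workflows

Patches grow from a random non-edge cell by whole neighbour rings (so
the final size may overshoot the target); any touched stomatal complex
is completed; edge cells and members of edge-clipped complexes are
excluded from the start. Randomness: one root seed, with a
counter-derived substream per (image, size, replicate) so any single
patch is reproducible alone. Patch traits re-aggregate the whole-image
per-cell tables restricted to members; stomatal north is reused from the
whole image (small patches may lack stomata); patch densities use the
summed member `area` as denominator.

Convergence: per trait and size, the SD of (patch − whole-image) deltas,
z-standardised with the across-image mean/SD of the whole-image dataset;
with a single image that scaling is undefined and raw deltas are used
(warned). The minimum recommended cell count is the smallest size whose
SD drops below the threshold (default 0.1); sizes with < 3 replicates
are flagged unstable and never-converging traits report "not reached".
Scaling with a single image requires user-supplied constants by design.

Reliability: traits are z-transformed on the whole table; the score is
the mean over plants (with ≥ 2 images) of the within-plant SD of the
z-scores. Score 0.2 ⇒ within-plant variation is 20% of the dataset
variation; score 1 ⇒ equal. The default threshold 0.2 drops anything
above. With k images per plant the plain SD biases the score low by the
usual c₄(k) factor (≈ 0.92 at k = 4); no correction is applied, matching
the plain-SD definition.

## Synthetic data

`simulate_cell` builds rectangles, 8-gon ellipse approximations and
non-convex "dart" crescents at aspect ratios 1–10, with each wall
displaced normally by a sine of p full periods tapered by sin²(πt), so
displacement *and slope* vanish at the junctions (a raw sine's nonzero
junction slope makes adjacent walls of sharp or reflex corners cross).
Ground truth is exact: amplitude is the tapered profile's numerical
peak, crossings are the sine's interior zeros (2p − 1 per wall),
complexity comes from 4096-point quadrature of the arc length. The
default factorial grid (3 shapes × 5 aspect ratios × 4 amplitudes × 4
period counts × 5 sign-jittered replicates) yields 1200 cells.

`simulate_mosaic` builds brick (running bond, T-points as true
junctions), hexagonal, and Lloyd-relaxed Voronoi tessellations;
tessellation edges shorter than 0.25 × cell size are collapsed, because
sub-resolution edges cannot be recovered from any raster and would make
"exact" junction recovery ill-posed. Shared walls can be undulated (both
cells traverse the same polyline) and stomatal complexes are carved into
designated rows: an inscribed ellipse (guard) flanked by two subsidiary
half-cells, with optional Gaussian across-row jitter of the centre.
Stomata whose flanking cells would be thinner than ~2 px are skipped
with a warning. Mosaic-level ground truth (per-cell undulation metrics,
adjacency at the ≥ 3 px shared-boundary threshold, junction counts from
shared tessellation vertices, row assignments, north = 0°) is recorded
at the polygon level. `rasterize_mosaic` assigns each pixel centre to
its polygon, draws walls of the requested width along label boundaries,
absorbs sub-4-px fragments pinched off at junction wedges into the wall,
and errors if any cell fails to survive as one region.

What the generator does **not** emulate: curved leaf surfaces, size
gradients, tracing errors (broken or doubled walls), papillae or other
cuticular noise, hypoplastic stomata, and biological lobe morphogenesis
(lobes never double back outside the simplified cell). Passing tests
therefore validate the measurement pipeline on clean tracings, not
robustness to segmentation error.

## Measured accuracy and limits

On rasterized ground truth (1-px walls): cell count, adjacency and
junction counts are recovered *exactly* on brick, hexagonal and Voronoi
tessellations (6×6 cells, 24–32 px/cell, multiple seeds);
`area_with_walls` is within 2% of polygon truth at 32-px cells (worst
cell ≤ 1.6% over 18 grid/seed combinations; error scales as 1/diameter,
up to ~3% at 24-px Voronoi cells). Median complexity is recovered within
2% and the crossing rate within 10% at 56-px cells. Amplitude is the
method's weak point: junction localization error (median ~0.7 px) plus
boundary quantization (~0.5 px) enter the max-over-walls statistic
additively, an absolute +≈1 px bias at any resolution — per-wall median
amplitude is within ~2%, but per-cell amplitude of a 2-px undulation
reads ~+35%. Small absolute amplitudes should be interpreted with that
floor in mind; complexity is the more robust undulation measure on
coarse rasters, consistent with its role as the headline metric.

Problem sizes used by the test suite and `scripts/acceptance.py` (chosen
as the smallest that make each property cleanly measurable): 210
straight-walled cells for the baseline check; 100 random ellipses; 6×6
tessellations for round trips; 1000 patch draws at target 15 on an ~80
cell mosaic; the convergence study on a ~570-cell Voronoi epidermis with
four stomatal rows at sizes {50, 100, 200, 400} × 25 replicates; and
1000 plants × 4 replicates for reliability recovery.
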