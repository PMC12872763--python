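# Methods

## Coordinate and mask conventions

All modules share one frame: x rightward, y downward, 0-based, coordinates
refer to pixel centers.  Masks are boolean arrays; foreground connectivity
is 8-connected throughout (component labeling, border following, skeleton
adjacency).  Before measurement a mask is reduced to its largest
8-connected component; size ties go to the component whose bounding-box
corner is smallest in row-major order, so the choice is deterministic.

The *length axis* of an object is the longer side of its axis-aligned
bounding box.  Objects are assumed to be laid roughly flat at acquisition;
no principal-axis rotation is applied, and bounding-box extents use the
inclusive pixel-count convention (max − min + 1).

## Contour, area, perimeter

The outer boundary is traced through pixel centers by Moore-neighbour
border following with Jacob's stopping criterion, starting at the first
foreground pixel in raster order.  The traced polygon is oriented to
positive shoelace area; `contour_area_perimeter` reports the raw shoelace
area and closed edge sum of that polygon (a 3×3 blob gives exactly
area 4 px², perimeter 8 px).

These polygon quantities are biased measures of the underlying *region*:
the pixel-center polygon under-counts region area by roughly half the
perimeter, and the 8-connected staircase over-counts the length of smooth
curved boundaries by several percent.  `measure_region` therefore reports
the region area as the foreground pixel count (unbiased to first order
under the pixel-center rasterization rule) and the boundary length as the
edge sum of the Douglas–Peucker-simplified contour (tolerance 1.2 px) plus
the offset term 2π·(1/2) px, since the pixel-center polygon runs half a
pixel inside the region boundary and offsetting a simple closed curve
outward by r lengthens it by 2πr.  The feature-extraction pipeline uses
`measure_region`; on the synthetic fixtures both area and perimeter land
within ~1% of the generating formulas, where the raw polygon numbers would
be 3–6% off.

## Thickness profile

Four stations at fractions 1/5, 2/5, 3/5, 4/5 of the length axis (interior
stations avoid degenerate end sections and yield exactly four well-defined
chords).  At each station the default chord is measured **perpendicular to
the local midline**: the midline slope is estimated by least squares over
column midpoints in a one-sided window facing the object's interior
(columns toward the ends can cross the end face and would corrupt the
fit), and the chord is the extent of the contiguous run of foreground
pixel centers along the normal ray.  For straight, axis-aligned objects
this equals the plain bounding-box cross-section, which remains available
as `method="section"`; for curved objects the section chord inflates by
1/cos of the local tilt (up to ~16 px on the steepest test band), which is
why the perpendicular chord is the default — it recovers 2t within 2 px on
every curved-band fixture.

## Skeleton main branch and curvature

The skeleton comes from Zhang–Suen-style iterative thinning
(`skimage.morphology.skeletonize`).  The main branch is the
maximum-geodesic-length path between two skeleton endpoints over the
8-adjacency graph with edge weights 1 and √2.  Exact geodesic ties occur
on symmetric shapes; they are broken first by the larger Euclidean
endpoint separation (so the branch spans the object) and then
lexicographically by (y, x).

Curvature is κ = 1/R of the circle through the branch's two endpoints and
its geodesic midpoint, constructed by perpendicular-bisector intersection;
collinear triples (triangle area < 1e-9) give κ = 0.  Applied literally to
the raster skeleton this is fragile, because thinning a blunt-ended band
grows diagonal spurs toward the end corners and quantizes every vertex to
the grid.  The estimator therefore:

1. **trims end spurs** — the path is cut to the longest contiguous run of
   vertices whose Euclidean-distance-transform value stays within
   ~1.5 px of the path's 98th-percentile value (medial vertices sit at the
   local half-width; spur vertices fall toward 1 px), never removing more
   than a third of the path per side;
2. **refines subpixel** — each of the three defining points is estimated
   as the mean of perpendicular cross-section midpoints over a window of
   path vertices (window = len/4, capped at 25; end anchors inset by half
   a window), with sections whose chord is noticeably shorter than the
   window's typical chord rejected, since near a blunt end the
   perpendicular chord clips the end face and would bias the midpoint.

The windowed mean's small radially-inward bias is common to all three
anchors and cancels in the fitted radius to first order.  On the fixture
grid the estimator recovers 1/R within 5% (mostly within 1–2%) for every
band whose medial axis actually traces the generating arc.  Two extreme
geometries — half-thickness 50 px with arc π/6 at radii 200 and 300 px —
violate that premise: there asin(t/R) approaches θ/2, the band is about as
thick as it is long, its true medial arc spans only a few pixels, and no
skeleton-derived three-point (or even all-point least-squares) circle
recovers the generating radius.  Curvature for such blob-like masks is
reported but not meaningful; real stipes, with length-to-thickness ratios
well above 3, are far from this regime.

Curvature is reported per mm (κ_px / c).  The physical unit of a curvature
"mean" in summary tables is ambiguous in parts of the field literature;
this package always states mm⁻¹.

## Centerline quintuplet

Interior keypoints at fractions 1/4, 1/2, 3/4 of the length-axis span are
the (min+max)/2 midpoints of their cross-section column.  Endpoints are
found by following the midline outward until it leaves the foreground: the
midline is a circle fitted algebraically (Kåsa) to column midpoints over
the central 60% of the span, falling back to a least-squares line when the
midpoints are straight to within 0.5 px (fitting many columns keeps the
extrapolation to the ends stable where a three-point fit would not).  For
a straight object this reproduces exactly the extreme foreground pixel of
the length axis with the median perpendicular coordinate; for a curved
band it lands on the midpoint of the end cap, i.e. on the generating arc.
The centerline length is the 4-segment polyline through the five points —
deliberately not a denser midline integration, to stay faithful to the
five-point annotation a human would place.  A five-point polyline on a
circular arc under-measures the arc by sin(θ/8)/(θ/8); at θ = π/2 that is
0.6%, well inside the 2% validation band.

## Calibration

The conversion coefficient is a through-origin least-squares fit,
c = Σ mm·px / Σ px², since a scale bar imaged at fixed distance maps 0 px
to 0 mm and an affine intercept would only absorb noise.  The shipped
default, 0.042 mm/px, describes the reference acquisition rig; every mm
output is recomputable under any user-supplied c (lengths ×c, areas ×c²,
per-pixel curvatures ÷c).  Reference-object verification reports the
signed error as true − measured.

## Grading, split, metrics

Grade bounds are inclusive upper bounds; values between two printed bounds
(e.g. 11.563) fall into the higher grade, preserving the printed boundary
values as exact grade maxima.  The 7:2:1 split uses floor for train,
round-half-up for test and the remainder for validation — the unique
simple rounding rule that partitions 985 into (689, 197, 99).  Summary
statistics use the sample (m−1) standard deviation.  R² denominators of
constant truth vectors raise an explicit error rather than returning NaN.

## Synthetic fixtures: what they do and do not show

A pixel is foreground iff its center satisfies the analytic inequality,
which makes the rasterized area unbiased to first order and every truth
value exact by construction.  The fixtures emulate the geometry of imaged
stipes (elongated, curved, roughly constant thickness, uniform background)
and, via seeded radial edge fuzz, the fluffy boundary of real specimens.
They do not emulate texture, shading, specular glare, background
non-uniformity or segmentation errors, so passing the recovery suite
demonstrates correctness of the measurement geometry, not robustness of
any upstream segmenter.  The chroma-key segmenter is a desk-scale
stand-in with a single dominance-margin parameter (default 30 intensity
units) and hole filling; it is not a substitute for the learned
segmentation stage of a production pipeline, which plugs in through the
mask-provider contract.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `mm_per_px` | 0.042 | reference-rig conversion coefficient |
| grading bounds | 11.56, 27.69, 43.83, 59.96 mm | inclusive upper bounds of the first four grades |
| split ratios | 0.7 / 0.2 / 0.1 | train / test / validation |
| chroma margin | 30 | background-channel dominance (8-bit units) |
| gray weights | 0.299, 0.587, 0.114 | BT.601 luminance |
| mask threshold | > 127 | 8-bit mask binarization |
| DP tolerance | 1.2 px | boundary simplification for region perimeter |
| fixture margin | 8 px | background border around synthetic shapes |

## Known limitations

* Measurements are axis-aligned; a stipe imaged at 45° to the image axes
  will report a bounding box (and hence length/width) of its rotated
  extent.  Skeleton, curvature, thickness and area are rotation-robust.
* The spur-trimming criterion assumes roughly constant width along the
  main branch; strongly tapered objects may be trimmed asymmetrically
  (bounded by the one-third-per-side cap).
* Curvature of blob-like masks (length ≲ 2× thickness) is ill-defined by
  the skeleton construction, as discussed above.
* The pose-annotation dialect covers exactly one object per image with
  five always-visible keypoints.
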