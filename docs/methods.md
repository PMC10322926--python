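# Methods

## Figure detection by H1 persistence

A binarized frame is reduced to the outer contour pixels of each
8-connected foreground component (interior holes are filled first, so
speckle holes inside a cell contribute nothing to the cloud). Each
contour is an independent planar point cloud `X`. The alpha complex
on `X` at radius `α` is the subcomplex of the Delaunay triangulation
whose simplices have an empty circumscribing ball of radius ≤ `α`; its
H1 persistence bars `[b, d)` record loops. A filled disk-like figure
of internal radius `r` produces one dominant bar: the loop is born
once the contour gaps close (`b` ≈ half the largest pixel gap, so
≈ 0.5–1 px for dense contours) and dies at `d ≈ r` when the triangle
circumscribed by the largest empty interior circle is inserted. The
circumcenter of that death triangle is the center of that circle —
for three points on a circle, exactly the circle's center — which is
why it is used to plot the detected point. The barycenter of the
death triangle, the historical plotting rule, can sit far from the
center for obtuse triangles; it remains available via
`DetectParams(plot="barycenter")` for comparison.

Overlapping figures share one contour, but each figure still carries
its own loop: the dent points where two boundary circles cross lie at
distance `r` from each center, so each figure's loop dies at its own
internal radius with its circumcenter at its own center. This is what
makes the detector robust to overlap, where erosion-based separation
fails.

### Implementation and exactness

Filtration values follow the standard alpha rules: a triangle enters
at its circumradius; an edge enters at half its length if its
diametral disk contains no opposing Delaunay vertex (Gabriel), and
otherwise at the value of the blocking incident triangle. H1 pairs
are computed by planar duality: connected components of the dual graph
(triangles plus the unbounded face), processed by decreasing
filtration, are in bijection with H1 classes; a union-find sweep over
dual edges emits each bar together with the triangle that kills it.
This is exact (no approximation of Euclidean death radii, unlike a
Rips filtration) and O(n log n) after the Delaunay step. The test
suite checks it against an independent brute-force Čech
boundary-matrix reduction (all pairs/triples ordered by
minimum-enclosing-ball radius) on hundreds of small random clouds —
the two filtrations have identical H1 diagrams because both are
nerves of the same union of balls.

Persistence is computed **per contour**, not on the pooled cloud of
all contours. Pooling adds H1 classes that span the background gaps
*between* well-separated components; their deaths can exceed any
threshold and their circumcenters fall in empty background. Since
overlapping figures already share a contour, per-contour computation
loses nothing the method targets. Deaths and births are reported in
pixel-radius units throughout, so `PH-thres` is literally "the minimum
internal radius of the figures to detect".

Ties (equal deaths) are broken by birth ascending, then lexicographic
death-simplex coordinates; degenerate death triangles (twice the
signed area below 1e-9 × the largest squared side) fall back to the
barycenter and are flagged. Sub-pixel positions are never rounded
until rendering.

## Relation to watershed sure-foreground

Eroding the foreground by distance `t` and counting components equals
drawing a vertical line at `t` through the barcode and counting bars
alive there (`birth ≤ t < death`). Persistence detection counts bars
with `death ≥ t` regardless of birth, which is always at least the
alive count: the barcode contains the erosion information and more.
`sure_foreground_count` implements the erosion view for comparison,
and the packaged four-figure model (`fig4b_model`, radii 16/16/11/7,
overlap depths 12/8/3) is constructed so that the smallest figure
vanishes (at `t = 7`) before the widest necks break (at ≈ 9.3 and
≈ 12.5): no erosion distance shows four components, while death
thresholding at 5 px finds all four.

## Tracking

Selection is deliberately minimal: cell `k`'s point in frame `i` is
the detected point nearest (Euclidean, in original coordinates) to its
frame `i−1` point, seeded by user initial points. It is Markov — each
frame depends only on the previous one — so a manual modification
(swapping one selection for another *detected* candidate) re-runs
selection forward and leaves earlier frames untouched. Selection is
per-cell independent; two cells may select the same point, which is
reported as a collision rather than resolved (an optional greedy
unique-assignment mode exists but is off by default). Ties are broken
toward the larger death (deeper bars are likelier true nuclei), then
the lower candidate index, making tracking bit-deterministic. A frame
with no detections is a hard error naming the frame, never silent
interpolation. Distances are measured after mapping detections back
through the inverse rotation/stretch, i.e. in original image
coordinates; with the transformations used in practice (|rot| ≤ 10°,
mult ≤ 3) the difference from selecting in transformed coordinates is
second-order.

Motion decomposition subtracts the per-frame barycenter (mean of the
N tracked positions) from each trajectory; the relative parts sum to
zero per frame and recompose the input exactly.

## Overcount reduction for single-image counting

Detections are processed from the largest death `d` downward. Each
claims the not-yet-claimed foreground pixels inside the disk of radius
`(1+ε)·d` around it and is kept iff strictly more than `α·π·d²` pixels
were claimed. `ε ≥ 0` absorbs boundary noise (deaths approximate
internal radii, so the inflated disk should cover the figure);
`α ∈ (0,1)` sets how much overlap with already-claimed figures is
accepted; the acceptance denominator is exactly `α·π·d²`, not
inflated by `ε`. "Pixels in the image" are foreground pixels of the
cleaned binary mask — claiming background would make `α` meaningless.
A discarded candidate's claim is rolled back by default
(`rollback_discarded=True`): rejected disks are typically spurious
large-death loops spanning dents or gaps, and letting them shadow
smaller genuine figures processed later would discard those too. The
permanent-erasure reading is available behind the flag. The kept set
shrinks monotonically in `α` and is order-independent under the
death/position tie-break.

## Parameters

| name | meaning | unit | typical |
|---|---|---|---|
| bin-thres | binarization threshold | intensity 0–255 | 150 (model), 35–255 (recordings) |
| polarity | which side of the threshold is foreground | – | dark cells / bright nuclei |
| nbd | cleanup window half-size (side `2·nbd+1`) | px | 5 |
| erase-thres | min white count in the window to survive | count | 0–70 |
| rot | rotation before detection | degrees CCW (x right, y down) | 0, ±5–10 |
| mult | stretch factor along `axis` | – | 1–3 |
| PH-thres | min internal radius of figures to detect | px | 2–20 |
| bd-thres | min contour length | boundary px | 2–50 |
| N, init | number of cells and their initial points | – | per dataset |
| ε | reduction disk inflation | – | 0.2–0.3 |
| α | min novel-coverage fraction | – | 1/3 |

The cleanup window count includes the center pixel, off-image pixels
count as black, and cleanup is a single simultaneous pass (not
iterated, and not a morphological erosion — the rule is a count
threshold). Rotation is about the image center; the angle sign is
counter-clockwise positive in raster (x right, y down) coordinates.
The transformation acts on contour point clouds, not on the raster, so
no interpolation artifacts enter; detections are mapped back with the
exact inverse. Color input is collapsed by BT.601 luma; 16-bit images
are rescaled to [0, 255] by their maximum.

## Synthetic ground truth

`gen_model_series` renders 10-frame series of three dark disks (radius
16 px, intensity 30 on 220) on a 256×256 canvas — the canvas size is a
package choice — with sub-pixel true centers recorded per frame and
per-frame displacements bounded by `step_px` (default 6 < radius, so
nearest-neighbor linking is well-posed). The three regimes script the
approach of no pair / one pair / all three pairs to overlap
mid-sequence and retreat, with seeded jitter; regime constraints and
the displacement bound are verified programmatically on every call. A
pixel is foreground iff its center lies in a disk (no anti-aliasing),
so the binary ground truth is unambiguous.

Noise conditions: Gaussian blur (σ = 1 small, 3 large), "pick" noise
(each pixel flipped to the opposite intensity extreme with probability
0.02), and blur+pick followed by a bounded uniform perturbation
(amplitude 10 on L and C, 10° on h) applied in CIE LCh and converted
back to gray. Pick and LCh noise magnitudes are the package's stated
definitions of otherwise qualitative conditions: they are chosen so
the pipeline degrades measurably but does not fail, and are
overridable. Noise never moves the recorded truth.

`gen_scatter_nuclei` renders mildly elliptical bright nuclei (axis
ratio ≤ 1.2, semi-minor 10–13 px — at least 2 px above the counting
preset's PH-thres, the same digitization margin the disk-recovery
property uses) with rejection-sampled centers at a minimum spacing
that permits moderate overlap. `fig4b_model` is the static
erosion-failure chain described above; its defining properties are
asserted by tests (exhaustive erosion sweep, exact count of 4), not
assumed.

What the generators do **not** emulate: uneven illumination, texture
inside nuclei, out-of-focus halos, cell division/appearance, or shape
change over time. Passing tests therefore demonstrate correctness of
the geometry/topology pipeline and its noise robustness, not
performance on arbitrary real recordings; on real data the documented
presets are starting points and the parameter meanings above are the
tuning guide.

## Problem sizes and numerics

The benchmark in `scripts/acceptance.py` uses ten seeded series per
regime (10 frames × 3 cells each; 300 distances per regime), the
series sizes the ground-truth regime defines; the whole run takes
seconds. Qhull degeneracies (collinear clouds) yield no bars rather
than errors; zero-persistence pairs are dropped with a 1e-12 relative
guard; the death-simplex circumradius equals the reported death to
1e-6 by construction and is asserted in tests.

## Known limitations

- A figure overlap with no boundary dent (one figure nearly inside
  another) yields one loop, not two; no contour-based method can
  separate that from a single figure without temporal context.
- Very non-disk-like or strongly dented cells produce several
  detections per cell; tracking tolerates this via selection, counting
  relies on the reduction step, and results may need `modify_track`.
- Figures touching the image edge lose part of their contour; their
  death underestimates the internal radius and counts near the border
  can be off by one — crop generously.
- `PH-thres` must stay ~2 px below the smallest true internal radius:
  digitized contours sit up to ~1.4 px inside the ideal outline, which
  lowers deaths accordingly.
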