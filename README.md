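# phtrack

Detection and tracking of overlapping disk-like cell nuclei in
microscopy image series, based on persistent homology.

Segmentation-based trackers struggle when nuclei overlap: a single
connected foreground blob hides two or three cells, and erosion-based
tricks (the watershed "sure foreground") fail as soon as a small cell
erodes away before a wide neck between two large cells breaks.
`phtrack` takes a topological route instead. For every binarized
figure it treats the contour pixels as a planar point cloud, computes
the **H1 persistence barcode of the alpha filtration**, and plots the
**circumcenter of each bar's death simplex**. Each disk-like figure —
overlapping or not — contributes one bar whose death radius
approximates the figure's internal radius, and whose death-simplex
circumcenter lies at the figure's center (three points on a circle
determine its center). Tracking then links these detected points
frame to frame by nearest-neighbor selection; single-image counting
removes overcounts with a greedy disk-cover reduction.

## The method in brief

For a contour cloud `X ⊂ R²` and growing radius `α`, the alpha complex
`A(X, α)` filters the Delaunay triangulation of `X`. Its H1 barcode is
a multiset of intervals `[b_i, d_i)`; a filled disk of internal radius
`r` yields one dominant bar with `d_i ≈ r`, killed by a triangle whose
circumscribed circle is the largest empty circle inside the figure.
The pipeline per frame is

1. **binarize** at `bin-thres` (dark or bright foreground),
2. **clean up** white pixels with fewer than `erase-thres` white
   neighbors in their `(2·nbd+1)²` window,
3. optionally **rotate by `rot` and stretch by `mult`** (point-cloud
   affine map, applied so elongated cells become disk-like),
4. extract outer **contours**, drop those shorter than `bd-thres`,
5. compute **H1 persistence** per contour and keep bars with
   `death ≥ PH-thres` (the minimum internal radius of the figures you
   want), plotting death-simplex circumcenters mapped back to original
   image coordinates,
6. **track**: cell `k` in frame `i` takes the detected point nearest
   to its frame `i−1` position (seeded by `init`, `N` cells), or
   **count**: process detections by decreasing death `d`, claim the
   still-unclaimed foreground within radius `(1+ε)·d`, and keep the
   point iff more than `α·π·d²` pixels were claimed.

All parameters have direct geometric meanings, so they can be set from
the image properties rather than by trial and error. The persistence
backend (alpha filtration values and H1 pairing via union-find on the
dual graph) is implemented in the package and is exact for planar
clouds; it is verified in the test suite against an independent
brute-force Čech boundary-matrix reduction.

## Worked example

`examples/detect_overlapping_figures.py` builds a chain of four
overlapping disks (radii 16, 16, 11, 7) on which erosion-based
counting provably fails, then separates them:

```
true figures: 4
best erosion (sure-foreground) count over all distances: 2
persistence detection count after reduction: 4
  detected ( 26.0,  26.0)  death 14.76 px  -> 0.00 px from a true center
  detected ( 46.0,  26.0)  death 14.76 px  -> 0.00 px from a true center
  detected ( 65.0,  26.0)  death  9.85 px  -> 0.00 px from a true center
  detected ( 80.0,  26.0)  death  5.66 px  -> 0.00 px from a true center
```

The death radii (14.8, 14.8, 9.9, 5.7) approximate the internal radii
of the four disks, and every circumcenter lands on a true center. The
smallest disk would be eroded away at distance 7 while the widest neck
only breaks at ≈12.5, so no single erosion distance can show four
components; thresholding bar *deaths* does not have this problem —
counting components after erosion by `t` equals counting bars alive at
`t`, which is never more than the bars with `death ≥ t`.

`examples/track_model_series.py` tracks three radius-16 disk cells
through a 10-frame series in which all three overlap mid-sequence:

```
noiseless three-overlap series: mean error 0.090 +/- 0.070 px (10 frames x 3 cells)
blur_small: mean error 0.257 +/- 0.156 px
blur_large: mean error 0.569 +/- 1.066 px
      pick: mean error 0.580 +/- 0.473 px
blur_pick_lch: mean error 0.475 +/- 0.333 px
```

Mean distances to the true centers stay sub-pixel under every noise
condition. `examples/count_scattered_nuclei.py` and
`examples/motion_decomposition.py` demonstrate single-image counting
(70 and 40 nuclei counted exactly) and the split of tracked motion
into barycenter drift plus rotation about the barycenter.

## Command line

```bash
phtrack synth model --regime three --seed 1 --out frames/
phtrack track frames/ --preset model --init "112,155;100,111;155,111" --out run/
phtrack eval run/track.csv frames/truth.csv
phtrack count image.png --preset bbbc005 --out counts/
```

`--preset` names a documented parameter set (`model`, `mdck1` …
`endothelial2`, `bbbc001`, `bbbc005`); every run writes a
`manifest.json` from which it can be reproduced byte-identically.
Track CSVs store `frame, cell, x, y, provenance, collision_flag` with
x = column, y = row, origin at the top-left pixel.

If a frame yields no detections the tracker stops with an error naming
the frame: first check that binarization did not erase a cell
(`bin-thres`), then lower `PH-thres` / `bd-thres`. A mis-selected
point can be fixed by `modify_track`, which swaps in another *detected*
candidate (never a free-hand coordinate) and re-selects all later
frames.

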