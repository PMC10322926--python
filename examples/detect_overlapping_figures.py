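"""Separate four overlapping disks where erosion-based counting fails.

Builds the packaged four-figure model (chained disks of radii 16, 16,
11, 7), sweeps every erosion distance to show that sure-foreground
counting never sees four components, then runs persistence detection
plus greedy reduction and recovers all four centers.
"""

import numpy as np
from scipy import ndimage
from skimage import measure

from phtrack import PipelineParams, ReduceParams, detect_in_image, reduce_points
from phtrack.synthdata import FIG4B_PH_THRES, fig4b_model

mask, centers = fig4b_model()
dist = ndimage.distance_transform_edt(mask)
components = [
    measure.label(dist >= t, connectivity=2, return_num=True)[1]
    for t in np.arange(0.25, dist.max() + 0.25, 0.25)
]
print(f"true figures: {len(centers)}")
print(f"best erosion (sure-foreground) count over all distances: "
      f"{max(components)}")

img = np.where(mask, 255, 0).astype(np.uint8)
params = PipelineParams.from_values(
    bin_thres=128, nbd=0, erase_thres=0, rot=0, mult=1,
    ph_thres=FIG4B_PH_THRES, bd_thres=20, polarity="bright_foreground",
)
dets, bars, cleaned = detect_in_image(img, params)
kept = reduce_points(dets, cleaned, ReduceParams(epsilon=0.2, alpha=1 / 3))
print(f"persistence detection count after reduction: {len(kept)}")
for k in kept:
    err = min(np.linalg.norm(centers - k.position, axis=1))
    print(f"  detected ({k.x:5.1f}, {k.y:5.1f})  death {k.death:5.2f} px  "
          f"-> {err:.2f} px from a true center")
print("Each death radius approximates the internal radius of one disk; "
      "the smallest disk erodes away (radius 7) before the widest neck "
      "(~12.5 px) would split, which is why no single erosion distance "
      "can count four.")
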