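"""Count scattered fluorescent-style nuclei in single images.

Generates benchmark-style images with 70 and 40 bright elliptical
nuclei (ground-truth centers recorded), detects candidate centers by
H1 persistence, and removes overcounts with the greedy disk-cover
reduction at (epsilon=0.3, alpha=1/3).
"""

import numpy as np

from phtrack import PipelineParams, ReduceParams, detect_in_image, reduce_points
from phtrack.synthdata import gen_scatter_nuclei

params = PipelineParams.from_values(
    bin_thres=50, nbd=5, erase_thres=0, rot=0, mult=1,
    ph_thres=8, bd_thres=30, polarity="bright_foreground",
)

for n in (70, 40):
    img, truth = gen_scatter_nuclei(n, seed=1)
    dets, _bars, mask = detect_in_image(img, params)
    kept = reduce_points(dets, mask, ReduceParams(epsilon=0.3, alpha=1 / 3))
    pos = np.array([k.position for k in kept])
    d = np.linalg.norm(truth[:, None] - pos[None], axis=-1)
    print(f"{n} nuclei rendered -> {len(dets)} raw detections -> "
          f"{len(kept)} after reduction "
          f"(max center error {d.min(axis=1).max():.2f} px)")

print("Raw detections include duplicate loops from boundary dents; a "
      "candidate is kept only if its inflated disk claims more than "
      "alpha*pi*d^2 not-yet-claimed foreground pixels, which leaves "
      "exactly one point per nucleus.")
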