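"""Decompose tracked motion into barycenter drift and rotation about it.

Two cells orbiting a drifting midpoint look like two wavy trajectories;
subtracting the per-frame barycenter exposes the rotation cleanly.
"""

import numpy as np

from phtrack import PipelineParams, TrackParams
from phtrack.synthdata import render_disks
from phtrack.trackcore import decompose_motion, track_sequence

n_frames, radius, orbit = 12, 14, 26
theta = np.linspace(0, np.pi, n_frames)
drift = np.linspace(0, 18, n_frames)
truth = np.empty((n_frames, 2, 2))
truth[:, 0, 0] = 110 + drift + orbit * np.cos(theta)
truth[:, 0, 1] = 128 + orbit * np.sin(theta)
truth[:, 1, 0] = 110 + drift - orbit * np.cos(theta)
truth[:, 1, 1] = 128 - orbit * np.sin(theta)
frames = [render_disks(truth[i], radius) for i in range(n_frames)]

pipeline = PipelineParams.from_values(150, 5, 0, 0, 1, 10, 40)
track = track_sequence(frames, pipeline,
                       TrackParams(n_cells=2, init=truth[0]))
bary, rel = decompose_motion(track)

print("frame   barycenter (x, y)    |relative| cell0  cell1")
for i in range(0, n_frames, 3):
    r = np.linalg.norm(rel[i], axis=1)
    print(f"{i:5d}   ({bary[i, 0]:6.2f}, {bary[i, 1]:6.2f})"
          f"      {r[0]:6.2f} {r[1]:7.2f}")

total = np.ptp(bary[:, 0])
print(f"\nbarycenter drifts {total:.1f} px in x while each cell stays "
      f"~{np.linalg.norm(rel, axis=-1).mean():.1f} px from it: the "
      "rotation is visible only after removing the common drift, and "
      "barycenter + relative recomposes the tracked positions exactly "
      f"(max residual {np.abs(bary[:, None] + rel - track.positions).max():.1e}).")
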