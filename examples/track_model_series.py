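"""Track three overlapping disk cells through a ground-truth series.

Generates a 10-frame model series in the hardest regime (all three
cells overlap at mid-sequence), tracks with the documented model
parameter set, and measures the distance to the true centers, with and
without noise.
"""

from phtrack import NoiseSpec, PipelineParams, TrackParams, add_noise
from phtrack.synthdata import gen_model_series
from phtrack.trackcore import evaluate, track_sequence

pipeline = PipelineParams.from_values(
    bin_thres=150, nbd=5, erase_thres=0, rot=0, mult=1,
    ph_thres=14, bd_thres=50,
)
pick_pipeline = PipelineParams.from_values(150, 5, 60, 0, 1, 13, 50)
lch_pipeline = PipelineParams.from_values(150, 5, 60, 0, 1, 12, 50)

series = gen_model_series("three", n_frames=10, n_cells=3, radius=16,
                          step_px=6.0, seed=1)
params = TrackParams(n_cells=3, init=series.truth[0])

track = track_sequence(series.frames, pipeline, params)
res = evaluate(track, series.truth)
print(f"noiseless three-overlap series: "
      f"mean error {res.mean:.3f} +/- {res.std:.3f} px "
      f"({track.n_frames} frames x {track.n_cells} cells)")

for kind, p in [("blur_small", pipeline), ("blur_large", pipeline),
                ("pick", pick_pipeline), ("blur_pick_lch", lch_pipeline)]:
    noisy = add_noise(series, NoiseSpec(kind, seed=1))
    res = evaluate(track_sequence(noisy.frames, p, params), series.truth)
    print(f"{kind:>10}: mean error {res.mean:.3f} +/- {res.std:.3f} px")

print("Errors stay sub-pixel: each cell's loop dies at its internal "
      "radius (~16 px) and the death-simplex circumcenter lands on the "
      "cell center even while the three contours are merged.")
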