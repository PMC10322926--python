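"""Frame-to-frame tracking of N labeled cells over detected points.

Linking is deliberately simple and transparent: the point selected for
cell k in frame i is the detected point nearest (Euclidean, in original
image coordinates) to cell k's selected point in frame i-1, seeded by
user-supplied initial positions.  Selection is per-cell independent, so
two cells may select the same point; such collisions are recorded rather
than resolved.  A manual modification replaces one selection by another
*detected* point (never a free-hand coordinate) and re-runs selection
forward, since each frame's selection depends only on the previous one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phdetect import DetectedPoint, PipelineParams, detect_in_image

__all__ = [
    "TrackParams",
    "Track",
    "EvalResult",
    "TrackingError",
    "select_points",
    "track_sequence",
    "modify_track",
    "decompose_motion",
    "evaluate",
]


class TrackingError(RuntimeError):
    """Raised when a frame yields no usable detections."""


@dataclass(frozen=True)
class TrackParams:
    """Number of cells, their initial positions, and the frame stride."""

    n_cells: int
    init: np.ndarray  # (n_cells, 2) initial (x, y) positions
    frame_stride: int = 1
    unique_assignment: bool = False

    def __post_init__(self) -> None:
        init = np.atleast_2d(np.asarray(self.init, dtype=float))
        object.__setattr__(self, "init", init)
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if init.shape != (self.n_cells, 2):
            raise ValueError(
                f"init must be ({self.n_cells}, 2), got {init.shape}"
            )
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")


@dataclass
class Track:
    """Tracking result: selected positions, provenance, and the per-frame
    candidate lists kept for later modification."""

    positions: np.ndarray  # (frames, n_cells, 2)
    provenance: np.ndarray  # (frames, n_cells) of {"auto", "modified"}
    candidates: list[list[DetectedPoint]]
    selected_index: np.ndarray  # (frames, n_cells) candidate indices
    collisions: list[tuple[int, int, int]] = field(default_factory=list)
    # (frame, cell_a, cell_b) pairs that selected the same candidate

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_cells(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class EvalResult:
    """Distances between tracked points and ground-truth centers."""

    per_cell_distances: np.ndarray  # (frames, n_cells)
    mean: float
    std: float


def select_points(
    prev: np.ndarray,
    detected: list[DetectedPoint],
    unique_assignment: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """For each previous position, pick the nearest detected point.

    Each cell minimizes its own distance independently; ties go to the
    candidate with the larger death, then the lower index.  Returns
    (positions (n, 2), candidate indices (n,)).  With
    ``unique_assignment`` cells are instead assigned greedily in order of
    increasing distance so no candidate is used twice (requires at least
    as many candidates as cells).
    """
    if not detected:
        raise TrackingError("no detected points to select from")
    prev = np.atleast_2d(np.asarray(prev, dtype=float))
    cand = np.array([d.position for d in detected])
    deaths = np.array([d.death for d in detected])
    dist = np.linalg.norm(prev[:, None, :] - cand[None, :, :], axis=-1)
    n, m = dist.shape
    if unique_assignment:
        if m < n:
            raise TrackingError(
                f"unique assignment needs >= {n} candidates, got {m}"
            )
        chosen = np.full(n, -1, dtype=int)
        order = [
            (dist[k, j], -deaths[j], j, k) for k in range(n) for j in range(m)
        ]
        used: set[int] = set()
        for _d, _nd, j, k in sorted(order):
            if chosen[k] == -1 and j not in used:
                chosen[k] = j
                used.add(j)
    else:
        # lexicographic minimum over (distance, -death, index)
        chosen = np.empty(n, dtype=int)
        for k in range(n):
            keys = list(zip(dist[k], -deaths, range(m)))
            chosen[k] = min(keys)[2]
    return cand[chosen].copy(), chosen


def _collisions_at(frame: int, chosen: np.ndarray) -> list[tuple[int, int, int]]:
    out = []
    for a in range(len(chosen)):
        for b in range(a + 1, len(chosen)):
            if chosen[a] == chosen[b]:
                out.append((frame, a, b))
    return out


def track_sequence(
    frames: list[np.ndarray],
    pipeline: PipelineParams,
    params: TrackParams,
) -> Track:
    """Track ``n_cells`` cells through a gray-image sequence.

    Frames are subsampled by ``frame_stride`` first.  Frame 0 selections
    are the detections nearest the initial points; every later frame is
    selected from the previous frame's selections.  A frame with no
    detections is a hard error (no interpolation): the message suggests
    lowering bin-thres first, then PH-thres / bd-thres.
    """
    frames = list(frames)[:: params.frame_stride]
    if not frames:
        raise TrackingError("no frames to track")
    n_f, n_c = len(frames), params.n_cells
    positions = np.empty((n_f, n_c, 2))
    selected = np.empty((n_f, n_c), dtype=int)
    provenance = np.full((n_f, n_c), "auto", dtype=object)
    candidates: list[list[DetectedPoint]] = []
    collisions: list[tuple[int, int, int]] = []
    prev = params.init
    for i, frame in enumerate(frames):
        dets, _bars, _mask = detect_in_image(frame, pipeline)
        if not dets:
            raise TrackingError(
                f"frame {i}: no points detected; check that binarization "
                "(bin-thres) keeps every cell, then lower PH-thres / bd-thres"
            )
        candidates.append(dets)
        pos, chosen = select_points(prev, dets, params.unique_assignment)
        positions[i], selected[i] = pos, chosen
        collisions.extend(_collisions_at(i, chosen))
        prev = pos
    return Track(positions, provenance, candidates, selected, collisions)


def modify_track(
    track: Track, frame: int, cell: int, candidate_index: int,
    unique_assignment: bool = False,
) -> Track:
    """Replace one selection by another detected candidate and re-select
    all later frames forward from the change.

    Frames before ``frame`` are untouched; the modified cell's provenance
    is recorded.  The replacement must be an index into that frame's
    candidate list.
    """
    cands = track.candidates[frame]
    if not 0 <= candidate_index < len(cands):
        available = ", ".join(
            f"{i}: ({d.x:.1f}, {d.y:.1f}) death={d.death:.2f}"
            for i, d in enumerate(cands)
        )
        raise IndexError(
            f"candidate {candidate_index} not in frame {frame}; "
            f"available: [{available}]"
        )
    positions = track.positions.copy()
    selected = track.selected_index.copy()
    provenance = track.provenance.copy()
    positions[frame, cell] = cands[candidate_index].position
    selected[frame, cell] = candidate_index
    provenance[frame, cell] = "modified"
    collisions = [c for c in track.collisions if c[0] < frame]
    collisions.extend(_collisions_at(frame, selected[frame]))
    prev = positions[frame]
    for i in range(frame + 1, track.n_frames):
        pos, chosen = select_points(prev, track.candidates[i], unique_assignment)
        positions[i], selected[i] = pos, chosen
        provenance[i] = "auto"
        collisions.extend(_collisions_at(i, chosen))
        prev = pos
    return Track(positions, provenance, track.candidates, selected, collisions)


def decompose_motion(track_or_positions) -> tuple[np.ndarray, np.ndarray]:
    """Split motion into the barycenter trajectory and per-cell motion
    relative to it.

    Returns (barycenter (frames, 2), relative (frames, n_cells, 2)) with
    ``barycenter[i] + relative[i, k] == positions[i, k]`` exactly and the
    relative positions summing to zero in every frame.
    """
    pos = (
        track_or_positions.positions
        if isinstance(track_or_positions, Track)
        else np.asarray(track_or_positions, dtype=float)
    )
    bary = pos.mean(axis=1)
    rel = pos - bary[:, None, :]
    return bary, rel


def evaluate(track: Track, truth: np.ndarray) -> EvalResult:
    """Distance between tracked points and ground-truth centers.

    ``truth`` is (frames, n_cells, 2) with cell correspondence fixed by
    the initial points.  Returns all per-cell per-frame distances with
    their mean and population standard deviation.
    """
    truth = np.asarray(truth, dtype=float)
    if truth.shape != track.positions.shape:
        raise ValueError(
            f"truth shape {truth.shape} != track shape {track.positions.shape}"
        )
    d = np.linalg.norm(track.positions - truth, axis=-1)
    return EvalResult(per_cell_distances=d, mean=float(d.mean()),
                      std=float(d.std()))
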