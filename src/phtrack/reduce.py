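"""Overcount reduction for single-image counting.

Tracking can tolerate overcounts because the selection step picks N
points, but counting figures in a single image cannot.  The reduction
rule is a greedy disk cover over the binarized foreground: candidates
are processed from the largest death radius d downward; each claims the
not-yet-claimed foreground pixels inside the disk of radius (1+eps)*d
around it and is kept only if it claimed strictly more than
alpha * pi * d**2 pixels.  Since deaths approximate internal radii, eps
absorbs boundary noise and alpha sets how much overlap with other
figures is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phdetect import DetectedPoint

__all__ = ["ReduceParams", "reduce_points"]


@dataclass(frozen=True)
class ReduceParams:
    """eps >= 0 inflates the claimed disk; alpha in (0, 1) is the minimum
    fraction of the nominal area pi*d^2 that must be newly claimed."""

    epsilon: float = 0.3
    alpha: float = 1.0 / 3.0
    rollback_discarded: bool = True

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def _disk_indices(shape, cx: float, cy: float, r: float):
    h, w = shape
    x0 = max(int(np.floor(cx - r)), 0)
    x1 = min(int(np.ceil(cx + r)) + 1, w)
    y0 = max(int(np.floor(cy - r)), 0)
    y1 = min(int(np.ceil(cy + r)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
    return ys[inside], xs[inside]


def reduce_points(
    dets: list[DetectedPoint],
    mask: np.ndarray,
    p: ReduceParams,
) -> list[DetectedPoint]:
    """Greedy disk-cover reduction of detected points.

    ``mask`` is the binarized (cleaned) foreground of the image the
    detections came from.  Candidates are sorted by death descending
    (ties by position, lexicographic); each in turn erases the remaining
    foreground pixels within radius (1+eps)*death of its position and is
    kept iff the erased count exceeds alpha*pi*death^2.  By default a
    discarded candidate's erasure is rolled back so that a rejected disk
    (typically a spurious loop spanning the gaps between figures) does
    not shadow smaller genuine figures processed later; set
    ``rollback_discarded=False`` for permanent erasure.
    """
    order = sorted(
        dets, key=lambda d: (-d.death, d.position[0], d.position[1])
    )
    remaining = np.asarray(mask, dtype=bool).copy()
    kept: list[DetectedPoint] = []
    for det in order:
        r = (1.0 + p.epsilon) * det.death
        idx = _disk_indices(remaining.shape, det.x, det.y, r)
        if idx is None:
            continue
        ys, xs = idx
        claimed = remaining[ys, xs]
        n_claimed = int(claimed.sum())
        if n_claimed > p.alpha * np.pi * det.death**2:
            remaining[ys, xs] = False
            kept.append(det)
        elif not p.rollback_discarded:
            remaining[ys, xs] = False
    return kept
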