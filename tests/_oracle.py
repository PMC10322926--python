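"""Independent brute-force oracles used only by the test suite.

``cech_h1_pairs`` computes H1 persistence of a small planar cloud by
explicit simplex enumeration (all pairs and triples, ordered by their
minimum-enclosing-ball radius) and textbook boundary-matrix reduction
over GF(2).  The Cech and alpha filtrations of the same cloud have
identical H1 diagrams (both are nerves of the same union of balls), so
this checks the production union-find implementation through a
completely different route.  Exponential in n; fine for n <= 12.
"""

from __future__ import annotations

import itertools

import numpy as np


def _meb_radius(pts: np.ndarray) -> float:
    """Minimum enclosing ball radius of 2 or 3 planar points."""
    if len(pts) == 2:
        return float(np.linalg.norm(pts[0] - pts[1]) / 2)
    best = np.inf
    # smallest ball through a pair containing the third
    for i, j in itertools.combinations(range(3), 2):
        c = (pts[i] + pts[j]) / 2
        r = np.linalg.norm(pts[i] - pts[j]) / 2
        k = 3 - i - j
        if np.linalg.norm(pts[k] - c) <= r + 1e-12:
            best = min(best, r)
    if np.isfinite(best):
        return float(best)
    # circumscribing circle
    a, b, c = pts
    d = 2 * ((b - a)[0] * (c - a)[1] - (b - a)[1] * (c - a)[0])
    ux = ((c - a)[1] * ((b - a) @ (b - a)) - (b - a)[1] * ((c - a) @ (c - a))) / d
    uy = ((b - a)[0] * ((c - a) @ (c - a)) - (c - a)[0] * ((b - a) @ (b - a))) / d
    return float(np.hypot(ux, uy))


def cech_h1_pairs(points: np.ndarray) -> list[tuple[float, float]]:
    """All finite H1 (birth, death) pairs of the Cech filtration."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for i in range(n):
        simplices.append((0.0, 0, (i,)))
    for e in itertools.combinations(range(n), 2):
        simplices.append((_meb_radius(pts[list(e)]), 1, e))
    for t in itertools.combinations(range(n), 3):
        simplices.append((_meb_radius(pts[list(t)]), 2, t))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: i for i, s in enumerate(simplices)}

    columns: list[set[int]] = []
    for _f, dim, verts in simplices:
        if dim == 0:
            columns.append(set())
        else:
            columns.append(
                {index[face] for face in
                 itertools.combinations(verts, dim)}
            )
    low_of: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    for j in range(len(columns)):
        col = columns[j]
        while col:
            low = max(col)
            if low not in low_of:
                low_of[low] = j
                pairs.append((low, j))
                break
            col ^= columns[low_of[low]]
    out = []
    for low, j in pairs:
        if simplices[low][1] == 1:  # killed simplex is an edge -> H1 pair
            birth, death = simplices[low][0], simplices[j][0]
            if death > birth + 1e-12:
                out.append((birth, death))
    return sorted(out)
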