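"""Persistent-homological figure detection.

The detector treats the contour pixels of a binarized frame as a planar
point cloud and computes the H1 persistence barcode of its alpha
filtration.  Each disk-like figure contributes one prominent loop whose
death radius approximates the figure's internal radius and whose death
simplex — the triangle that fills the loop in — has its circumcenter at
(approximately) the figure's center.  Plotting circumcenters of death
simplices therefore marks one point near the center of every disk-like
figure, including figures that overlap, as long as the shared boundary
shows a dent.

Persistence is computed exactly on the Delaunay triangulation: H1 classes
of a planar alpha filtration are in bijection with connected components
of the *dual* graph (triangles plus the unbounded face) filtered by
decreasing filtration value, so a single union-find sweep yields every
bar together with its killing triangle.  Birth and death are reported in
pixel-radius units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from skimage import measure

from .imgops import TransformParams, inverse_transform_points, transform_points

__all__ = [
    "Contour",
    "PersistenceBar",
    "DetectedPoint",
    "DetectParams",
    "PipelineParams",
    "extract_contours",
    "filter_contours",
    "compute_ph1",
    "circumcenter",
    "detect_points",
    "sure_foreground_count",
    "detect_in_image",
]

# Moore neighborhood in clockwise order, (dx, dy), starting due west.
_MOORE = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]


@dataclass(frozen=True)
class Contour:
    """Outer boundary of one 8-connected foreground component.

    ``points`` is the (n, 2) array of distinct boundary pixels in (x, y)
    coordinates — every pixel of the hole-filled component with a
    background 8-neighbor (the image border counts as background), so
    interior holes contribute nothing — ordered along a
    boundary-following walk, with inner-corner pixels the walk bypasses
    appended at the end; ``length`` is the number of boundary pixels.
    """

    points: np.ndarray
    label: int

    @property
    def length(self) -> int:
        return len(self.points)


@dataclass(frozen=True, eq=False)
class PersistenceBar:
    """One H1 class of the alpha filtration, in pixel-radius units.

    ``death_simplex`` holds the three cloud points of the triangle whose
    insertion kills the cycle; ``simplex_indices`` are their indices into
    the input cloud.
    """

    birth: float
    death: float
    death_simplex: np.ndarray
    simplex_indices: tuple[int, int, int]
    source: int = 0

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass(frozen=True, eq=False)
class DetectedPoint:
    """A detected figure center in original-image coordinates."""

    position: np.ndarray
    death: float
    bar: PersistenceBar
    degenerate: bool = False
    contour_id: int = -1

    @property
    def x(self) -> float:
        return float(self.position[0])

    @property
    def y(self) -> float:
        return float(self.position[1])


@dataclass(frozen=True)
class DetectParams:
    """Detection thresholds.

    ``ph_thres`` is the minimum internal radius (px) of the figures to
    detect: bars whose death is below it are discarded.  ``bd_thres``
    drops contours shorter than this many boundary pixels before
    persistence is computed, ignoring too-small figures.
    """

    ph_thres: float
    bd_thres: int = 0
    plot: str = "circumcenter"

    def __post_init__(self) -> None:
        if self.ph_thres < 0:
            raise ValueError("ph_thres must be >= 0")
        if self.bd_thres < 0:
            raise ValueError("bd_thres must be >= 0")
        if self.plot not in ("circumcenter", "barycenter"):
            raise ValueError("plot must be 'circumcenter' or 'barycenter'")


def _trace_boundary(mask: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore-neighbor boundary trace from a row-major-first start pixel.

    Returns the closed walk as (x, y) pixels; pixels on one-pixel-wide
    spurs may repeat.
    """
    h, w = mask.shape

    def fg(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and mask[y, x]

    sx, sy = start
    walk = [(sx, sy)]
    # Entered the start pixel from the west (scan order guarantees the
    # west neighbor is background).
    cx, cy, back = sx, sy, 0
    first_move = None
    for _ in range(8 * int(mask.sum()) + 8):
        for k in range(8):
            d = (back + 1 + k) % 8
            dx, dy = _MOORE[d]
            if fg(cx + dx, cy + dy):
                nxt = (cx + dx, cy + dy, d)
                break
        else:
            return walk  # isolated pixel
        if first_move is None:
            first_move = nxt
        elif (cx, cy) == (sx, sy) and nxt == first_move:
            break  # closed the walk with the same outgoing direction
        cx, cy, d = nxt
        walk.append((cx, cy))
        # new backtrack: direction pointing at the previous pixel
        back = (d + 4) % 8
    if walk[-1] == walk[0] and len(walk) > 1:
        walk.pop()
    return walk


def extract_contours(mask: np.ndarray) -> list[Contour]:
    """Outer contours of all 8-connected foreground components.

    Holes are ignored; each contour's points are the distinct boundary
    pixels (foreground pixels with a background 8-neighbor, the image
    border counting as background) in boundary-walk order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    contours: list[Contour] = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        # fill holes so that only the outer boundary remains: pixels
        # around an interior hole must not enter the point cloud
        sub = ndimage.binary_fill_holes(labels[sl] == lab)
        boundary = sub & ~ndimage.binary_erosion(
            sub, structure=np.ones((3, 3), dtype=bool), border_value=0)
        ys, xs = np.nonzero(sub)
        order = np.lexsort((xs, ys))  # row-major: topmost, then leftmost
        start = (int(xs[order[0]]), int(ys[order[0]]))
        walk = _trace_boundary(sub, start)
        seen: set[tuple[int, int]] = set()
        pts = []
        for p in walk:
            if p not in seen:
                seen.add(p)
                pts.append(p)
        # inner-corner pixels whose only background contact is diagonal
        # are bypassed by the Moore walk; append them in scan order
        for y, x in zip(*np.nonzero(boundary)):
            if (int(x), int(y)) not in seen:
                pts.append((int(x), int(y)))
        arr = np.array(pts, dtype=float)
        arr[:, 0] += sl[1].start
        arr[:, 1] += sl[0].start
        contours.append(Contour(points=arr, label=lab))
    return contours


def filter_contours(contours: list[Contour], bd_thres: int) -> list[Contour]:
    """Keep contours whose boundary length is at least ``bd_thres``."""
    return [c for c in contours if c.length >= bd_thres]


def circumcenter(a, b, c) -> tuple[np.ndarray, bool]:
    """Circumcenter of the triangle ``abc``.

    Returns ``(point, degenerate)``.  If the triangle is (near-)collinear
    — twice the signed area below ``1e-9`` times the largest pairwise
    squared distance — the barycenter is returned with the degenerate
    flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ab, ac, bc = b - a, c - a, c - b
    scale = max(ab @ ab, ac @ ac, bc @ bc)
    cross = ab[0] * ac[1] - ab[1] * ac[0]
    if abs(cross) < 1e-9 * max(scale, 1e-300):
        return (a + b + c) / 3.0, True
    d = 2.0 * cross
    ux = (ac[1] * (ab @ ab) - ab[1] * (ac @ ac)) / d
    uy = (ab[0] * (ac @ ac) - ac[0] * (ab @ ab)) / d
    return a + np.array([ux, uy]), False


def _circumradius(a, b, c) -> float:
    center, degen = circumcenter(a, b, c)
    if degen:
        # collinear triple: filtration value is half the longest side
        pts = np.array([a, b, c], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return float(d.max() / 2.0)
    return float(np.linalg.norm(np.asarray(a, float) - center))


class _UnionFind:
    """Union-find over dual nodes; each root remembers the incident
    triangle of maximum filtration value (ties to the lower index)."""

    def __init__(self, n_tri: int, tri_filt: np.ndarray):
        self.parent = list(range(n_tri + 1))  # node n_tri = unbounded face
        self.best = [(tri_filt[i], i) for i in range(n_tri)]
        self.best.append((np.inf, -1))
        self.outside = n_tri

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def elder(self, a: int, b: int) -> tuple[int, int]:
        """Return (survivor, dying) roots by max triangle filtration."""
        fa, ia = self.best[a]
        fb, ib = self.best[b]
        if (fa, -ia) >= (fb, -ib):
            return a, b
        return b, a


def compute_ph1(cloud: np.ndarray, source: int = 0) -> list[PersistenceBar]:
    """H1 persistence bars of the 2-D alpha filtration on a point cloud.

    Filtration values are Euclidean radii: a triangle enters at its
    circumradius, an edge at half its length if its diametral disk is
    empty (Gabriel) and otherwise at the value of the incident triangle
    that blocks it.  Bars are found by the planar duality between H1
    classes and connected components of the complement: triangles and
    the unbounded face are union-find nodes, Delaunay edges are merges
    processed in decreasing filtration order, and each merge that absorbs
    a bounded component emits the bar (edge value, component's maximum
    triangle value) with that triangle as the death simplex.

    Bars are sorted by death descending, then birth ascending, then by
    the death-simplex coordinates.  Fewer than three (or collinear)
    points yield no bars.
    """
    pts = np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        return []
    try:
        tri = Delaunay(pts)
    except QhullError:
        return []  # collinear input: no loops
    simplices = tri.simplices
    n_tri = len(simplices)
    if n_tri == 0:
        return []

    tri_filt = np.empty(n_tri)
    for t in range(n_tri):
        i, j, k = simplices[t]
        tri_filt[t] = _circumradius(pts[i], pts[j], pts[k])

    # edge -> incident triangle indices
    edges: dict[tuple[int, int], list[int]] = {}
    for t in range(n_tri):
        i, j, k = sorted(int(v) for v in simplices[t])
        for e in ((i, j), (i, k), (j, k)):
            edges.setdefault(e, []).append(t)

    def edge_filt(e: tuple[int, int], tris: list[int]) -> float:
        a, b = pts[e[0]], pts[e[1]]
        mid = (a + b) / 2.0
        r2 = ((a - b) @ (a - b)) / 4.0
        blocking = []
        for t in tris:
            opp = next(int(v) for v in simplices[t] if int(v) not in e)
            d2 = (pts[opp] - mid) @ (pts[opp] - mid)
            if d2 < r2 - 1e-12 * max(r2, 1.0):
                blocking.append(tri_filt[t])
        if blocking:
            return float(min(blocking))
        return float(np.sqrt(r2))

    dual = []  # (filt, i, j, node_a, node_b)
    uf = _UnionFind(n_tri, tri_filt)
    for e, tris in edges.items():
        f = edge_filt(e, tris)
        na = tris[0]
        nb = tris[1] if len(tris) == 2 else uf.outside
        dual.append((f, e[0], e[1], na, nb))
    dual.sort(key=lambda r: (-r[0], r[1], r[2]))

    bars: list[PersistenceBar] = []
    for f, _i, _j, na, nb in dual:
        ra, rb = uf.find(na), uf.find(nb)
        if ra == rb:
            continue
        survivor, dying = uf.elder(ra, rb)
        death, t_idx = uf.best[dying]
        uf.parent[dying] = survivor
        if death > f * (1 + 1e-12) + 1e-12:
            idx = tuple(sorted(int(v) for v in simplices[t_idx]))
            bars.append(
                PersistenceBar(
                    birth=float(f),
                    death=float(death),
                    death_simplex=pts[list(idx)].copy(),
                    simplex_indices=idx,
                    source=source,
                )
            )
    bars.sort(key=lambda b: (-b.death, b.birth, b.death_simplex.ravel().tolist()))
    return bars


def detect_points(
    bars: list[PersistenceBar],
    p: DetectParams,
    t: TransformParams | None = None,
    contour_of_point: np.ndarray | None = None,
) -> list[DetectedPoint]:
    """Plot one detected point per bar with death >= ``ph_thres``.

    The point is the circumcenter of the death simplex (barycenter when
    the simplex is degenerate, or always when ``p.plot == 'barycenter'``),
    mapped back to original-image coordinates through the inverse of the
    rotation/stretch transformation.  Results are sorted by death
    descending.
    """
    out: list[DetectedPoint] = []
    for bar in bars:
        if bar.death < p.ph_thres:
            continue
        a, b, c = bar.death_simplex
        if p.plot == "barycenter":
            pos, degen = (np.asarray(a) + b + c) / 3.0, False
        else:
            pos, degen = circumcenter(a, b, c)
        if t is not None and not t.is_identity:
            pos = inverse_transform_points(pos, t)[0]
        cid = -1
        if contour_of_point is not None:
            cid = int(contour_of_point[bar.simplex_indices[0]])
        out.append(
            DetectedPoint(
                position=np.asarray(pos, dtype=float),
                death=bar.death,
                bar=bar,
                degenerate=degen,
                contour_id=cid,
            )
        )
    out.sort(key=lambda d: -d.death)
    return out


def sure_foreground_count(bars: list[PersistenceBar], t: float) -> int:
    """Number of bars alive at radius ``t`` (birth <= t < death).

    This is the barcode analogue of watershed sure-foreground: eroding
    the foreground by distance ``t`` and counting components corresponds
    to drawing a vertical line at ``t`` through the barcode and counting
    intersections.  Thresholding deaths instead retains every bar with
    death >= t regardless of birth, which is why persistence detection
    can separate figures that no single erosion distance can.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    return sum(1 for b in bars if b.birth <= t < b.death)


@dataclass(frozen=True)
class PipelineParams:
    """All parameters of the single-frame detection pipeline."""

    binarize: "object"
    cleanup: "object"
    transform: TransformParams
    detect: DetectParams

    @classmethod
    def from_values(
        cls,
        bin_thres: float,
        nbd: int,
        erase_thres: int,
        rot: float,
        mult: float,
        ph_thres: float,
        bd_thres: int,
        polarity: str = "dark_foreground",
        axis: str = "x",
        plot: str = "circumcenter",
    ) -> "PipelineParams":
        from .imgops import BinarizeParams, CleanupParams

        return cls(
            binarize=BinarizeParams(bin_thres, polarity),
            cleanup=CleanupParams(nbd, erase_thres),
            transform=TransformParams(rot, mult, axis),
            detect=DetectParams(ph_thres, bd_thres, plot),
        )


def detect_in_image(
    gray: np.ndarray, p: PipelineParams
) -> tuple[list[DetectedPoint], list[PersistenceBar], np.ndarray]:
    """Full single-frame detection: binarize, clean, extract and filter
    contours, compute H1 persistence of each contour's point cloud
    (after the optional rotate/stretch transformation), and plot
    circumcenters back in original-image coordinates.

    Persistence is computed per contour rather than on the pooled cloud:
    overlapping figures already share one contour, while pooling
    well-separated components would add spurious large loops spanning
    the background gaps between them.

    Returns (detected points, all bars, cleaned binary mask).
    """
    from .imgops import binarize, erase_sparse_white, to_gray

    gray = to_gray(gray)
    mask = erase_sparse_white(binarize(gray, p.binarize), p.cleanup)
    contours = filter_contours(extract_contours(mask), p.detect.bd_thres)
    if not contours:
        return [], [], mask
    t = p.transform.with_image_center(mask.shape)
    bars: list[PersistenceBar] = []
    dets: list[DetectedPoint] = []
    for i, contour in enumerate(contours):
        cloud = (transform_points(contour.points, t)
                 if not t.is_identity else contour.points)
        cbars = compute_ph1(cloud, source=i)
        bars.extend(cbars)
        dets.extend(
            detect_points(cbars, p.detect, t,
                          np.full(contour.length, i))
        )
    dets.sort(key=lambda d: -d.death)
    return dets, bars, mask
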