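"""Image preprocessing: grayscale conversion, binarization, sparse-white
cleanup, and the rotate/stretch point-cloud transformation.

Images are plain ``numpy`` arrays: a *gray image* is a 2-D ``uint8`` array
(row, column) with intensities in [0, 255]; a *binary image* is a 2-D
boolean array of the same shape, ``True`` = foreground ("white").

Point coordinates throughout the package are ``(x, y)`` with ``x`` the
column and ``y`` the row, origin at the top-left pixel, sub-pixel values
kept as floats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BinarizeParams",
    "CleanupParams",
    "TransformParams",
    "to_gray",
    "binarize",
    "erase_sparse_white",
    "transform_points",
    "inverse_transform_points",
]

# BT.601 luma weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class BinarizeParams:
    """Intensity threshold and which side of it is foreground.

    ``dark_foreground`` marks pixels strictly below ``bin_thres`` as
    foreground (phase-contrast cells on a light background);
    ``bright_foreground`` marks pixels at or above it (fluorescent nuclei
    on a dark background).
    """

    bin_thres: float
    polarity: str = "dark_foreground"

    def __post_init__(self) -> None:
        if not 0 <= self.bin_thres <= 255:
            raise ValueError(f"bin_thres must be in [0, 255], got {self.bin_thres}")
        if self.polarity not in ("dark_foreground", "bright_foreground"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class CleanupParams:
    """Sparse-white cleanup: a white pixel survives only if its square
    neighborhood of side ``2*nbd + 1`` (center included, off-image pixels
    counted as black) contains at least ``erase_thres`` white pixels."""

    nbd: int = 5
    erase_thres: int = 0

    def __post_init__(self) -> None:
        if self.nbd < 0:
            raise ValueError("nbd must be >= 0")
        if self.erase_thres < 0:
            raise ValueError("erase_thres must be >= 0")


@dataclass(frozen=True)
class TransformParams:
    """Rotation (degrees, counter-clockwise positive in x-right / y-down
    raster coordinates) about the image center, followed by multiplying
    the ``axis`` coordinate by ``mult`` to make elongated figures
    disk-like."""

    rot: float = 0.0
    mult: float = 1.0
    axis: str = "x"
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mult <= 0:
            raise ValueError(f"mult must be > 0, got {self.mult}")
        if self.axis not in ("x", "y"):
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")

    @property
    def is_identity(self) -> bool:
        return self.rot == 0.0 and self.mult == 1.0

    def with_image_center(self, shape: tuple[int, int]) -> "TransformParams":
        """Return a copy whose rotation center is the center of an image
        of the given (height, width)."""
        h, w = shape[:2]
        return TransformParams(self.rot, self.mult, self.axis,
                               ((w - 1) / 2.0, (h - 1) / 2.0))


def to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an image array to 2-D uint8 gray.

    RGB(A) is collapsed with BT.601 luma; 16-bit input is rescaled to
    [0, 255] by its maximum value.
    """
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float64)
        top = arr.max()
        if top > 255:
            arr = arr * (255.0 / top)
        arr = np.clip(np.rint(arr), 0, 255)
    return arr.astype(np.uint8)


def binarize(img: np.ndarray, p: BinarizeParams) -> np.ndarray:
    """Threshold a gray image into a boolean foreground mask."""
    gray = np.asarray(img)
    if gray.ndim != 2:
        gray = to_gray(gray)
    if p.polarity == "dark_foreground":
        return gray < p.bin_thres
    return gray >= p.bin_thres


def erase_sparse_white(mask: np.ndarray, p: CleanupParams) -> np.ndarray:
    """Erase white pixels whose neighborhood white-count is below threshold.

    Counts are taken simultaneously over the *input* mask (a single pass,
    not iterated), so the result does not depend on any scan order.
    Output foreground is always a subset of input foreground.
    """
    mask = np.asarray(mask, dtype=bool)
    if p.erase_thres == 0:
        return mask.copy()
    size = 2 * p.nbd + 1
    counts = ndimage.uniform_filter(
        mask.astype(np.float64), size=size, mode="constant", cval=0.0
    ) * (size * size)
    counts = np.rint(counts).astype(np.int64)
    return mask & (counts >= p.erase_thres)


def _affine(p: TransformParams) -> tuple[np.ndarray, np.ndarray]:
    """Forward map as x -> A @ (x - c) + c."""
    th = np.deg2rad(p.rot)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    stretch = np.diag([p.mult, 1.0] if p.axis == "x" else [1.0, p.mult])
    return stretch @ rot, np.asarray(p.center, dtype=float)


def transform_points(pts: np.ndarray, p: TransformParams) -> np.ndarray:
    """Rotate points about the center, then stretch along one axis.

    Operates on (n, 2) arrays of (x, y) coordinates; order is preserved.
    The transformation is applied to contour point clouds rather than by
    resampling the raster, which avoids interpolation artifacts.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    a, c = _affine(p)
    return (pts - c) @ a.T + c


def inverse_transform_points(pts: np.ndarray, p: TransformParams) -> np.ndarray:
    """Exact inverse of :func:`transform_points` (undo stretch, rotate back)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    a, c = _affine(p)
    return (pts - c) @ np.linalg.inv(a).T + c
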