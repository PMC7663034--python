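"""Closed nodule boundaries and conversion between masks and contours.

A :class:`NoduleContour` is an ordered, implicitly closed polygon in image
pixel coordinates (x right, y down, 0-based).  It is the unit every shape
feature is computed from: expert-drawn ground-truth outlines arrive either
as coordinate lists (XML annotations) or as binary masks that are traced
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import (
    AmbiguousObjectError,
    DegenerateContourError,
    NoObjectError,
    OutOfBoundsError,
)

__all__ = ["NoduleContour", "mask_to_contour", "contour_to_mask"]


def _dedupe_closed(points: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicates and an explicit closing point."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour points must be an (N, 2) array")
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    if len(pts) > 1 and np.all(pts[0] == pts[-1]):
        pts = pts[:-1]
    return pts


@dataclass(frozen=True)
class NoduleContour:
    """Ordered closed boundary of one nodule, in pixel coordinates.

    Parameters
    ----------
    points
        ``(N, 2)`` array of ``(x, y)`` vertices; the closing edge from the
        last back to the first vertex is implicit.
    source
        ``"polygon-annotation"`` for coordinates read from an annotation
        file, ``"traced-from-mask"`` for boundaries traced from a raster.
    image_size
        Optional ``(width, height)`` of the image the contour lives in.
    """

    points: np.ndarray
    source: str = "polygon-annotation"
    image_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        pts = _dedupe_closed(self.points)
        if len(pts) < 3:
            raise DegenerateContourError("contour needs at least 3 distinct points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour coordinates must be finite")
        if self.image_size is not None and np.any(pts < 0):
            raise ValueError("negative coordinates with image_size present")
        # shoelace area; collinear input has zero area
        x, y = pts[:, 0], pts[:, 1]
        area2 = np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area2 <= 0:
            raise DegenerateContourError("zero-area object")
        object.__setattr__(self, "points", pts)
        pts.setflags(write=False)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[:, 0], self.points[:, 1]

    def signed_area(self) -> float:
        x, y = self.xy
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def resampled(self, spacing: float = 1.0) -> np.ndarray:
        """Return boundary points resampled at uniform arc-length spacing.

        This densifies sparse polygon annotations to border-pixel density
        so that pairwise axis searches and radial statistics do not depend
        on how many vertices the annotator clicked.
        """
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        # cap keeps the O(n^2) axis searches tractable for huge contours
        n = min(max(int(np.ceil(total / spacing)), 64), 2500)
        t = np.linspace(0.0, total, n, endpoint=False)
        x = np.interp(t, s, pts[:, 0])
        y = np.interp(t, s, pts[:, 1])
        return np.column_stack([x, y])


def mask_to_contour(
    mask: np.ndarray,
    *,
    keep_largest: bool = False,
    min_pixels: int = 9,
    smoothing_sigma: float = 0.8,
) -> NoduleContour:
    """Trace the outer boundary of the single object in a binary mask.

    Holes are filled before tracing: the ground truth is a nodule outline,
    so "filled area" semantics apply.  The boundary is extracted with
    marching squares at the 0.5 level of the (lightly Gaussian-smoothed)
    indicator, giving sub-pixel vertices free of staircase perimeter bias;
    re-rasterization recovers the mask to Jaccard >= 0.98 for realistic
    nodule sizes.

    Parameters
    ----------
    mask
        2-D array; nonzero pixels are foreground.
    keep_largest
        If several connected components exist, trace only the largest
        instead of raising :class:`AmbiguousObjectError`.
    min_pixels
        Minimum size of the traced component.
    smoothing_sigma
        Sigma (px) of the pre-trace smoothing; 0 traces the raw
        indicator.  Falls back to the raw indicator automatically if
        smoothing erases a very small object.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    # float coverage fields (anti-aliased rasterization, interpolated
    # rotations) carry a sub-pixel 0.5-level edge; trace it directly
    is_coverage = arr.dtype.kind == "f" and bool(np.any((arr > 0) & (arr < 1)))
    fg = arr >= 0.5 if is_coverage else arr != 0
    if not fg.any():
        raise NoObjectError("no object")
    labels, n_comp = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n_comp > 1:
        if not keep_largest:
            raise AmbiguousObjectError(f"ambiguous object: {n_comp} components")
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n_comp + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    if fg.sum() < min_pixels:
        raise NoObjectError(f"object smaller than {min_pixels} pixels")
    filled = ndimage.binary_fill_holes(fg)
    if is_coverage:
        field = arr.astype(float).copy()
        field[filled & ~fg] = 1.0  # fill interior holes
        field[~filled & (arr >= 0.5)] = 0.0  # drop discarded components
        padded = np.pad(field, 4)
        rings = measure.find_contours(padded, 0.5)
    else:
        padded = np.pad(filled.astype(float), 4)
        rings = []
        if smoothing_sigma > 0:
            rings = measure.find_contours(
                ndimage.gaussian_filter(padded, smoothing_sigma), 0.5
            )
        if not rings:  # tiny object smoothed away: trace the raw indicator
            rings = measure.find_contours(padded, 0.5)
    ring = max(rings, key=len)  # outer boundary of the single component
    # find_contours yields (row, col); shift off the pad and flip to (x, y)
    xy = np.column_stack([ring[:, 1] - 4.0, ring[:, 0] - 4.0])
    h, w = fg.shape
    # subpixel vertices of border-touching objects may poke out by < 1 px
    xy[:, 0] = np.clip(xy[:, 0], 0.0, w - 1.0)
    xy[:, 1] = np.clip(xy[:, 1], 0.0, h - 1.0)
    return NoduleContour(xy, source="traced-from-mask", image_size=(w, h))


def contour_to_mask(
    contour: NoduleContour, size: tuple[int, int], *, antialias: bool = False
) -> np.ndarray:
    """Rasterize the filled interior of a contour onto a ``(w, h)`` canvas.

    A pixel is foreground when its center lies inside the polygon
    (half-open on the high edge), so the pixel count tracks the polygon
    area without the ~perimeter/2 overcount of boundary-inclusive
    filling, and the convention matches the pixel-center coordinates of
    :func:`mask_to_contour`.

    With ``antialias`` the result is a float coverage field (4x4
    supersampling per pixel) whose 0.5-level set follows the polygon
    boundary with sub-pixel accuracy; binary masks instead carry an
    ~1 px staircase.

    Raises
    ------
    OutOfBoundsError
        If any vertex falls outside the canvas.
    """
    import shapely
    from shapely.affinity import translate
    from shapely.geometry import Polygon

    w, h = size
    x, y = contour.xy
    if x.min() < -0.5 or y.min() < -0.5 or x.max() > w - 0.5 or y.max() > h - 0.5:
        raise OutOfBoundsError("out of bounds: contour exceeds canvas")
    poly = Polygon(contour.points)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    # nudge so centers on the low boundary count as inside, high as outside
    poly = translate(poly, -1e-7, -1e-7)
    x0 = max(int(np.floor(x.min())), 0)
    x1 = min(int(np.ceil(x.max())) + 1, w)
    y0 = max(int(np.floor(y.min())), 0)
    y1 = min(int(np.ceil(y.max())) + 1, h)
    if antialias:
        ss = 4
        offs = (np.arange(ss) + 0.5) / ss - 0.5
        gx = (np.arange(x0, x1)[:, None] + offs[None, :]).ravel()
        gy = (np.arange(y0, y1)[:, None] + offs[None, :]).ravel()
        xs, ys = np.meshgrid(gx, gy)
        sub = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(xs.shape)
        cover = sub.reshape(y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
        mask = np.zeros((h, w), dtype=float)
        mask[y0:y1, x0:x1] = cover
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(xs.shape)
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[y0:y1, x0:x1] = inside.astype(np.uint8)
    return mask
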