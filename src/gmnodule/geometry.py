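"""Base geometric measurements of a nodule contour.

Everything the 27 feature formulas consume is computed here once per
contour: polygon area and perimeter, convex hull, major/minor axes with
their endpoints, orientation, oriented and axis-aligned boxes, and the
reference shapes (minimum-area rectangle, related ellipse, equal-area
circle) that the perimeter-ratio features compare against.

Conventions
-----------
Coordinates are 0-based pixels, x right / y down as stored.  Orientation
is reported after converting to a y-up mathematical frame, in degrees in
(-90, 90], measured counterclockwise from +x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import shapely
from shapely.geometry import Polygon

from .contour import NoduleContour, contour_to_mask
from .errors import DegenerateContourError

__all__ = [
    "GeometryConfig",
    "ShapeGeometry",
    "ReferenceShapes",
    "compute_geometry",
    "minimum_area_rectangle",
    "reference_shapes",
    "ellipse_perimeter_ramanujan",
]


@dataclass(frozen=True)
class GeometryConfig:
    """Tunable conventions for the base measurements.

    minor_axis_mode
        ``"chord"`` (default): longest boundary-to-boundary chord whose
        direction is perpendicular to the major axis within
        ``minor_axis_angle_tol_deg``.  ``"projection"``: width of the
        boundary projected onto the perpendicular direction.
    tcp_reference
        Circle the TCP features compare against: ``"equal_area"``
        (default) or ``"major_diameter"``.
    tep_reference
        Ellipse the TEP features compare against: ``"axes_ellipse"``
        (default, semi-axes L_MA/2 and L_ma/2) or ``"moments_ellipse"``
        (second-moment fit of the boundary).
    resample_spacing
        Arc-length spacing (px) of the border points used for axis
        searches and radial statistics.  The sub-pixel default keeps the
        tolerance-band chord search stable under symmetry operations.
    """

    minor_axis_mode: str = "chord"
    minor_axis_angle_tol_deg: float = 2.0
    tcp_reference: str = "equal_area"
    tep_reference: str = "axes_ellipse"
    resample_spacing: float = 0.5


DEFAULT_CONFIG = GeometryConfig()


@dataclass(frozen=True)
class ShapeGeometry:
    """All base measurements of one contour (units: px and px^2)."""

    area_An: float
    perimeter_Pn: float
    hull: NoduleContour
    convex_area_Ac: float
    convex_perimeter_Pc: float
    filled_area: float
    centroid: tuple[float, float]
    major_axis_endpoints: tuple[tuple[float, float], tuple[float, float]]
    major_axis_length: float
    minor_axis_endpoints: tuple[tuple[float, float], tuple[float, float]]
    minor_axis_length: float
    orientation_deg: float
    oriented_box: tuple[float, float]  # (L_n, W_n), L_n >= W_n
    aligned_extent: tuple[float, float]  # (width W, depth D)
    bbox_area: float  # L_MA * L_ma
    boundary_points: np.ndarray  # resampled border used for axis/radial stats


@dataclass(frozen=True)
class ReferenceShapes:
    """Reference rectangle, ellipse and circle for ratio features."""

    min_rect_area_Ar: float
    ellipse_semi_axes: tuple[float, float]  # (a, b), a >= b
    ellipse_perimeter_Pe: float
    circle_radius: float
    circle_perimeter: float


def _major_axis(border: np.ndarray) -> tuple[int, int, float]:
    """Farthest pair of border points; ties broken by lowest (x, y) endpoint.

    Exhaustive pairwise scan (vectorized): exactly the definition of the
    longest line traced through the object over every combination of
    border pixels.
    """
    dx = border[:, 0][:, None] - border[:, 0][None, :]
    dy = border[:, 1][:, None] - border[:, 1][None, :]
    d2 = dx * dx + dy * dy
    dmax = d2.max()
    ii, jj = np.nonzero(d2 == dmax)
    # orient each candidate pair so its first endpoint is lexicographically
    # smallest, then pick the lexicographically smallest pair
    best = None
    for i, j in zip(ii.tolist(), jj.tolist()):
        p, q = border[i], border[j]
        if (q[0], q[1]) < (p[0], p[1]):
            i, j = j, i
            p, q = q, p
        key = (p[0], p[1], q[0], q[1])
        if best is None or key < best[0]:
            best = (key, i, j)
    return best[1], best[2], float(np.sqrt(dmax))


def _minor_axis_chord(
    border: np.ndarray, major_dir: np.ndarray, tol_deg: float
) -> tuple[tuple[float, float], tuple[float, float], float] | None:
    """Longest chord perpendicular to the major axis within +/- tol_deg."""
    dx = border[:, 0][:, None] - border[:, 0][None, :]
    dy = border[:, 1][:, None] - border[:, 1][None, :]
    d2 = dx * dx + dy * dy
    dot = dx * major_dir[0] + dy * major_dir[1]
    # |cos(angle to major)| <= sin(tol)  <=>  within tol of perpendicular
    sin_tol = np.sin(np.deg2rad(tol_deg))
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (dot * dot) <= (d2 * sin_tol * sin_tol)
    ok &= d2 > 0
    if not ok.any():
        return None
    d2_ok = np.where(ok, d2, -np.inf)
    dmax = d2_ok.max()
    ii, jj = np.nonzero(d2_ok == dmax)
    best = None
    for i, j in zip(ii.tolist(), jj.tolist()):
        p, q = border[i], border[j]
        if (q[0], q[1]) < (p[0], p[1]):
            p, q = q, p
        key = (p[0], p[1], q[0], q[1])
        if best is None or key < best[0]:
            best = (key, p, q)
    _, p, q = best
    return (float(p[0]), float(p[1])), (float(q[0]), float(q[1])), float(np.sqrt(dmax))


def _minor_axis_projection(
    border: np.ndarray, major_dir: np.ndarray
) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Extent of the border projected perpendicular to the major axis."""
    perp = np.array([-major_dir[1], major_dir[0]])
    proj = border @ perp
    i, j = int(np.argmin(proj)), int(np.argmax(proj))
    length = float(proj[j] - proj[i])
    return tuple(border[i]), tuple(border[j]), length


def compute_geometry(
    contour: NoduleContour, config: GeometryConfig = DEFAULT_CONFIG
) -> ShapeGeometry:
    """Measure everything the feature formulas need from one contour.

    Area is the shoelace polygon area; perimeter the Euclidean arc length
    of the closed polygon.  The major axis is the farthest pair among
    uniformly resampled border points; the minor axis the longest chord
    perpendicular to it (within the configured angular tolerance).
    ``filled_area`` is the foreground pixel count of the rasterized
    interior, realizing the pixel-count "Filled Area" feature alongside
    the polygonal "Area".
    """
    poly = Polygon(contour.points)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
        if poly.geom_type != "Polygon":
            raise DegenerateContourError("contour is not a simple polygon")
    area = float(poly.area)
    if area <= 0:
        raise DegenerateContourError("zero-area object")
    perimeter = float(poly.length)

    hull_poly = poly.convex_hull
    hull_pts = np.asarray(hull_poly.exterior.coords)[:-1]
    hull = NoduleContour(hull_pts, source=contour.source, image_size=contour.image_size)

    border = contour.resampled(config.resample_spacing)
    i, j, l_ma_len = _major_axis(border)
    p1, p2 = border[i], border[j]
    major_dir = (p2 - p1) / l_ma_len

    if config.minor_axis_mode == "chord":
        minor = _minor_axis_chord(border, major_dir, config.minor_axis_angle_tol_deg)
        if minor is None:
            warnings.warn(
                "no chord perpendicular to the major axis within tolerance; "
                "falling back to projection width",
                stacklevel=2,
            )
            minor = _minor_axis_projection(border, major_dir)
    elif config.minor_axis_mode == "projection":
        minor = _minor_axis_projection(border, major_dir)
    else:
        raise ValueError(f"unknown minor_axis_mode {config.minor_axis_mode!r}")
    q1, q2, l_mi_len = minor

    # orientation of the major axis in a y-up frame, (-90, 90]
    ang = np.degrees(np.arctan2(-(p2[1] - p1[1]), p2[0] - p1[0]))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0

    x, y = contour.xy
    width = float(x.max() - x.min())
    depth = float(y.max() - y.min())

    # rasterize in a local frame for the pixel-count area
    shift = np.floor(np.min(contour.points, axis=0)) - 1
    local = NoduleContour(contour.points - shift, source=contour.source)
    span = np.ceil(np.max(local.points, axis=0)).astype(int) + 2
    filled = float(contour_to_mask(local, (int(span[0]), int(span[1]))).sum())

    c = poly.centroid
    return ShapeGeometry(
        area_An=area,
        perimeter_Pn=perimeter,
        hull=hull,
        convex_area_Ac=float(hull_poly.area),
        convex_perimeter_Pc=float(hull_poly.length),
        filled_area=filled,
        centroid=(float(c.x), float(c.y)),
        major_axis_endpoints=(tuple(map(float, p1)), tuple(map(float, p2))),
        major_axis_length=l_ma_len,
        minor_axis_endpoints=(tuple(map(float, q1)), tuple(map(float, q2))),
        minor_axis_length=l_mi_len,
        orientation_deg=float(ang),
        oriented_box=(l_ma_len, l_mi_len),
        aligned_extent=(width, depth),
        bbox_area=l_ma_len * l_mi_len,
        boundary_points=border,
    )


def minimum_area_rectangle(hull: NoduleContour) -> float:
    """Area of the smallest enclosing rectangle over all orientations.

    Rotating-calipers contract: one side of the optimum is collinear with
    a hull edge.
    """
    poly = Polygon(hull.points).convex_hull
    if poly.area <= 0:
        raise DegenerateContourError("zero-area object")
    rect = poly.minimum_rotated_rectangle
    return float(rect.area)


def ellipse_perimeter_ramanujan(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter.

    Relative error < 1e-6 for aspect ratios up to ~5.
    """
    h = ((a - b) / (a + b)) ** 2
    return float(np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))


def reference_shapes(
    geom: ShapeGeometry, config: GeometryConfig = DEFAULT_CONFIG
) -> ReferenceShapes:
    """Reference rectangle, ellipse and circle for the ratio features.

    The related ellipse has semi-axes L_MA/2 and L_ma/2 (or a second-moment
    fit when configured); the relevant circle has the same area as the
    object (or diameter L_MA when configured).  Both defaults make the
    TEP and TCP ratios 1 for a disk.
    """
    if config.tep_reference == "axes_ellipse":
        a, b = geom.major_axis_length / 2.0, geom.minor_axis_length / 2.0
    elif config.tep_reference == "moments_ellipse":
        pts = geom.boundary_points - np.asarray(geom.centroid)
        cov = np.cov(pts.T, bias=True)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        # semi-axes of the ellipse with matching boundary second moments
        a, b = float(np.sqrt(2.0 * evals[0])), float(np.sqrt(2.0 * evals[1]))
    else:
        raise ValueError(f"unknown tep_reference {config.tep_reference!r}")
    pe = ellipse_perimeter_ramanujan(a, b)

    if config.tcp_reference == "equal_area":
        radius = float(np.sqrt(geom.area_An / np.pi))
    elif config.tcp_reference == "major_diameter":
        radius = geom.major_axis_length / 2.0
    else:
        raise ValueError(f"unknown tcp_reference {config.tcp_reference!r}")
    p_circle = 2.0 * np.pi * radius

    return ReferenceShapes(
        min_rect_area_Ar=minimum_area_rectangle(geom.hull),
        ellipse_semi_axes=(a, b),
        ellipse_perimeter_Pe=pe,
        circle_radius=radius,
        circle_perimeter=float(p_circle),
    )
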