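"""The 27 geometric and morphological (G-M) shape features.

Nineteen geometric features describe the boundary's shape and
irregularity (convexity, solidity, compactness, axes, circular and
elliptic variance, ...); eight morphological features describe its
structuring measurements (area, perimeter, aspect ratio and the
perimeter ratios against a related ellipse and circle).  Eleven of the
27 are the fixed TIRADS-aligned subset chosen for classification: they
capture the shape, size, margin-irregularity and orientation attributes
a physician grades on ultrasound.

Feature registry (name, formula, units):

==== ======================= ==================================== =====
idx  name                    formula                              units
==== ======================= ==================================== =====
1    convex_hull             number of hull vertices              --
2    convexity               P_c / P_n                            --
3    solidity                A_n / A_c                            --
4    elongation              W_n / L_n (oriented box)             --
5    compactness             4 pi A_n / P_n^2                     --
6    rectangularity          A_n / A_r (min-area rectangle)       --
7    orientation             major-axis angle, y-up frame         deg
8    roundness               4 pi A_n / P_c^2                     --
9    major_axis_length       L_MA (farthest border pair)          px
10   minor_axis_length       L_ma (perpendicular chord)           px
11   eccentricity            L_ma / L_MA                          --
12   circular_variance       sigma_R / mu_R (radial distances)    --
13   elliptic_variance       sigma'_R / mu'_R (Mahalanobis)       --
14   axis_ratio              L_MA / L_ma                          --
15   bounding_box            L_MA * L_ma                          px^2
16   centroid                center of gravity (c_x, c_y)         px
17   convex_area             A_c                                  px^2
18   filled_area             rasterized-interior pixel count      px^2
19   convex_perimeter        P_c                                  px
20   area                    A_n (shoelace)                       px^2
21   perimeter               P_n (arc length)                     px
22   aspect_ratio            D / W (axis-aligned depth/width)     --
23   ap_ratio                A_n / P_n                            px
24   tep_ratio               P_n / P_e (related ellipse)          --
25   tep_difference          P_n - P_e                            px
26   tcp_ratio               P_n / P_circle (equal-area circle)   --
27   tcp_difference          P_n - P_circle                       px
==== ======================= ==================================== =====
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

from .contour import NoduleContour
from .errors import GMNoduleError
from .geometry import (
    DEFAULT_CONFIG,
    GeometryConfig,
    ReferenceShapes,
    ShapeGeometry,
    compute_geometry,
    reference_shapes,
)

__all__ = [
    "FEATURE_NAMES",
    "TIRADS11_NAMES",
    "RadialProfile",
    "MahalanobisProfile",
    "FeatureVector",
    "radial_profile",
    "mahalanobis_profile",
    "geometric_features",
    "morphological_features",
    "extract_feature_vector",
    "select_significant",
]

GEOMETRIC_NAMES: tuple[str, ...] = (
    "convex_hull",
    "convexity",
    "solidity",
    "elongation",
    "compactness",
    "rectangularity",
    "orientation",
    "roundness",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "circular_variance",
    "elliptic_variance",
    "axis_ratio",
    "bounding_box",
    "centroid",
    "convex_area",
    "filled_area",
    "convex_perimeter",
)

MORPHOLOGICAL_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "aspect_ratio",
    "ap_ratio",
    "tep_ratio",
    "tep_difference",
    "tcp_ratio",
    "tcp_difference",
)

#: All 27 feature names in inventory order.
FEATURE_NAMES: tuple[str, ...] = GEOMETRIC_NAMES + MORPHOLOGICAL_NAMES

#: The fixed 11-feature TIRADS-aligned selection, in its fixed clinical order.
TIRADS11_NAMES: tuple[str, ...] = (
    "solidity",
    "orientation",
    "roundness",
    "major_axis_length",
    "minor_axis_length",
    "bounding_box",
    "convex_area",
    "area",
    "perimeter",
    "aspect_ratio",
    "ap_ratio",
)


@dataclass(frozen=True)
class RadialProfile:
    """Centroid-to-boundary distances and their first two moments (px)."""

    distances: np.ndarray
    mean_muR: float
    sd_sigmaR: float


@dataclass(frozen=True)
class MahalanobisProfile:
    """Covariance-normalized boundary distances (dimensionless).

    The covariance of the centered boundary coordinates defines the
    best-fitting oval; distances are measured in its metric, so a perfect
    ellipse has near-constant distances and near-zero elliptic variance.
    """

    distances: np.ndarray
    mean_muRp: float
    sd_sigmaRp: float
    covariance: np.ndarray


def radial_profile(geom: ShapeGeometry) -> RadialProfile:
    """Distances from the centroid to the border points."""
    d = np.linalg.norm(geom.boundary_points - np.asarray(geom.centroid), axis=1)
    return RadialProfile(d, float(d.mean()), float(d.std()))


def mahalanobis_profile(geom: ShapeGeometry) -> MahalanobisProfile:
    """Boundary distances in the metric of the fitted oval."""
    v = geom.boundary_points - np.asarray(geom.centroid)
    cov = np.cov(v.T, bias=True)
    cov_inv = np.linalg.inv(cov)
    d = np.sqrt(np.einsum("ni,ij,nj->n", v, cov_inv, v))
    return MahalanobisProfile(d, float(d.mean()), float(d.std()), cov)


class FeatureVector(Mapping[str, object]):
    """The 27 named G-M feature values for one nodule.

    Behaves as an ordered read-only mapping in inventory order.
    ``centroid`` holds an ``(c_x, c_y)`` pair; every other entry is a
    scalar.  :meth:`as_row` flattens the centroid into two columns for
    tabular export.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, object]):
        missing = [n for n in FEATURE_NAMES if n not in values]
        if missing:
            raise GMNoduleError(f"incomplete feature vector: missing {missing}")
        extra = [n for n in values if n not in FEATURE_NAMES]
        if extra:
            raise GMNoduleError(f"unknown feature names {extra}")
        self._values = {n: values[n] for n in FEATURE_NAMES}

    def __getitem__(self, name: str) -> object:
        return self._values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:
        return f"FeatureVector({self._values!r})"

    def as_row(self) -> dict[str, float]:
        """Flatten to 28 numeric columns (centroid -> centroid_x/_y)."""
        row: dict[str, float] = {}
        for name, value in self._values.items():
            if name == "centroid":
                row["centroid_x"], row["centroid_y"] = map(float, value)
            else:
                row[name] = float(value)
        return row


def geometric_features(
    geom: ShapeGeometry, refs: ReferenceShapes
) -> dict[str, object]:
    """The 19 geometric features from precomputed base measurements."""
    l_major = geom.major_axis_length
    l_minor = geom.minor_axis_length
    rad = radial_profile(geom)
    mah = mahalanobis_profile(geom)
    l_n, w_n = geom.oriented_box
    return {
        "convex_hull": float(len(geom.hull)),
        "convexity": geom.convex_perimeter_Pc / geom.perimeter_Pn,
        "solidity": geom.area_An / geom.convex_area_Ac,
        "elongation": w_n / l_n,
        "compactness": 4.0 * np.pi * geom.area_An / geom.perimeter_Pn**2,
        "rectangularity": geom.area_An / refs.min_rect_area_Ar,
        "orientation": geom.orientation_deg,
        "roundness": 4.0 * np.pi * geom.area_An / geom.convex_perimeter_Pc**2,
        "major_axis_length": l_major,
        "minor_axis_length": l_minor,
        "eccentricity": l_minor / l_major,
        "circular_variance": rad.sd_sigmaR / rad.mean_muR,
        "elliptic_variance": mah.sd_sigmaRp / mah.mean_muRp,
        "axis_ratio": l_major / l_minor,
        "bounding_box": l_major * l_minor,
        "centroid": geom.centroid,
        "convex_area": geom.convex_area_Ac,
        "filled_area": geom.filled_area,
        "convex_perimeter": geom.convex_perimeter_Pc,
    }


def morphological_features(
    geom: ShapeGeometry, refs: ReferenceShapes
) -> dict[str, float]:
    """The 8 morphological features from precomputed base measurements.

    Aspect ratio is depth over width in the image frame (axis-aligned
    extents): values above 1 are the taller-than-wide configuration that
    TIRADS treats as a malignancy sign.
    """
    width, depth = geom.aligned_extent
    return {
        "area": geom.area_An,
        "perimeter": geom.perimeter_Pn,
        "aspect_ratio": depth / width,
        "ap_ratio": geom.area_An / geom.perimeter_Pn,
        "tep_ratio": geom.perimeter_Pn / refs.ellipse_perimeter_Pe,
        "tep_difference": geom.perimeter_Pn - refs.ellipse_perimeter_Pe,
        "tcp_ratio": geom.perimeter_Pn / refs.circle_perimeter,
        "tcp_difference": geom.perimeter_Pn - refs.circle_perimeter,
    }


def extract_feature_vector(
    contour: NoduleContour, config: GeometryConfig = DEFAULT_CONFIG
) -> FeatureVector:
    """Compute all 27 G-M features of one contour."""
    geom = compute_geometry(contour, config)
    refs = reference_shapes(geom, config)
    values: dict[str, object] = {}
    values.update(geometric_features(geom, refs))
    values.update(morphological_features(geom, refs))
    return FeatureVector(values)


def select_significant(
    fv: FeatureVector | Mapping[str, object], mode: str = "tirads11"
) -> dict[str, object]:
    """Apply the fixed clinical feature selection.

    ``mode="tirads11"`` returns the 11 selected features in their
    fixed clinical order; ``"discounted16"`` the complementary 16;
    ``"global27"`` all 27.
    """
    missing = [n for n in FEATURE_NAMES if n not in fv]
    if missing:
        raise GMNoduleError(f"incomplete feature vector: missing {missing}")
    if mode == "tirads11":
        names: tuple[str, ...] = TIRADS11_NAMES
    elif mode == "discounted16":
        names = tuple(n for n in FEATURE_NAMES if n not in TIRADS11_NAMES)
    elif mode == "global27":
        names = FEATURE_NAMES
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return {n: fv[n] for n in names}
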