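"""Seeded synthetic nodule contours with TIRADS-like class structure.

Real thyroid-nodule ground truth is an expert-drawn closed boundary.
This generator emulates the two clinical phenotypes at the level of
boundary geometry only (no ultrasound texture):

* benign-like: smooth ovals, wider than tall, near-horizontal major axis;
* malignant-like: taller than wide, lobulated, with spiculated
  (irregular) margins.

A contour is a radial perturbation of an ellipse,

    r(theta) = r_ellipse(theta) * (1 + lob * sin(k_lob * theta + phi)
                                     + spic * s(theta)),

where ``s`` is seeded band-limited noise whose dominant harmonics sit at
the requested spicule count, normalized to unit peak amplitude.  Because
``r > 0`` the curve is star-shaped about its center and therefore simple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .contour import NoduleContour, contour_to_mask
from .dataset_io import CaseRecord

__all__ = [
    "ShapeSpec",
    "BENIGN_PARAMS",
    "MALIGNANT_PARAMS",
    "generate_shape",
    "generate_cohort",
]

_N_BOUNDARY = 256  # vertices per generated contour
_LOBULATION_HARMONIC = 3


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic nodule contour."""

    class_label: int
    base_semi_axes: tuple[float, float]  # (x semi-axis, y semi-axis), px
    rotation_deg: float = 0.0
    spicule_amplitude: float = 0.0  # fraction of local radius
    spicule_count: int = 8
    lobulation_amplitude: float = 0.0
    canvas: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 or 1")
        a, b = self.base_semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        for amp in (self.spicule_amplitude, self.lobulation_amplitude):
            if not 0.0 <= amp < 0.5:
                raise ValueError("amplitudes must be in [0, 0.5)")


def _band_limited_noise(
    theta: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Periodic noise with dominant harmonics around ``count`` lobes."""
    harmonics = range(max(2, count - 2), count + 3)
    s = np.zeros_like(theta)
    for m in harmonics:
        weight = 1.0 if m == count else 0.4
        amp = weight * rng.uniform(0.5, 1.0)
        s += amp * np.cos(m * theta + rng.uniform(0.0, 2.0 * np.pi))
    peak = np.max(np.abs(s))
    return s / peak if peak > 0 else s


def generate_shape(spec: ShapeSpec) -> tuple[np.ndarray, NoduleContour]:
    """Generate one (mask, contour) pair; deterministic per seed.

    The contour is centered on the canvas; rotation is counterclockwise
    in the y-up mathematical frame, so a measured orientation matches
    ``rotation_deg`` for elongated shapes.
    """
    rng = np.random.default_rng(spec.seed)
    a, b = spec.base_semi_axes
    theta = np.linspace(0.0, 2.0 * np.pi, _N_BOUNDARY, endpoint=False)
    r_ellipse = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)

    factor = np.ones_like(theta)
    if spec.lobulation_amplitude > 0:
        factor += spec.lobulation_amplitude * np.sin(
            _LOBULATION_HARMONIC * theta + rng.uniform(0.0, 2.0 * np.pi)
        )
    if spec.spicule_amplitude > 0:
        factor += spec.spicule_amplitude * _band_limited_noise(
            theta, spec.spicule_count, rng
        )
    if factor.min() <= 0.05:
        warnings.warn("radial modulation clamped to keep the curve simple", stacklevel=2)
        factor = np.clip(factor, 0.05, None)
    r = r_ellipse * factor

    x = r * np.cos(theta)
    y_up = r * np.sin(theta)
    phi = np.deg2rad(spec.rotation_deg)
    xr = np.cos(phi) * x - np.sin(phi) * y_up
    yr = np.sin(phi) * x + np.cos(phi) * y_up
    w, h = spec.canvas
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    pts = np.column_stack([cx + xr, cy - yr])  # y-down storage
    contour = NoduleContour(pts, source="polygon-annotation", image_size=spec.canvas)
    mask = contour_to_mask(contour, spec.canvas)
    return mask, contour


#: Benign-like class defaults: smooth, wider-than-tall ovals.
BENIGN_PARAMS: dict[str, tuple[float, float]] = {
    "semi_width": (35.0, 60.0),
    "flatness": (0.55, 0.9),  # b/a, vertical over horizontal semi-axis
    "rotation_deg": (-10.0, 10.0),
    "spicule_amplitude": (0.0, 0.03),
    "spicule_count": (6, 12),
    "lobulation_amplitude": (0.0, 0.0),
}

#: Malignant-like class defaults: taller-than-wide, spiculated, lobulated.
MALIGNANT_PARAMS: dict[str, tuple[float, float]] = {
    "semi_width": (30.0, 50.0),
    "depth_over_width": (1.05, 1.5),
    "rotation_deg": (-10.0, 10.0),
    "spicule_amplitude": (0.08, 0.2),
    "spicule_count": (8, 14),
    "lobulation_amplitude": (0.03, 0.08),
}


def _draw_spec(
    label: int, params: dict, canvas: tuple[int, int], rng: np.random.Generator
) -> ShapeSpec:
    a = rng.uniform(*params["semi_width"])
    if label == 0:
        b = a * rng.uniform(*params["flatness"])
    else:
        b = a * rng.uniform(*params["depth_over_width"])
    lo, hi = params["spicule_count"]
    return ShapeSpec(
        class_label=label,
        base_semi_axes=(a, b),
        rotation_deg=rng.uniform(*params["rotation_deg"]),
        spicule_amplitude=rng.uniform(*params["spicule_amplitude"]),
        spicule_count=int(rng.integers(lo, hi + 1)),
        lobulation_amplitude=rng.uniform(*params["lobulation_amplitude"]),
        canvas=canvas,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_per_class: int | tuple[int, int],
    benign_params: dict | None = None,
    malignant_params: dict | None = None,
    seed: int = 0,
    canvas: tuple[int, int] = (256, 256),
    with_masks: bool = False,
) -> list[CaseRecord]:
    """Generate a labeled two-class cohort of synthetic nodule cases.

    ``n_per_class`` is either one count for both classes or a
    ``(n_benign, n_malignant)`` pair for imbalanced cohorts.  Returns
    single-nodule cases (benign first), fully determined by ``seed``.
    With ``with_masks`` each case also carries its rasterized mask in
    ``case.mask``.
    """
    if isinstance(n_per_class, int):
        n_benign = n_malignant = n_per_class
    else:
        n_benign, n_malignant = n_per_class
    if min(n_benign, n_malignant) < 1:
        raise ValueError("need at least one case per class")
    benign = {**BENIGN_PARAMS, **(benign_params or {})}
    malignant = {**MALIGNANT_PARAMS, **(malignant_params or {})}
    rng = np.random.default_rng(seed)
    cases: list[CaseRecord] = []
    for label, params, prefix, count in (
        (0, benign, "b", n_benign),
        (1, malignant, "m", n_malignant),
    ):
        for i in range(count):
            spec = _draw_spec(label, params, canvas, rng)
            mask, contour = generate_shape(spec)
            cases.append(
                CaseRecord(
                    case_id=f"syn-{prefix}{i:04d}",
                    contours=[contour],
                    tirads_category=None,
                    label=label,
                    mask=mask if with_masks else None,
                )
            )
    return cases
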