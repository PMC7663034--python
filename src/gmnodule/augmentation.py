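"""Class balancing by stochastic flip / rotate / blur augmentation.

Geometric operations (flips, continuous rotation about the image center)
are applied identically to the image and the ground-truth contour, so
features computed from the transformed contour stay consistent with the
transformed raster.  Gaussian blur acts on pixel intensities only and
never alters the contour — a blur-only augmented row therefore carries
feature values identical to its source, which mirrors the usual
augment-then-extract procedure and can be disabled with
``drop_feature_duplicates``.

Every draw comes from one seeded generator, so identical inputs, config
and seed give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .contour import NoduleContour
from .dataset_io import CaseRecord
from .errors import ConfigError

__all__ = [
    "AugmentationConfig",
    "AugmentedCase",
    "augment_case",
    "balance_and_augment",
    "augmented_feature_table",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """Stochastic augmentation parameters.

    Each operation fires independently with its probability; rotation
    angles (degrees, counterclockwise in the y-up frame) and blur sigmas
    (px) are drawn uniformly from their ranges.
    """

    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    p_rotate: float = 0.5
    rotate_range_deg: tuple[float, float] = (-25.0, 25.0)
    p_blur: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.5, 2.0)
    target_per_class: int = 0
    seed: int = 0
    drop_feature_duplicates: bool = False

    def __post_init__(self) -> None:
        for name in ("p_flip_h", "p_flip_v", "p_rotate", "p_blur"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} not a probability")
        lo, hi = self.rotate_range_deg
        if not (-180.0 < lo <= hi <= 180.0):
            raise ConfigError("rotate_range_deg must lie within (-180, 180]")


@dataclass
class AugmentedCase:
    """One row of an augmented cohort with its provenance and op log."""

    case_id: str
    source_case_id: str
    source_tag: str  # "original" | "augmented"
    contour: NoduleContour
    label: int
    image: np.ndarray | None = None
    op_log: dict | None = None


def _rotate_pair(
    image: np.ndarray | None,
    pts: np.ndarray,
    shape: tuple[int, int],
    angle_deg: float,
) -> tuple[np.ndarray | None, np.ndarray, tuple[int, int]]:
    """Rotate image and contour together about the canvas center.

    The canvas is re-fit (expanded) exactly as ``scipy.ndimage.rotate``
    with ``reshape=True`` does, so the nodule is never cropped.
    """
    h, w = shape
    phi = np.deg2rad(angle_deg)
    c, s = np.cos(phi), np.sin(phi)
    # new canvas size, matching scipy's reshape computation
    nw = int(np.round(abs(w * c) + abs(h * s)))
    nh = int(np.round(abs(w * s) + abs(h * c)))
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    ncx, ncy = (nw - 1) / 2.0, (nh - 1) / 2.0
    x = pts[:, 0] - cx
    y_up = -(pts[:, 1] - cy)
    xr = c * x - s * y_up
    yr = s * x + c * y_up
    new_pts = np.column_stack([xr + ncx, -yr + ncy])
    if image is not None:
        # positive angle = counterclockwise in the y-up display frame;
        # interpolate in float so binary masks keep a subpixel edge ramp
        image = ndimage.rotate(image.astype(float), -angle_deg, reshape=True, order=1)
    return image, new_pts, (nh, nw)


def augment_case(
    image: np.ndarray | None,
    contour: NoduleContour,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray | None, NoduleContour, dict]:
    """Apply one stochastic draw of the flip/rotate/blur pipeline.

    Returns the transformed image (None stays None), the transformed
    contour, and an op log recording which operations fired with which
    parameters.
    """
    if contour.image_size is not None:
        w, h = contour.image_size
    elif image is not None:
        h, w = image.shape[:2]
    else:
        # no canvas known: use the contour's own bounding box
        w = int(np.ceil(contour.points[:, 0].max())) + 1
        h = int(np.ceil(contour.points[:, 1].max())) + 1
    pts = np.array(contour.points)
    log: dict = {"flip_h": False, "flip_v": False, "rotate_deg": None, "blur_sigma": None}

    if rng.random() < config.p_flip_h:
        pts[:, 0] = (w - 1) - pts[:, 0]
        if image is not None:
            image = image[:, ::-1]
        log["flip_h"] = True
    if rng.random() < config.p_flip_v:
        pts[:, 1] = (h - 1) - pts[:, 1]
        if image is not None:
            image = image[::-1, :]
        log["flip_v"] = True
    if rng.random() < config.p_rotate:
        angle = float(rng.uniform(*config.rotate_range_deg))
        image, pts, (h, w) = _rotate_pair(image, pts, (h, w), angle)
        log["rotate_deg"] = angle
    if rng.random() < config.p_blur:
        sigma = float(rng.uniform(*config.blur_sigma_range))
        if image is not None:
            image = ndimage.gaussian_filter(image.astype(float), sigma)
        log["blur_sigma"] = sigma

    out = NoduleContour(pts, source=contour.source, image_size=(w, h))
    return image, out, log


def balance_and_augment(
    cases: list[CaseRecord],
    config: AugmentationConfig,
    keep_images: bool = False,
) -> list[AugmentedCase]:
    """Grow each class to exactly ``target_per_class`` rows.

    All original nodules are retained; the remainder is generated by
    cycling over each class's originals and applying fresh stochastic
    draws.  Augmented rows are tagged with their source case id and the
    op log of the draw that produced them.
    """
    by_class: dict[int, list[tuple[CaseRecord, NoduleContour]]] = {0: [], 1: []}
    for case in cases:
        if case.label not in (0, 1):
            raise ValueError(f"case {case.case_id} has no binary label")
        for contour in case.contours:
            by_class[case.label].append((case, contour))
    target = config.target_per_class
    largest = max(len(v) for v in by_class.values() if v)
    if target < largest:
        raise ConfigError(
            f"target_per_class={target} below the largest original class ({largest})"
        )
    rng = np.random.default_rng(config.seed)
    out: list[AugmentedCase] = []
    for label, members in sorted(by_class.items()):
        if not members:
            continue
        for case, contour in members:
            out.append(
                AugmentedCase(
                    case_id=case.case_id,
                    source_case_id=case.case_id,
                    source_tag="original",
                    contour=contour,
                    label=label,
                    image=case.mask if keep_images else None,
                )
            )
        n_needed = target - len(members)
        for k in range(n_needed):
            case, contour = members[k % len(members)]
            image = case.mask if case.mask is not None else None
            aug_image, aug_contour, log = augment_case(image, contour, config, rng)
            out.append(
                AugmentedCase(
                    case_id=f"{case.case_id}-aug{k:05d}",
                    source_case_id=case.case_id,
                    source_tag="augmented",
                    contour=aug_contour,
                    label=label,
                    image=aug_image if keep_images else None,
                    op_log=log,
                )
            )
    return out


def augmented_feature_table(
    rows: list[AugmentedCase],
    geometry_config=None,
    drop_feature_duplicates: bool = False,
):
    """Extract one labeled feature row per augmented-cohort member.

    With ``drop_feature_duplicates`` rows whose op log shows that no
    geometric operation fired (blur-only or no-op draws, whose features
    exactly duplicate their source) are skipped.
    """
    import pandas as pd

    from .dataset_io import TABLE_COLUMNS, validate_feature_table
    from .features import extract_feature_vector
    from .geometry import DEFAULT_CONFIG

    cfg = geometry_config or DEFAULT_CONFIG
    records = []
    for row in rows:
        if drop_feature_duplicates and row.op_log is not None:
            geometric = (
                row.op_log["flip_h"]
                or row.op_log["flip_v"]
                or row.op_log["rotate_deg"] is not None
            )
            if not geometric:
                continue
        # the table's case_id is the SOURCE case: augmented siblings share
        # it, which is what a group-aware split needs to group on
        rec: dict = {"case_id": row.source_case_id, "source_tag": row.source_tag}
        rec.update(extract_feature_vector(row.contour, cfg).as_row())
        rec["label"] = row.label
        records.append(rec)
    df = pd.DataFrame(records, columns=list(TABLE_COLUMNS))
    validate_feature_table(df)
    return df
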