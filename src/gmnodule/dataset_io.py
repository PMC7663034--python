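"""Reading case annotations and reading/writing labeled feature tables.

Annotations follow the DDTI convention: one XML file per case with a
``<number>`` (case id), an optional ``<tirads>`` category, and one
``<mark>`` per annotated nodule whose ``<svg>`` element holds a JSON
array of polygons, each a list of ``{"x": int, "y": int}`` boundary
points.  TIRADS categories are collapsed to a binary label
(0 = benign, 1 = malignant) for classification.

Feature tables are plain CSV: ``case_id``, ``source_tag``
(original/augmented), 28 numeric feature columns (the 27 features with
the centroid flattened to two columns) and a binary ``label``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from lxml import etree

from .contour import NoduleContour
from .errors import GMNoduleError, SchemaError
from .features import FEATURE_NAMES, extract_feature_vector
from .geometry import DEFAULT_CONFIG, GeometryConfig

__all__ = [
    "CaseRecord",
    "DEFAULT_TIRADS_MAPPING",
    "FEATURE_COLUMNS",
    "TABLE_COLUMNS",
    "parse_annotation_xml",
    "write_annotation_xml",
    "map_tirads_to_binary",
    "extract_feature_table",
    "write_feature_table",
    "read_feature_table",
    "validate_feature_table",
]

#: Default collapse of TIRADS categories to benign (0) / malignant (1).
#: Overridable: institutions differ on where 4a belongs.
DEFAULT_TIRADS_MAPPING: dict[str, int] = {
    "2": 0,
    "3": 0,
    "4a": 1,
    "4b": 1,
    "4c": 1,
    "5": 1,
}

#: The 28 numeric feature columns of a labeled table, in fixed order.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    col
    for name in FEATURE_NAMES
    for col in (("centroid_x", "centroid_y") if name == "centroid" else (name,))
)

TABLE_COLUMNS: tuple[str, ...] = ("case_id", "source_tag") + FEATURE_COLUMNS + ("label",)


@dataclass
class CaseRecord:
    """One annotated case: contours plus its TIRADS-derived label."""

    case_id: str
    contours: list[NoduleContour]
    tirads_category: str | None = None
    label: int | None = None
    image_ref: str | None = None
    mask: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def map_tirads_to_binary(
    category: str, mapping: Mapping[str, int] = DEFAULT_TIRADS_MAPPING
) -> int:
    """Collapse a TIRADS category to a binary benign/malignant label."""
    key = str(category).strip().lower()
    if key not in mapping:
        raise GMNoduleError(f"unmapped TIRADS category {category!r}")
    return int(mapping[key])


def parse_annotation_xml(
    path: str | Path,
    *,
    auto_label: bool = True,
    mapping: Mapping[str, int] = DEFAULT_TIRADS_MAPPING,
) -> CaseRecord:
    """Read one DDTI-style XML annotation into a :class:`CaseRecord`.

    Coordinate lists with fewer than 3 points are skipped with a warning;
    if none remain the parse fails.  When ``auto_label`` is set and a
    TIRADS element is present, the binary label is derived from it;
    requesting auto-labeling without a TIRADS element is an error.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise GMNoduleError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    number = root.findtext("number")
    case_id = number.strip() if number else path.stem
    tirads = root.findtext("tirads")
    tirads = tirads.strip() if tirads and tirads.strip() else None

    contours: list[NoduleContour] = []
    for mark in root.iter("mark"):
        svg_text = mark.findtext("svg")
        if not svg_text or not svg_text.strip():
            continue
        for poly in json.loads(svg_text):
            pts = [(float(p["x"]), float(p["y"])) for p in poly["points"]]
            if len(pts) < 3:
                warnings.warn(
                    f"{path}: skipping coordinate list with {len(pts)} points",
                    stacklevel=2,
                )
                continue
            contours.append(NoduleContour(pts, source="polygon-annotation"))
    if not contours:
        raise GMNoduleError(f"{path}: no usable coordinate list")

    label: int | None = None
    if auto_label:
        if tirads is None:
            raise GMNoduleError(
                f"{path}: auto-labeling requested but no TIRADS element present"
            )
        label = map_tirads_to_binary(tirads, mapping)
    return CaseRecord(
        case_id=case_id, contours=contours, tirads_category=tirads, label=label
    )


def write_annotation_xml(case: CaseRecord, path: str | Path) -> None:
    """Serialize a case to the DDTI-style XML dialect (lossless coords)."""
    root = etree.Element("case")
    etree.SubElement(root, "number").text = case.case_id
    if case.tirads_category is not None:
        etree.SubElement(root, "tirads").text = case.tirads_category
    for contour in case.contours:
        mark = etree.SubElement(root, "mark")
        points = [{"x": x, "y": y} for x, y in contour.points.tolist()]
        etree.SubElement(mark, "svg").text = json.dumps([{"points": points}])
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def extract_feature_table(
    cases: Iterable[CaseRecord],
    config: GeometryConfig = DEFAULT_CONFIG,
    source_tag: str = "original",
) -> pd.DataFrame:
    """Extract one labeled feature row per annotated nodule."""
    rows = []
    for case in cases:
        if case.label is None:
            raise GMNoduleError(f"case {case.case_id}: no label")
        for contour in case.contours:
            try:
                fv = extract_feature_vector(contour, config)
            except GMNoduleError as exc:
                raise GMNoduleError(f"case {case.case_id}: {exc}") from exc
            row: dict[str, object] = {
                "case_id": case.case_id,
                "source_tag": source_tag,
            }
            row.update(fv.as_row())
            row["label"] = int(case.label)
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    validate_feature_table(df)
    return df


def validate_feature_table(df: pd.DataFrame) -> None:
    """Check schema, completeness and binary labels; raise SchemaError."""
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"schema mismatch: missing columns {missing}")
    if df[list(FEATURE_COLUMNS)].isna().any().any():
        raise SchemaError("schema mismatch: missing feature values")
    labels = set(df["label"].unique().tolist())
    if not labels <= {0, 1}:
        raise SchemaError("schema mismatch: label not binary")


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled feature table as comma-delimited UTF-8 CSV.

    Floats are written with 17 significant digits so a read round-trip
    reproduces every value bit-exactly.
    """
    validate_feature_table(df)
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a labeled feature table written by this package."""
    df = pd.read_csv(path, encoding="utf-8")
    validate_feature_table(df)
    df["label"] = df["label"].astype(int)
    return df
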