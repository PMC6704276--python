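"""Laser-microdissection XML export of ROI shapes and calibration points.

The LMD instrument imports cut shapes from an XML file together with three
calibration (teaching) points.  One teaching point acts as the origin: every
other coordinate — the two remaining landmarks and all ROI vertices — is
re-expressed relative to it and rounded to integers.  During import the same
three points are clicked in the instrument's live image, which anchors the
relative coordinates on the stage.

Schema (frozen so golden-file tests are bit-exact): root ``ImageData``
containing ``GlobalCoordinates``, ``X_CalibrationPoint_i``/``Y_CalibrationPoint_i``
for i = 1..3, ``ShapeCount``, and per shape a ``Shape_i`` element with
``PointCount`` and ``X_j``/``Y_j`` vertex elements.  Coordinates are emitted
y-down (image convention); ``flip_y`` mirrors the y axis for instruments
expecting y-up.
"""

from __future__ import annotations

import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import DegenerateGeometryError
from .roi import RoiBoundarySet

logger = logging.getLogger(__name__)


class LmdSchemaError(ValueError):
    """The XML file does not conform to the LMD shape-import schema."""


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


@dataclass
class TeachingPoints:
    """Three landmarks in the optical frame; the first is the origin."""

    origin: tuple[float, float]
    landmark_2: tuple[float, float]
    landmark_3: tuple[float, float]

    def __post_init__(self) -> None:
        p, q, r = (np.asarray(v, float) for v in (self.origin, self.landmark_2, self.landmark_3))
        area = 0.5 * abs((q[0] - p[0]) * (r[1] - p[1]) - (r[0] - p[0]) * (q[1] - p[1]))
        if area <= 1e-9:
            raise DegenerateGeometryError("teaching points are collinear")

    @classmethod
    def read_csv(cls, path: str | Path) -> "TeachingPoints":
        """Read 3 rows of ``x,y`` (header optional)."""
        rows = []
        for line in Path(path).read_text().splitlines():
            fields = line.replace(",", "\t").split()
            try:
                rows.append((float(fields[0]), float(fields[1])))
            except (ValueError, IndexError):
                continue  # header or blank line
        if len(rows) != 3:
            raise ValueError(f"{path}: expected 3 teaching points, found {len(rows)}")
        return cls(rows[0], rows[1], rows[2])


@dataclass
class LmdDocument:
    """Calibration points plus closed integer-vertex shapes, export-ready."""

    calibration_points: list  # 3 integer (x, y) pairs
    shapes: list  # (segment_id, [(x, y), ...] closed integer vertex list)
    global_coordinates_flag: bool = True

    def __post_init__(self) -> None:
        if len(self.calibration_points) != 3:
            raise ValueError("exactly 3 calibration points are required")
        self.calibration_points = [(int(x), int(y)) for x, y in self.calibration_points]
        norm = []
        for seg_id, verts in self.shapes:
            verts = [(int(x), int(y)) for x, y in verts]
            if not verts:
                raise ValueError("every shape needs at least one vertex")
            if verts[0] != verts[-1]:
                raise ValueError("every shape must be closed")
            norm.append((int(seg_id), verts))
        self.shapes = norm


def to_lmd_coordinates(
    boundaries: RoiBoundarySet | Sequence[RoiBoundarySet],
    tp: TeachingPoints,
    flip_y: bool = False,
) -> LmdDocument:
    """Re-express boundary vertices and teaching points relative to the origin.

    ``boundaries`` must already be in the optical frame (chain transforms
    first).  Every vertex and the two non-origin landmarks are translated by
    ``−origin`` (the origin maps to (0, 0)) and rounded with
    ``floor(v + 0.5)``.
    """
    if isinstance(boundaries, RoiBoundarySet):
        boundaries = [boundaries]
    ox, oy = tp.origin
    ysign = -1.0 if flip_y else 1.0

    def rel(p: Sequence[float]) -> tuple[int, int]:
        return (_round_half_up(p[0] - ox), _round_half_up(ysign * (p[1] - oy)))

    calibration = [rel(tp.origin), rel(tp.landmark_2), rel(tp.landmark_3)]
    shapes = []
    for bset in boundaries:
        for poly in bset.polygons:
            shapes.append((bset.segment_id, [rel(v) for v in poly]))
    return LmdDocument(calibration_points=calibration, shapes=shapes)


def write_lmd_xml(doc: LmdDocument, path: str | Path) -> None:
    """Serialize to the LMD import schema; byte-deterministic UTF-8 output."""
    root = ET.Element("ImageData")
    ET.SubElement(root, "GlobalCoordinates").text = (
        "1" if doc.global_coordinates_flag else "0"
    )
    for i, (x, y) in enumerate(doc.calibration_points, start=1):
        ET.SubElement(root, f"X_CalibrationPoint_{i}").text = str(x)
        ET.SubElement(root, f"Y_CalibrationPoint_{i}").text = str(y)
    ET.SubElement(root, "ShapeCount").text = str(len(doc.shapes))
    for i, (seg_id, verts) in enumerate(doc.shapes, start=1):
        shape = ET.SubElement(root, f"Shape_{i}")
        ET.SubElement(shape, "PointCount").text = str(len(verts))
        ET.SubElement(shape, "CapID").text = str(seg_id)
        for j, (x, y) in enumerate(verts, start=1):
            ET.SubElement(shape, f"X_{j}").text = str(x)
            ET.SubElement(shape, f"Y_{j}").text = str(y)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), encoding="utf-8", xml_declaration=True)


def _require(parent: ET.Element, tag: str) -> str:
    el = parent.find(tag)
    if el is None or el.text is None:
        raise LmdSchemaError(f"missing element: {tag}")
    return el.text.strip()


def read_lmd_xml(path: str | Path) -> LmdDocument:
    """Parse an LMD shape-import XML file back into an :class:`LmdDocument`.

    Unknown elements are ignored with a warning; a missing calibration point
    or a ``ShapeCount``/``PointCount`` mismatch raises :class:`LmdSchemaError`
    naming the offending element.
    """
    root = ET.parse(str(path)).getroot()
    if root.tag != "ImageData":
        raise LmdSchemaError(f"root element must be ImageData, got {root.tag}")
    flag = _require(root, "GlobalCoordinates") == "1"
    calibration = [
        (int(_require(root, f"X_CalibrationPoint_{i}")),
         int(_require(root, f"Y_CalibrationPoint_{i}")))
        for i in (1, 2, 3)
    ]
    shape_count = int(_require(root, "ShapeCount"))
    shapes = []
    for i in range(1, shape_count + 1):
        shape = root.find(f"Shape_{i}")
        if shape is None:
            raise LmdSchemaError(f"ShapeCount is {shape_count} but Shape_{i} is missing")
        point_count = int(_require(shape, "PointCount"))
        cap = shape.find("CapID")
        seg_id = int(cap.text) if cap is not None and cap.text else i
        verts = []
        for j in range(1, point_count + 1):
            verts.append((int(_require(shape, f"X_{j}")), int(_require(shape, f"Y_{j}"))))
        shapes.append((seg_id, verts))
    known = {"GlobalCoordinates", "ShapeCount"}
    known.update(f"{ax}_CalibrationPoint_{i}" for ax in "XY" for i in (1, 2, 3))
    known.update(f"Shape_{i}" for i in range(1, shape_count + 1))
    for child in root:
        if child.tag not in known:
            warnings.warn(f"ignoring unknown element {child.tag}", stacklevel=2)
    return LmdDocument(calibration_points=calibration, shapes=shapes,
                       global_coordinates_flag=flag)
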