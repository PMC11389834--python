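"""Read and write Icy-dialect ROI XML and convert to/from PlantMap tables.

Icy (https://icy.bioimageanalysis.org) stores traced regions of interest as a
small XML dialect::

    <root>
      <roi>
        <classname>plugins.kernel.roi.roi2d.ROI2DPolygon</classname>
        <id>17</id>
        <name>C1</name>
        <points>
          <point><pos_x>12.0</pos_x><pos_y>34.5</pos_y></point>
          ...
        </points>
      </roi>
      ...
    </root>

Only 2-D polygon ROIs (class name ending in ``ROI2DPolygon``) are converted;
rectangles, ellipses and lines are skipped with a warning.  ``ROI.id`` is
assigned by document order starting at 1 — integer ids in the source file are
ignored so that ids are always a clean, duplicate-free 1..n sequence.  Element
names are configurable through :class:`IcySchema` for near-dialect files.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .map_model import (
    CORE_COLUMNS,
    POINT,
    ROI_ID,
    ROI_NAME,
    X,
    Y,
    ROIPolygon,
    assert_valid_map,
    map_from_polygons,
    polygons_from_map,
)

logger = logging.getLogger(__name__)

#: Class name written for polygon ROIs (the suffix is what the parser keys on).
POLYGON_CLASS = "plugins.kernel.roi.roi2d.ROI2DPolygon"


class XMLParseError(ValueError):
    """Malformed XML; the message carries the line/column reported by the parser."""


class EmptyDocumentError(ValueError):
    """No polygon ROI survived filtering."""


@dataclass(frozen=True)
class IcySchema:
    """Element names of the Icy ROI dialect (override for near-dialects)."""

    roi_tag: str = "roi"
    classname_tag: str = "classname"
    name_tag: str = "name"
    id_tag: str = "id"
    points_tag: str = "points"
    point_tag: str = "point"
    pos_x_tag: str = "pos_x"
    pos_y_tag: str = "pos_y"
    polygon_class_suffix: str = "ROI2DPolygon"


DEFAULT_SCHEMA = IcySchema()


@dataclass
class ParseReport:
    """What the parser read, skipped and warned about."""

    n_polygons: int = 0
    n_skipped: int = 0
    warnings: list[str] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        logger.warning(msg)


def parse_icy_xml_with_report(
    source,
    *,
    strict: bool = False,
    schema: IcySchema = DEFAULT_SCHEMA,
) -> tuple[pd.DataFrame, ParseReport]:
    """Parse an Icy ROI XML file into a PlantMap plus a :class:`ParseReport`.

    Parameters
    ----------
    source :
        Path, bytes, or readable binary stream containing the document.
    strict :
        If true, a polygon with fewer than 3 distinct points is an error
        instead of a skip-with-warning.
    schema :
        Element names of the dialect.

    Returns
    -------
    (map, report) :
        ``map`` passes ``validate_map``; ROI order equals document order;
        names are whitespace-trimmed; unnamed ROIs are called ``ROI.<id>``.

    Raises
    ------
    XMLParseError
        On malformed XML (message includes line number).
    EmptyDocumentError
        When no polygon ROI remains after filtering.
    """
    report = ParseReport()
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        raise XMLParseError(f"malformed XML: {exc}") from exc
    root = tree.getroot()

    polygons: list[ROIPolygon] = []
    next_id = 1
    for elem in root.iter(schema.roi_tag):
        cls = (elem.findtext(schema.classname_tag) or "").strip()
        if not cls.endswith(schema.polygon_class_suffix):
            report.n_skipped += 1
            report.warn(f"skipping non-polygon ROI of class {cls or '<none>'!r}")
            continue
        name = (elem.findtext(schema.name_tag) or "").strip()
        point_lists = elem.findall(schema.points_tag)
        if len(point_lists) > 1:
            report.warn(
                f"ROI {name or next_id!r} carries {len(point_lists)} contours; "
                "only the first is read (holes unsupported)"
            )
        pts = _read_points(point_lists[0], schema) if point_lists else np.empty((0, 2))
        if not name:
            name = f"ROI.{next_id}"
            report.warn(f"unnamed polygon ROI assigned name {name!r}")
        try:
            poly = ROIPolygon(name=name, roi_id=next_id, points=pts)
        except ValueError as exc:
            if strict:
                raise
            report.n_skipped += 1
            report.warn(f"skipping degenerate polygon ROI {name!r}: {exc}")
            continue
        polygons.append(poly)
        next_id += 1
        report.n_polygons += 1

    if not polygons:
        raise EmptyDocumentError("document contains no usable polygon ROI")
    return map_from_polygons(polygons), report


def parse_icy_xml(source, *, strict: bool = False, schema: IcySchema = DEFAULT_SCHEMA) -> pd.DataFrame:
    """Convert Icy ROI XML to a PlantMap table (see :func:`parse_icy_xml_with_report`)."""
    map_df, _ = parse_icy_xml_with_report(source, strict=strict, schema=schema)
    return map_df


def _read_points(points_elem, schema: IcySchema) -> np.ndarray:
    xs, ys = [], []
    for pt in points_elem.findall(schema.point_tag):
        x_text = pt.findtext(schema.pos_x_tag)
        y_text = pt.findtext(schema.pos_y_tag)
        if x_text is None or y_text is None:
            raise XMLParseError("point element lacks position coordinates")
        x, y = float(x_text), float(y_text)
        if not (np.isfinite(x) and np.isfinite(y)):
            raise XMLParseError(f"non-finite point position ({x_text}, {y_text})")
        xs.append(x)
        ys.append(y)
    return np.column_stack([xs, ys]) if xs else np.empty((0, 2))


def write_icy_xml(map_df: pd.DataFrame, path, *, schema: IcySchema = DEFAULT_SCHEMA) -> None:
    """Write a PlantMap as an Icy ROI XML document (inverse of :func:`parse_icy_xml`).

    One polygon ROI element is emitted per ``ROI.id`` in first-appearance
    order; re-parsing recovers an equal map (names byte-equal under UTF-8,
    coordinates to full ``repr`` precision).  Extra attribute columns are not
    representable in the dialect and are dropped (Icy knows nothing of them).

    Raises ``ValueError`` listing all violations if the map is invalid.
    """
    assert_valid_map(map_df)
    root = ET.Element("root")
    for poly in polygons_from_map(map_df):
        roi = ET.SubElement(root, schema.roi_tag)
        ET.SubElement(roi, schema.classname_tag).text = POLYGON_CLASS
        ET.SubElement(roi, schema.id_tag).text = str(poly.roi_id)
        ET.SubElement(roi, schema.name_tag).text = poly.name
        pts = ET.SubElement(roi, schema.points_tag)
        for x, y in poly.points:
            pt = ET.SubElement(pts, schema.point_tag)
            ET.SubElement(pt, schema.pos_x_tag).text = repr(float(x))
            ET.SubElement(pt, schema.pos_y_tag).text = repr(float(y))
    ET.indent(root)
    tree = ET.ElementTree(root)
    if hasattr(path, "write"):
        tree.write(path, encoding="utf-8", xml_declaration=True)
    else:
        tmp = f"{os.fspath(path)}.tmp"
        tree.write(tmp, encoding="utf-8", xml_declaration=True)
        os.replace(tmp, path)


def split_name_levels(
    map_df: pd.DataFrame,
    separator: str,
    level_names: list[str],
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Split structured ROI names into extra attribute columns.

    A naming convention like ``SAM.CZ.L1`` encodes several anatomical levels
    in one string; this expands them into columns (e.g. ``Organ``, ``Zone``,
    ``Layer``), constant per ROI, keeping the original ``ROI.name``.  Names
    with the wrong number of separators raise in strict mode; otherwise their
    added columns are left missing.
    """
    if not level_names:
        raise ValueError("level_names must be non-empty")
    out = map_df.copy()
    tokens_by_id: dict[int, list[str] | None] = {}
    for roi_id, grp in map_df.groupby(ROI_ID, sort=False):
        name = str(grp[ROI_NAME].iloc[0]).strip()
        parts = name.split(separator)
        if len(parts) != len(level_names):
            if strict:
                raise ValueError(
                    f"ROI.id {int(roi_id)}: name {name!r} splits into {len(parts)} "
                    f"token(s), expected {len(level_names)}"
                )
            tokens_by_id[int(roi_id)] = None
        else:
            tokens_by_id[int(roi_id)] = parts
    for i, col in enumerate(level_names):
        out[col] = [
            (tokens_by_id[int(rid)][i] if tokens_by_id[int(rid)] is not None else pd.NA)
            for rid in out[ROI_ID]
        ]
    return out
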