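"""Core data model for plant tissue maps.

A *PlantMap* is a long-format :class:`pandas.DataFrame` in which each row is
one vertex of one traced region of interest (ROI) polygon.  The five core
columns are

``ROI.name``
    text label of the tissue level the ROI belongs to (many ROIs may share a
    name — e.g. every cell of the outermost cortex layer is ``C1``);
``ROI.id``
    positive integer identifying one polygon, unique within a map;
``point``
    1-based vertex ordinal within its ROI, consecutive without gaps;
``x``, ``y``
    planar coordinates in image pixel units, *y increasing downward* (image
    convention — coordinates are stored exactly as traced, orientation is a
    rendering concern).

Extra columns (e.g. anatomical ``Zone`` or ``Layer`` annotations) are allowed
and must be constant within each ROI.  This module defines the schema,
validation, polygon geometry (shoelace area / centroid) and CSV interchange.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The five mandatory columns of a PlantMap table, in canonical order.
CORE_COLUMNS: tuple[str, ...] = ("ROI.name", "ROI.id", "point", "x", "y")

ROI_NAME, ROI_ID, POINT, X, Y = CORE_COLUMNS


class SchemaError(ValueError):
    """A required column is missing or has the wrong form."""


class DegeneratePolygonError(ValueError):
    """Polygon has fewer than 3 distinct vertices or zero area where one is required."""


@dataclass(frozen=True)
class ROIPolygon:
    """One named, ordered, closed polygon traced on an image.

    Parameters
    ----------
    name :
        Tissue-level label; stripped of surrounding whitespace, must be
        non-empty afterwards.
    roi_id :
        Positive integer identifier, unique within one map.
    points :
        Ordered ``(n, 2)`` array of (x, y) vertices, n >= 3 after removal of
        consecutive duplicates.  The closing edge (last -> first vertex) is
        implicit.
    """

    name: str
    roi_id: int
    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        name = self.name.strip()
        if not name:
            raise ValueError("ROI name must be non-empty after whitespace trimming")
        object.__setattr__(self, "name", name)
        if int(self.roi_id) < 1:
            raise ValueError(f"roi_id must be >= 1, got {self.roi_id}")
        object.__setattr__(self, "roi_id", int(self.roi_id))
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be an (n, 2) array, got shape {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("polygon vertices must be finite")
        pts = _drop_consecutive_duplicates(pts)
        if len(pts) < 3:
            raise DegeneratePolygonError(
                f"ROI {self.roi_id!r} ({name!r}) has fewer than 3 distinct points"
            )
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)


def _drop_consecutive_duplicates(pts: np.ndarray) -> np.ndarray:
    """Remove vertices equal to their predecessor (incl. a repeated closing vertex)."""
    if len(pts) == 0:
        return pts
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = (np.abs(np.diff(pts, axis=0)) > 0).any(axis=1)
    pts = pts[keep]
    # an explicitly closed ring repeats the first vertex at the end — drop it
    if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    return np.ascontiguousarray(pts)


# ---------------------------------------------------------------------------
# polygon geometry (shoelace formulas)
# ---------------------------------------------------------------------------

def polygon_signed_area(p: ROIPolygon | np.ndarray) -> float:
    """Signed shoelace area; positive for counter-clockwise vertex order
    in a y-up frame (clockwise in the y-down image frame)."""
    pts = p.points if isinstance(p, ROIPolygon) else np.asarray(p, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(p: ROIPolygon | np.ndarray) -> float:
    """Absolute area of a simple closed polygon in pixel² units.

    Orientation-independent: traversing the ring in either direction gives
    the same value.

    Raises
    ------
    DegeneratePolygonError
        If fewer than 3 distinct vertices remain after normalisation.
    """
    if not isinstance(p, ROIPolygon):
        p = ROIPolygon("_", 1, np.asarray(p, dtype=float))
    return abs(polygon_signed_area(p))


def polygon_centroid(p: ROIPolygon | np.ndarray) -> tuple[float, float]:
    """Area-weighted centroid of a simple closed polygon.

    Uses the standard shoelace centroid formulas
    ``Cx = 1/(6A) * sum (x_i + x_{i+1}) (x_i y_{i+1} - x_{i+1} y_i)`` (and the
    y analogue), which weight by enclosed area rather than by vertex density.

    Raises
    ------
    DegeneratePolygonError
        If the polygon has zero area (collinear vertices).
    """
    if not isinstance(p, ROIPolygon):
        p = ROIPolygon("_", 1, np.asarray(p, dtype=float))
    pts = p.points
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if math.isclose(a, 0.0, abs_tol=1e-12):
        raise DegeneratePolygonError(
            f"ROI {p.roi_id!r} ({p.name!r}) has zero area; centroid undefined"
        )
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return cx, cy


# ---------------------------------------------------------------------------
# PlantMap table <-> polygons
# ---------------------------------------------------------------------------

def require_columns(df: pd.DataFrame, columns: Iterable[str], what: str = "table") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def polygons_from_map(map_df: pd.DataFrame) -> list[ROIPolygon]:
    """Materialise one :class:`ROIPolygon` per ``ROI.id``, in first-appearance order."""
    require_columns(map_df, CORE_COLUMNS, "PlantMap")
    out: list[ROIPolygon] = []
    for roi_id, grp in map_df.groupby(ROI_ID, sort=False):
        grp = grp.sort_values(POINT)
        out.append(
            ROIPolygon(
                name=str(grp[ROI_NAME].iloc[0]),
                roi_id=int(roi_id),
                points=grp[[X, Y]].to_numpy(dtype=float),
            )
        )
    return out


def map_from_polygons(
    polygons: Sequence[ROIPolygon],
    attrs: Mapping[int, Mapping[str, object]] | None = None,
) -> pd.DataFrame:
    """Assemble a PlantMap table from polygons (inverse of :func:`polygons_from_map`).

    ``attrs`` optionally supplies extra per-ROI columns keyed by roi_id; each
    is replicated onto every vertex row of that ROI.
    """
    frames = []
    for p in polygons:
        rec = {
            ROI_NAME: p.name,
            ROI_ID: p.roi_id,
            POINT: np.arange(1, p.n_points + 1),
            X: p.points[:, 0],
            Y: p.points[:, 1],
        }
        if attrs and p.roi_id in attrs:
            for k, v in attrs[p.roi_id].items():
                rec[k] = v
        frames.append(pd.DataFrame(rec))
    if not frames:
        return pd.DataFrame(columns=list(CORE_COLUMNS))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_map`."""

    rule: str
    roi_id: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" (ROI.id={self.roi_id})" if self.roi_id is not None else ""
        return f"{self.rule}{where}: {self.message}"


def validate_map(map_df: pd.DataFrame) -> list[Violation]:
    """Check every PlantMap invariant; return all violations (empty = valid).

    Content problems are *reported*, never raised; only a structurally
    unreadable table (missing core columns) raises :class:`SchemaError`.

    Rules checked, each tagged with the ``rule`` name used in the report:

    - ``point-ordinal gap``: within each ROI, ``point`` must be exactly 1..k;
    - ``name not constant within ROI``: one roi_id, one name;
    - ``empty name``: names blank after trimming;
    - ``non-positive roi_id``;
    - ``too few points``: fewer than 3 vertices;
    - ``non-finite coordinate``;
    - ``attribute not constant within ROI``: extra columns must be per-ROI.
    """
    require_columns(map_df, CORE_COLUMNS, "PlantMap")
    violations: list[Violation] = []
    extra_cols = [c for c in map_df.columns if c not in CORE_COLUMNS]

    for roi_id, grp in map_df.groupby(ROI_ID, sort=False):
        rid = int(roi_id) if float(roi_id) == int(roi_id) else roi_id
        names = grp[ROI_NAME].astype(str).str.strip().unique()
        if len(names) > 1:
            violations.append(
                Violation("name not constant within ROI", rid,
                          f"names {sorted(names)!r} share ROI.id {rid}")
            )
        if any(n == "" for n in names):
            violations.append(Violation("empty name", rid, "ROI.name blank after trimming"))
        if not (isinstance(rid, int) and rid >= 1):
            violations.append(Violation("non-positive roi_id", None,
                                        f"ROI.id {roi_id!r} is not a positive integer"))
        pts = grp[POINT].to_numpy()
        expected = np.arange(1, len(pts) + 1)
        if not np.array_equal(pts, expected):
            violations.append(
                Violation("point-ordinal gap", rid,
                          f"point sequence {list(pts)[:8]}… is not 1..{len(pts)}")
            )
        if len(grp) < 3:
            violations.append(Violation("too few points", rid,
                                        f"only {len(grp)} point(s)"))
        xy = grp[[X, Y]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            violations.append(Violation("non-finite coordinate", rid,
                                        "x/y contain NaN or infinity"))
        for c in extra_cols:
            if grp[c].nunique(dropna=False) > 1:
                violations.append(
                    Violation("attribute not constant within ROI", rid,
                              f"column {c!r} varies within the ROI")
                )
    return violations


def assert_valid_map(map_df: pd.DataFrame, what: str = "PlantMap") -> None:
    """Raise ``ValueError`` listing every violation if the map is invalid."""
    violations = validate_map(map_df)
    if violations:
        lines = "\n  ".join(str(v) for v in violations)
        raise ValueError(f"invalid {what}:\n  {lines}")


# ---------------------------------------------------------------------------
# registry summary
# ---------------------------------------------------------------------------

def map_summary(registry: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Summarise a registry of named PlantMaps (one record per map).

    The registry key is expected to follow the ``<species>.<tissue...>``
    naming convention (e.g. ``Ms.root.crosssection``); species/tissue tags
    are derived from it and left empty when the name has no dots.

    Returns a table with columns ``name, species, tissue, n_rois, n_levels``.
    An empty registry yields an empty table.
    """
    records = []
    for name, df in registry.items():
        require_columns(df, CORE_COLUMNS, f"PlantMap {name!r}")
        parts = name.split(".")
        species = parts[0] if len(parts) > 1 else ""
        tissue = ".".join(parts[1:]) if len(parts) > 1 else ""
        records.append(
            {
                "name": name,
                "species": species,
                "tissue": tissue,
                "n_rois": int(df[ROI_ID].nunique()),
                "n_levels": int(df[ROI_NAME].astype(str).str.strip().nunique()),
            }
        )
    return pd.DataFrame(records, columns=["name", "species", "tissue", "n_rois", "n_levels"])


# ---------------------------------------------------------------------------
# delimited-text interchange
# ---------------------------------------------------------------------------

def read_map_csv(path) -> pd.DataFrame:
    """Read a PlantMap from CSV (UTF-8, header row mandatory, extra columns kept)."""
    df = pd.read_csv(path, encoding="utf-8")
    require_columns(df, CORE_COLUMNS, f"PlantMap file {path!r}")
    return df


def write_map_csv(map_df: pd.DataFrame, path) -> None:
    """Write a PlantMap to CSV with the canonical header ``ROI.name,ROI.id,point,x,y``
    first, extra columns after, UTF-8, no index."""
    require_columns(map_df, CORE_COLUMNS, "PlantMap")
    extra = [c for c in map_df.columns if c not in CORE_COLUMNS]
    map_df[list(CORE_COLUMNS) + extra].to_csv(path, index=False, encoding="utf-8")


def read_table_csv(path) -> pd.DataFrame:
    """Read a quantitative or merged table from CSV verbatim (UTF-8)."""
    return pd.read_csv(path, encoding="utf-8")


def write_table_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")
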