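"""Standalone SVG export with stable per-ROI identifiers.

Emits SVG 1.1 documents in which every ROI polygon is one ``<path>`` element
(``M x,y L x,y … Z``) carrying a stable ``id`` (default ``<ROI.name>.<ROI.id>``),
grouped into one ``<g>`` per tissue level so an eFP-style pipeline or a vector
editor can recolor a whole tissue with a single selector.  Coordinates are
written y-down — SVG shares the image convention, so no inversion happens
here (this intentionally differs from the raster renderer).

Numbers are printed with exactly 6 decimal places and a ``.`` separator,
independent of locale, so repeated exports are byte-identical and suitable
for golden-file comparison.
"""

from __future__ import annotations

import os
import re
from typing import Callable

import numpy as np
import pandas as pd

from . import colors as _colors
from .map_model import ROI_ID, assert_valid_map, polygons_from_map, require_columns
from .rendering import OUTLINE_COLOR, RenderSpec, heatmap_fills

SVG_NS = "http://www.w3.org/2000/svg"
UNIFORM_FILL = "#d9d9d9"

IdScheme = Callable[[str, int], str]


def default_id_scheme(roi_name: str, roi_id: int) -> str:
    return f"{roi_name}.{roi_id}"


def sanitize_class(name: str) -> str:
    """CSS class per level: non-alphanumerics become underscores."""
    return re.sub(r"[^0-9A-Za-z]", "_", name)


def _fmt(v: float) -> str:
    return f"{v:.6f}"


def _path_data(points: np.ndarray) -> str:
    head = f"M {_fmt(points[0, 0])},{_fmt(points[0, 1])}"
    rest = " ".join(f"L {_fmt(x)},{_fmt(y)}" for x, y in points[1:])
    return f"{head} {rest} Z"


def _emit(
    map_df: pd.DataFrame,
    path,
    fill_by_roi: dict[int, str],
    id_scheme: IdScheme,
    stroke_width: float,
) -> None:
    polygons = polygons_from_map(map_df)

    ids = [id_scheme(p.name, p.roi_id) for p in polygons]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"id scheme produces colliding path id(s): {sorted(dup)}")

    xy = map_df[["x", "y"]].to_numpy(dtype=float)
    (xmin, ymin), (xmax, ymax) = xy.min(axis=0), xy.max(axis=0)
    pad_x = 0.01 * (xmax - xmin or 1.0)
    pad_y = 0.01 * (ymax - ymin or 1.0)
    x0, y0 = xmin - pad_x, ymin - pad_y
    w, h = (xmax - xmin) + 2 * pad_x, (ymax - ymin) + 2 * pad_y

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="{SVG_NS}" version="1.1" '
        f'width="{_fmt(w)}" height="{_fmt(h)}" '
        f'viewBox="{_fmt(x0)} {_fmt(y0)} {_fmt(w)} {_fmt(h)}">',
    ]
    # group paths by level, levels in first-appearance order
    by_level: dict[str, list] = {}
    for p, pid in zip(polygons, ids):
        by_level.setdefault(p.name, []).append((p, pid))
    for level, members in by_level.items():
        cls = sanitize_class(level)
        lines.append(f'  <g id="level.{_xml_escape(level)}" class="{cls}">')
        for p, pid in members:
            lines.append(
                f'    <path id="{_xml_escape(pid)}" class="{cls}" '
                f'd="{_path_data(p.points)}" '
                f'fill="{fill_by_roi[p.roi_id]}" '
                f'stroke="{OUTLINE_COLOR}" stroke-width="{_fmt(stroke_width)}"/>'
            )
        lines.append("  </g>")
    lines.append("</svg>")
    text = "\n".join(lines) + "\n"

    if hasattr(path, "write"):
        path.write(text)
    else:
        tmp = f"{os.fspath(path)}.tmp"
        with open(tmp, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)


def _xml_escape(s: str) -> str:
    return (
        s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def to_svg(
    map_df: pd.DataFrame,
    path,
    fill_mode: str = "categorical",
    id_scheme: IdScheme = default_id_scheme,
    spec: RenderSpec | None = None,
) -> None:
    """Write a PlantMap as an SVG document.

    ``fill_mode='categorical'`` colors each level with the same deterministic
    palette assignment the raster renderer uses; ``'uniform'`` fills every
    path in light grey (for downstream recoloring pipelines that only need
    the geometry and the ids).
    """
    assert_valid_map(map_df)
    spec = spec or RenderSpec()
    if fill_mode == "categorical":
        level_by_roi = {p.roi_id: p.name for p in polygons_from_map(map_df)}
        palette = _colors.level_color_map(level_by_roi.values(), spec.categorical_palette)
        fill_by_roi = {rid: palette[lvl] for rid, lvl in level_by_roi.items()}
    elif fill_mode == "uniform":
        fill_by_roi = {p.roi_id: UNIFORM_FILL for p in polygons_from_map(map_df)}
    else:
        raise ValueError(f"fill_mode must be 'categorical' or 'uniform', got {fill_mode!r}")
    _emit(map_df, path, fill_by_roi, id_scheme, spec.linewidth)


def to_svg_heatmap(
    merged: pd.DataFrame,
    value_quant: str,
    path,
    spec: RenderSpec | None = None,
    vmin: float | None = None,
    vmax: float | None = None,
    id_scheme: IdScheme = default_id_scheme,
) -> None:
    """Write a MergedMap as a quantitative SVG heatmap.

    Per-path fill colors come from the exact same normalisation/palette
    routine as the raster heatmap (:func:`plantmap.rendering.heatmap_fills`),
    so vector and raster output agree on every ROI's color by construction.
    Missing values are filled with ``spec.na_color``.
    """
    require_columns(merged, [ROI_ID, value_quant], "merged map")
    assert_valid_map(merged, "merged map")
    spec = spec or RenderSpec()
    fills = heatmap_fills(merged, value_quant, spec, vmin, vmax)
    _emit(merged, path, fills, id_scheme, spec.linewidth)
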