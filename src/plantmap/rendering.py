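"""Render PlantMaps as categorical tissue maps and MergedMaps as heatmaps.

One filled matplotlib polygon patch is drawn per ROI.  Because traced
coordinates follow the image convention (y grows downward) the vertical axis
is inverted at render time so the figure matches the source image; the stored
table is never flipped.  Figures are built on plain
:class:`matplotlib.figure.Figure` objects (no pyplot, no global state).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from matplotlib.cm import ScalarMappable
from matplotlib.colors import Normalize, to_hex
from matplotlib.figure import Figure
from matplotlib.patches import Patch, Polygon

from . import colors as _colors
from .map_model import (
    ROI_ID,
    ROI_NAME,
    DegeneratePolygonError,
    polygon_area,
    polygon_centroid,
    polygons_from_map,
    require_columns,
)

logger = logging.getLogger(__name__)

OUTLINE_COLOR = "black"


@dataclass(frozen=True)
class RenderSpec:
    """Rendering options with the tool's documented defaults.

    layer
        Column used for categorical color mapping (default: the ROI name).
    show_legend
        Draw a legend (categorical) or colorbar (heatmap); default True.
    linewidth
        Polygon outline width in points; 0 removes outlines; default 1.
    """

    layer: str = ROI_NAME
    show_legend: bool = True
    linewidth: float = 1.0
    categorical_palette: str = _colors.DEFAULT_CATEGORICAL
    continuous_palette: str = _colors.DEFAULT_CONTINUOUS
    na_color: str = _colors.DEFAULT_NA_COLOR
    figsize: tuple[float, float] = (6.0, 6.0)
    dpi: int = 100

    def __post_init__(self) -> None:
        if self.linewidth < 0:
            raise ValueError(f"linewidth must be >= 0, got {self.linewidth}")

    def replace(self, **kw) -> "RenderSpec":
        return replace(self, **kw)


def _new_axes(spec: RenderSpec):
    fig = Figure(figsize=spec.figsize, dpi=spec.dpi)
    ax = fig.add_subplot(111)
    return fig, ax


def _finish_axes(ax, map_df: pd.DataFrame) -> None:
    """Equal aspect, padded limits, image orientation (y axis inverted)."""
    x, y = map_df["x"].to_numpy(float), map_df["y"].to_numpy(float)
    pad_x = 0.02 * (x.max() - x.min() or 1.0)
    pad_y = 0.02 * (y.max() - y.min() or 1.0)
    ax.set_xlim(x.min() - pad_x, x.max() + pad_x)
    ax.set_ylim(y.max() + pad_y, y.min() - pad_y)  # inverted: image y-down
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")


def _add_patches(ax, map_df: pd.DataFrame, fill_by_roi: dict[int, str], linewidth: float):
    for poly in polygons_from_map(map_df):
        ax.add_patch(
            Polygon(
                poly.points,
                closed=True,
                facecolor=fill_by_roi[poly.roi_id],
                edgecolor=OUTLINE_COLOR,
                linewidth=linewidth,
                label=f"{poly.name}.{poly.roi_id}",
            )
        )


def plot_map(map_df: pd.DataFrame, spec: RenderSpec | None = None, out=None) -> Figure:
    """Draw a categorical tissue map: one patch per ROI, filled by the ROI's
    value in ``spec.layer``, with one legend entry per distinct level.

    Returns the figure; also writes it to ``out`` when given (format by
    file extension: .png/.svg/.pdf).
    """
    spec = spec or RenderSpec()
    require_columns(map_df, [spec.layer], "map")
    if map_df.empty:
        raise ValueError("cannot plot an empty map")

    level_by_roi = {
        int(rid): str(grp[spec.layer].iloc[0])
        for rid, grp in map_df.groupby(ROI_ID, sort=False)
    }
    palette = _colors.level_color_map(level_by_roi.values(), spec.categorical_palette)
    fill_by_roi = {rid: palette[lvl] for rid, lvl in level_by_roi.items()}

    fig, ax = _new_axes(spec)
    _add_patches(ax, map_df, fill_by_roi, spec.linewidth)
    _finish_axes(ax, map_df)
    if spec.show_legend:
        handles = [Patch(facecolor=c, edgecolor=OUTLINE_COLOR, label=lvl)
                   for lvl, c in palette.items()]
        ax.legend(handles=handles, title=spec.layer, loc="center left",
                  bbox_to_anchor=(1.02, 0.5))
    if out is not None:
        fig.savefig(out, bbox_inches="tight")
    return fig


def heatmap_fills(
    merged: pd.DataFrame,
    value_quant: str,
    spec: RenderSpec,
    vmin: float | None = None,
    vmax: float | None = None,
) -> dict[int, str]:
    """Per-ROI hex fill for a merged map's value column (shared with SVG export)."""
    require_columns(merged, [ROI_ID, value_quant], "merged map")
    per_roi = (
        merged.groupby(ROI_ID, sort=False)[value_quant]
        .first()
    )
    hexes = _colors.continuous_colors(
        per_roi.to_numpy(dtype=float),
        palette=spec.continuous_palette,
        vmin=vmin,
        vmax=vmax,
        na_color=spec.na_color,
    )
    return {int(rid): h for rid, h in zip(per_roi.index, hexes)}


def plot_heatmap(
    merged: pd.DataFrame,
    value_quant: str,
    spec: RenderSpec | None = None,
    vmin: float | None = None,
    vmax: float | None = None,
    out=None,
) -> Figure:
    """Draw a quantitative choropleth: each ROI filled by its value in
    ``value_quant`` under min–max normalisation of the continuous palette.

    Missing values (unmatched levels) are filled with ``spec.na_color``.  A
    colorbar replaces the discrete legend when ``spec.show_legend``.  A
    constant value column renders in the palette midpoint color with a
    degenerate (zero-span) colorbar rather than failing.
    """
    spec = spec or RenderSpec()
    if merged.empty:
        raise ValueError("cannot plot an empty map")
    fills = heatmap_fills(merged, value_quant, spec, vmin, vmax)

    fig, ax = _new_axes(spec)
    _add_patches(ax, merged, fills, spec.linewidth)
    _finish_axes(ax, merged)
    if spec.show_legend:
        vals = merged[value_quant].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        lo = float(finite.min()) if vmin is None else vmin
        hi = float(finite.max()) if vmax is None else vmax
        sm = ScalarMappable(norm=Normalize(lo, hi if hi > lo else lo + 1e-12),
                            cmap=spec.continuous_palette)
        fig.colorbar(sm, ax=ax, label=value_quant)
    if out is not None:
        fig.savefig(out, bbox_inches="tight")
    return fig


def annotate_labels(fig: Figure, map_df: pd.DataFrame, label_col: str = ROI_NAME) -> Figure:
    """Add one text label per distinct ``label_col`` value, anchored at the
    area-weighted centroid of the largest polygon carrying that value.

    Degenerate (zero-area) polygons are skipped with a log message rather
    than raising — a label is a readability aid, not a contract.
    """
    require_columns(map_df, [label_col], "map")
    ax = fig.axes[0]
    best: dict[str, tuple[float, tuple[float, float]]] = {}
    label_by_roi = {
        int(rid): str(grp[label_col].iloc[0])
        for rid, grp in map_df.groupby(ROI_ID, sort=False)
    }
    for poly in polygons_from_map(map_df):
        label = label_by_roi[poly.roi_id]
        try:
            area = polygon_area(poly)
            cxy = polygon_centroid(poly)
        except DegeneratePolygonError:
            logger.info("skipping label for degenerate ROI %d", poly.roi_id)
            continue
        if label not in best or area > best[label][0]:
            best[label] = (area, cxy)
    for label, (_, (cx, cy)) in best.items():
        ax.text(cx, cy, label, ha="center", va="center", fontsize=9)
    return fig
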