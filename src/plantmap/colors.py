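"""Color assignment shared by the raster renderer and the SVG exporter.

Both output paths must agree byte-for-byte on the color given to a tissue
level or a quantitative value, so all palette lookups live here.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import matplotlib
import numpy as np
from matplotlib.colors import to_hex

DEFAULT_CATEGORICAL = "tab20"
DEFAULT_CONTINUOUS = "viridis"
DEFAULT_NA_COLOR = "#808080"  # mid-grey for unmatched/missing values


def categorical_palette_colors(palette: str, n: int) -> list[str]:
    """``n`` hex colors from a named palette; listed palettes cycle with a warning
    when levels outnumber entries, continuous maps are sampled evenly."""
    cmap = matplotlib.colormaps[palette]
    base = getattr(cmap, "colors", None)
    if base is not None:
        base_hex = [to_hex(c) for c in base]
        if n > len(base_hex):
            warnings.warn(
                f"{n} levels exceed the {len(base_hex)} entries of palette "
                f"{palette!r}; colors will repeat",
                stacklevel=2,
            )
        return [base_hex[i % len(base_hex)] for i in range(n)]
    if n == 1:
        return [to_hex(cmap(0.0))]
    return [to_hex(cmap(i / (n - 1))) for i in range(n)]


def level_color_map(levels: Sequence[str], palette: str = DEFAULT_CATEGORICAL) -> dict[str, str]:
    """Deterministic level→hex assignment: levels sorted lexicographically,
    colors taken in palette order.  Reproducible across runs by construction."""
    ordered = sorted(dict.fromkeys(str(v) for v in levels))
    colors = categorical_palette_colors(palette, len(ordered))
    return dict(zip(ordered, colors))


def normalize_values(
    values,
    vmin: float | None = None,
    vmax: float | None = None,
) -> np.ndarray:
    """Min–max normalise to [0, 1]; NaN stays NaN; a constant column maps to 0.5.

    Explicit ``vmin``/``vmax`` override the data range (for cross-panel
    comparability, e.g. multi-gene grids sharing one scale); values outside
    the override range are clipped.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size == 0:
        raise ValueError(
            "value column is entirely missing — check the merge keys "
            "(did the quantitative table's names match the map's levels?)"
        )
    lo = float(np.min(finite)) if vmin is None else float(vmin)
    hi = float(np.max(finite)) if vmax is None else float(vmax)
    if hi == lo:
        frac = np.where(np.isfinite(v), 0.5, np.nan)
    else:
        frac = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return frac


def continuous_colors(
    values,
    palette: str = DEFAULT_CONTINUOUS,
    vmin: float | None = None,
    vmax: float | None = None,
    na_color: str = DEFAULT_NA_COLOR,
) -> list[str]:
    """Hex fill color per value: palette evaluated at the normalised position,
    ``na_color`` for missing.  The single authoritative quantitative-color
    routine — heatmap patches and SVG fills both call this."""
    frac = normalize_values(values, vmin, vmax)
    cmap = matplotlib.colormaps[palette]
    out = []
    for f in frac:
        out.append(to_hex(na_color) if np.isnan(f) else to_hex(cmap(float(f))))
    return out
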