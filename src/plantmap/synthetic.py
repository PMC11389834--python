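"""Programmatic generation of plant-like maps and matching quantitative tables.

Real maps are traced by hand from micrographs; these generators build valid,
anatomically structured stand-ins — concentric cell layers like a root
cross-section, rectangular cell files, or a Voronoi mosaic — so the whole
pipeline is exercisable with no image and no download.  Every generated map
passes ``validate_map`` and ships with a ground-truth record (true polygon
areas, level assignment) for use as an independent oracle.

Naming follows the cortex-layer convention: the outermost layer is ``C1``,
the next ``C2``, and so on, with many cells (ROIs) sharing each level name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .map_model import ROIPolygon, map_from_polygons, polygon_area

PRESETS = ("rings", "grid", "random_voronoi")
_PRESET_STREAM = {"rings": 1, "grid": 2, "random_voronoi": 3}

#: vertices per arc of a ring sector — 32 keeps the polygonal area within
#: ~0.1% of the closed-form annular-sector area for quarter-circle sectors
ARC_VERTICES = 32


class ParameterError(ValueError):
    """Invalid fixture specification."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic map.

    preset
        ``rings`` — n_layers concentric annuli, each split into
        cells_per_layer sector cells (a stylised root cross-section);
        ``grid`` — n_layers rows of cells_per_layer rectangular cells;
        ``random_voronoi`` — Voronoi mosaic, layers assigned by distance
        from the canvas centre.
    jitter
        Gaussian vertex perturbation in pixels; capped at 20% of the
        smallest cell dimension so polygons stay simple.
    canvas
        (width, height) in pixels; image convention, y grows downward.
    """

    preset: str = "rings"
    n_layers: int = 2
    cells_per_layer: int = 4
    jitter: float = 0.0
    seed: int = 0
    canvas: tuple[float, float] = (512.0, 512.0)

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ParameterError(f"preset must be one of {PRESETS}, got {self.preset!r}")
        if self.n_layers < 1 or self.cells_per_layer < 1:
            raise ParameterError("n_layers and cells_per_layer must be >= 1")
        if self.jitter < 0:
            raise ParameterError("jitter must be >= 0")
        if min(self.canvas) <= 0:
            raise ParameterError("canvas dimensions must be positive")
        limit = 0.2 * self._min_cell_dimension()
        if self.jitter >= limit and self.jitter > 0:
            raise ParameterError(
                f"jitter {self.jitter} too large for this geometry "
                f"(must stay below {limit:.3g} = 20% of the smallest cell dimension)"
            )

    def _min_cell_dimension(self) -> float:
        w, h = self.canvas
        if self.preset == "rings":
            r_out = 0.45 * min(w, h)
            r_in = 0.1 * min(w, h)
            radial = (r_out - r_in) / self.n_layers
            inner_arc = r_in * 2 * np.pi / self.cells_per_layer
            return float(min(radial, inner_arc))
        if self.preset == "grid":
            return min(w / self.cells_per_layer, h / self.n_layers)
        # voronoi: conservative bound from mean cell spacing
        n = self.n_layers * self.cells_per_layer
        return float(np.sqrt(w * h / n) / 2)

    def rng(self) -> np.random.Generator:
        """Random stream isolated per (seed, preset) so adding presets never
        shifts the draws of existing ones."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _PRESET_STREAM[self.preset]])
        )


@dataclass
class GroundTruth:
    """Per-ROI truth recorded at generation time (independent test oracle)."""

    spec: FixtureSpec
    true_area: dict[int, float] = field(default_factory=dict)   # exact where known
    level: dict[int, str] = field(default_factory=dict)
    polygon_area: dict[int, float] = field(default_factory=dict)  # shoelace of emitted vertices

    def to_json(self) -> str:
        return json.dumps(
            {
                "preset": self.spec.preset,
                "n_layers": self.spec.n_layers,
                "cells_per_layer": self.spec.cells_per_layer,
                "jitter": self.spec.jitter,
                "seed": self.spec.seed,
                "canvas": list(self.spec.canvas),
                "arc_vertices": ARC_VERTICES,
                "rois": [
                    {
                        "roi_id": rid,
                        "level": self.level[rid],
                        "true_area": self.true_area.get(rid),
                        "polygon_area": self.polygon_area[rid],
                    }
                    for rid in sorted(self.level)
                ],
            },
            indent=2,
        )


def generate_synthetic_map(spec: FixtureSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Build a valid PlantMap (and its ground truth) from a fixture spec.

    Deterministic for a fixed seed.  For ``rings`` with jitter 0 the true
    area of every cell is the closed-form annular sector
    ``pi * (r2^2 - r1^2) / cells_per_layer``.
    """
    rng = spec.rng()
    if spec.preset == "rings":
        polygons, truth = _rings(spec, rng)
    elif spec.preset == "grid":
        polygons, truth = _grid(spec, rng)
    else:
        polygons, truth = _voronoi(spec, rng)
    for p in polygons:
        truth.polygon_area[p.roi_id] = polygon_area(p)
    return map_from_polygons(polygons), truth


def _jitter_points(pts: np.ndarray, spec: FixtureSpec, rng) -> np.ndarray:
    if spec.jitter == 0:
        return pts
    return pts + rng.normal(0.0, spec.jitter, size=pts.shape)


def _rings(spec: FixtureSpec, rng) -> tuple[list[ROIPolygon], GroundTruth]:
    w, h = spec.canvas
    cx, cy = w / 2, h / 2
    r_out = 0.45 * min(w, h)
    r_in = 0.1 * min(w, h)
    radii = np.linspace(r_out, r_in, spec.n_layers + 1)  # outermost layer first = C1
    truth = GroundTruth(spec)
    polygons = []
    roi_id = 1
    for layer in range(spec.n_layers):
        r2, r1 = radii[layer], radii[layer + 1]  # r2 outer, r1 inner
        level = f"C{layer + 1}"
        sector = 2 * np.pi / spec.cells_per_layer
        for c in range(spec.cells_per_layer):
            a0, a1 = c * sector, (c + 1) * sector
            ang = np.linspace(a0, a1, ARC_VERTICES)
            outer = np.column_stack([cx + r2 * np.cos(ang), cy + r2 * np.sin(ang)])
            inner = np.column_stack([cx + r1 * np.cos(ang[::-1]), cy + r1 * np.sin(ang[::-1])])
            pts = _jitter_points(np.vstack([outer, inner]), spec, rng)
            polygons.append(ROIPolygon(level, roi_id, pts))
            truth.level[roi_id] = level
            if spec.jitter == 0:
                truth.true_area[roi_id] = float(np.pi * (r2**2 - r1**2) / spec.cells_per_layer)
            roi_id += 1
    return polygons, truth


def _grid(spec: FixtureSpec, rng) -> tuple[list[ROIPolygon], GroundTruth]:
    w, h = spec.canvas
    cell_w, cell_h = w / spec.cells_per_layer, h / spec.n_layers
    truth = GroundTruth(spec)
    polygons = []
    roi_id = 1
    for row in range(spec.n_layers):
        level = f"C{row + 1}"
        for col in range(spec.cells_per_layer):
            x0, y0 = col * cell_w, row * cell_h
            pts = np.array([
                [x0, y0], [x0 + cell_w, y0],
                [x0 + cell_w, y0 + cell_h], [x0, y0 + cell_h],
            ])
            pts = _jitter_points(pts, spec, rng)
            polygons.append(ROIPolygon(level, roi_id, pts))
            truth.level[roi_id] = level
            if spec.jitter == 0:
                truth.true_area[roi_id] = float(cell_w * cell_h)
            roi_id += 1
    return polygons, truth


def _voronoi(spec: FixtureSpec, rng) -> tuple[list[ROIPolygon], GroundTruth]:
    """Voronoi mosaic clipped to the canvas; layer = distance-from-centre band."""
    from scipy.spatial import Voronoi

    w, h = spec.canvas
    n = spec.n_layers * spec.cells_per_layer
    seeds = rng.uniform([0.08 * w, 0.08 * h], [0.92 * w, 0.92 * h], size=(n, 2))
    # mirror seeds across every border so all interior cells are bounded
    mirrored = [seeds]
    for axis, bound in ((0, 0.0), (0, w), (1, 0.0), (1, h)):
        m = seeds.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))

    centre = np.array([w / 2, h / 2])
    dist = np.linalg.norm(seeds - centre, axis=1)
    # equal-count distance bands: innermost band is the deepest layer C<n_layers>
    order = np.argsort(dist)
    band = np.empty(n, dtype=int)
    for rank, idx in enumerate(order):
        band[idx] = spec.n_layers - 1 - (rank * spec.n_layers) // n

    truth = GroundTruth(spec)
    polygons = []
    roi_id = 1
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:  # cannot happen with mirrored seeds
            continue
        pts = vor.vertices[region]
        pts = _jitter_points(pts, spec, rng)
        level = f"C{band[i] + 1}"
        polygons.append(ROIPolygon(level, roi_id, pts))
        truth.level[roi_id] = level
        roi_id += 1
    return polygons, truth


def generate_synthetic_quant(
    levels: Sequence[str],
    model: str = "gradient",
    seed: int = 0,
    key_column: str = "ROI.name",
    value_column: str = "value",
) -> pd.DataFrame:
    """One quantitative record per level, emulating a per-tissue expression table.

    ``gradient`` assigns strictly increasing values along the given level
    order (1, 2, …) — handy for monotone-color tests; ``constant`` assigns
    1.0 everywhere; ``random`` draws Uniform(0, 10) deterministically from
    the seed.
    """
    if not levels:
        raise ValueError("levels must be non-empty")
    levels = [str(v) for v in levels]
    if model == "gradient":
        values = np.arange(1, len(levels) + 1, dtype=float)
    elif model == "constant":
        values = np.ones(len(levels))
    elif model == "random":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
        values = rng.uniform(0.0, 10.0, size=len(levels))
    else:
        raise ValueError(f"model must be gradient|random|constant, got {model!r}")
    return pd.DataFrame({key_column: levels, value_column: values})


def write_fixture(spec: FixtureSpec, out_dir, stem: str = "fixture") -> dict[str, str]:
    """Write one fixture's full artefact set: Icy XML, PlantMap CSV,
    gradient QuantTable CSV and ground-truth JSON.  Returns the paths."""
    import os

    from .map_model import ROI_NAME, write_map_csv, write_table_csv
    from .roi_io import write_icy_xml

    os.makedirs(out_dir, exist_ok=True)
    map_df, truth = generate_synthetic_map(spec)
    levels = sorted(map_df[ROI_NAME].unique())
    quant = generate_synthetic_quant(levels, model="gradient", seed=spec.seed)
    paths = {
        "xml": os.path.join(out_dir, f"{stem}.xml"),
        "map_csv": os.path.join(out_dir, f"{stem}.map.csv"),
        "quant_csv": os.path.join(out_dir, f"{stem}.quant.csv"),
        "truth_json": os.path.join(out_dir, f"{stem}.truth.json"),
    }
    write_icy_xml(map_df, paths["xml"])
    write_map_csv(map_df, paths["map_csv"])
    write_table_csv(quant, paths["quant_csv"])
    with open(paths["truth_json"], "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
    return paths
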