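# Methods

## Data model

A **PlantMap** is a long-format table with one row per polygon vertex and
five mandatory columns: `ROI.name` (tissue level), `ROI.id` (positive
integer, unique per polygon), `point` (1-based vertex ordinal, consecutive
within its ROI), `x`, `y` (image pixel coordinates, y increasing downward).
Many polygons share a level name — a level is a tissue or cell type, not a
single cell — and quantitative data attach at the level. Extra columns
(e.g. `Zone`, `Layer`) are allowed and must be constant within each ROI;
`split_name_levels` can derive them from structured names like `SAM.CZ.L1`.

Coordinates are stored exactly as traced, in image convention. No flip
happens at the model layer: orientation is a rendering concern, and keeping
the stored table lossless means XML → table → XML round-trips are exact.

`ROI.id` is always assigned by document order starting at 1. Icy files do
carry integer ids, but they reflect tracing history (deletions leave gaps,
re-ordering is possible), so they are ignored wholesale rather than patched
case by case; this guarantees a duplicate-free 1..n sequence.

## Icy XML dialect

The parser keys on ROI elements whose `classname` text ends in
`ROI2DPolygon`; rectangles, ellipses and lines are skipped with a warning
and never shift the ids of retained polygons. Element names are configurable
(`IcySchema`) because near-dialects exist in the wild. Multi-contour ROIs
(holes) are not supported — plant cell traces are simple polygons — and only
the first contour is read, with a warning. Unnamed ROIs get the name
`ROI.<id>`. Parsing uses the stdlib XML parser, whose errors carry the line
number; a document with zero usable polygons is a distinct error from a
malformed one, and the two map to different CLI exit codes (2 vs 1).

## Geometry

Area and centroid use the shoelace formulas on the ordered vertex ring
(consecutive duplicate vertices and a repeated closing vertex are removed on
construction). `polygon_area` is the absolute signed area, hence
orientation-independent; `polygon_centroid` is the area-weighted centroid
and raises on zero-area polygons. Tests verify both against an independent
Monte-Carlo oracle: uniform samples over the bounding box classified by
matplotlib's point-in-polygon test, with agreement required within 3σ of the
binomial sampling error (area) and 1% of the bounding-box diagonal
(centroid).

## Merge semantics

`merge_quant` is a **left** join: every map row is retained and unmatched
levels carry missing values, so un-measured tissue still renders (in the
`na_color`, a mid grey) and the anatomy stays visible. Keys match exactly
and case-sensitively after whitespace trimming — silent case folding hides
curation errors; `rename_levels` exists for deliberate harmonisation.
Duplicate keys in the quantitative table are an error, not a broadcast: a
row-multiplying join would break the one-row-per-vertex contract, and
`aggregate_quant` (mean/median/sum/max, missing dropped, groups emitted in
lexicographic order) is the deliberate route from record-level data (e.g.
per-cell single-cell expression) to one value per level. Quantitative
records that match no map level are dropped with a logged count.

## Rendering

One filled matplotlib patch per ROI. The vertical axis is inverted at render
time (limits set high-to-low) so the figure matches the source image; SVG
output, by contrast, keeps raw y-down coordinates because SVG natively
shares the image convention. Defaults: color by `ROI.name`, legend shown,
outline width 1 pt, equal aspect.

Categorical colors: levels are sorted lexicographically and assigned palette
entries in order (default `tab20`), cycling with a warning when levels
outnumber entries — assignment is reproducible across runs by construction.

Quantitative colors: min–max normalisation to [0, 1], evaluated through the
continuous palette (default `viridis`, perceptually uniform). Min–max rather
than quantile normalisation keeps the mapping invertible and makes the
endpoints meaningful; explicit `vmin`/`vmax` overrides allow a shared scale
across panels (multi-gene grids). A constant column maps to the palette
midpoint (degenerate but non-crashing); an all-missing column is an error
that points at the merge keys. All color math lives in one routine shared by
the raster renderer and the SVG exporter, so the two agree byte-for-byte;
tests additionally probe rendered pixels at polygon centroids against the
SVG fill attributes.

Label placement (`annotate_labels`) puts one text per level at the shoelace
centroid of the largest polygon of that level; degenerate polygons are
skipped with a log message.

## SVG export

One `<path>` per ROI (`M x,y L x,y … Z`), grouped in one `<g>` per level so
a whole tissue can be restyled with one selector; each path carries a stable
id (default `<ROI.name>.<ROI.id>`, scheme pluggable since eFP pipelines vary)
and a CSS class equal to the level name with non-alphanumerics replaced by
underscores. Id collisions under a custom scheme are an error. Coordinates
are printed with exactly 6 decimals and a `.` separator regardless of
locale, making repeated exports byte-identical (golden-file friendly) and
bounding round-trip error by 5e-7 px. The document's width/height/viewBox
equal the map's bounding box padded by 1%.

## Synthetic fixtures

The generators stand in for hand-traced maps and define the test conditions:

- `rings` — concentric annuli between radii 0.45·min(canvas) and
  0.1·min(canvas), each split into equal sectors; the outermost layer is
  `C1`, matching the cortex-naming convention. Arcs are discretised at 32
  vertices per sector arc, keeping the polygonal area within 0.5% (measured:
  ~0.04% for quarter sectors) of the closed-form annular-sector area
  π(r₂²−r₁²)/cells, which is recorded per ROI in a ground-truth JSON.
- `grid` — rectangular cell files, rows as layers; exact rectangle areas.
- `random_voronoi` — a Voronoi mosaic (seeds mirrored across the canvas
  borders so every cell is bounded), layers assigned by equal-count distance
  bands from the canvas centre.

Default canvas is 512×512 px with 2 layers × 4 cells — small enough that the
whole suite runs in seconds, large enough that every contract (multiple ROIs
per level, multiple levels, curved polygons) is exercised. Vertex jitter is
Gaussian with a cap at 20% of the smallest cell dimension so polygons stay
simple; the rings cap uses the inner arc length as the limiting dimension.
Random streams are isolated per (seed, preset) via `SeedSequence([seed,
preset_code])`, so adding presets never shifts existing draws. What the
fixtures do **not** emulate: tracing noise correlated along outlines,
overlapping or non-simple hand traces, multi-contour cells, and anatomical
realism beyond layered naming — passing tests therefore demonstrate contract
correctness, not robustness to messy human tracings (the lenient parser
paths cover the common failure modes: unnamed, degenerate and non-polygon
ROIs).

## Numerical choices

- Coordinate equality tolerance in tests: 1e-6 px absolute (SVG precision);
  XML round-trips are exact because coordinates are written with `repr`.
- Area/centroid invariance tolerances: 1e-9 relative.
- Shoelace zero-area threshold for the centroid: 1e-12 absolute.
- Fill rule: matplotlib/SVG default nonzero winding; traced cell outlines
  are simple polygons so the rule rarely matters, but it is fixed for
  determinism.

## CLI

`plantmap` exposes convert / merge / plot / heatmap / svg / synth as thin
wrappers over the library functions (CLI output equals library output on the
same inputs). Exit codes: 0 success, 1 I/O or parse failure, 2 invalid user
input. Output files are written atomically (temp file + rename) so a failed
run leaves nothing behind. An optional TOML config can pre-set any flag;
explicit flags win. Logs go to stderr, data only to files.

## Known limitations

- No raster image analysis: tracing happens upstream in Icy.
- No Fiji/ImageJ `.roi` or LabelMe JSON input (the `IcySchema` indirection
  is the extension point).
- No multi-contour (holed) polygons.
- No interactive viewer; developmental series render as repeated calls.
- `aggregate_quant` expects a plain table; export from single-cell
  containers (loom/h5ad) to a two-column table first.
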