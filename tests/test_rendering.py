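"""Renderer contracts: defaults, legend/linewidth switches, color math, orientation."""

import matplotlib
import numpy as np
import pandas as pd
import pytest
from matplotlib.colors import to_hex, to_rgba

from plantmap.map_model import SchemaError
from plantmap.quant_merge import merge_quant
from plantmap.rendering import RenderSpec, annotate_labels, plot_heatmap, plot_map
from plantmap.synthetic import FixtureSpec, generate_synthetic_map, generate_synthetic_quant

from conftest import make_map


def patches_of(fig):
    return fig.axes[0].patches


class TestPlotMapDefaults:
    def test_defaults_match_documented_behaviour(self, rings_map):
        spec = RenderSpec()
        assert spec.layer == "ROI.name"
        assert spec.show_legend is True
        assert spec.linewidth == 1.0
        fig = plot_map(rings_map)
        assert len(patches_of(fig)) == 8
        assert fig.axes[0].get_legend() is not None
        assert all(p.get_linewidth() == 1.0 for p in patches_of(fig))

    def test_show_legend_false_removes_legend(self, rings_map):
        fig = plot_map(rings_map, RenderSpec(show_legend=False))
        assert fig.axes[0].get_legend() is None

    def test_linewidth_zero_gives_zero_outline(self, rings_map):
        fig = plot_map(rings_map, RenderSpec(linewidth=0))
        assert all(p.get_linewidth() == 0.0 for p in patches_of(fig))

    def test_negative_linewidth_rejected(self):
        with pytest.raises(ValueError):
            RenderSpec(linewidth=-1)

    def test_single_square_patch_vertices_equal_input(self, square_map):
        fig = plot_map(square_map, RenderSpec(show_legend=False))
        (patch,) = patches_of(fig)
        np.testing.assert_allclose(
            patch.get_xy()[:4], square_map[["x", "y"]].to_numpy()
        )

    def test_missing_layer_column_is_schema_error(self, rings_map):
        with pytest.raises(SchemaError, match="Zone"):
            plot_map(rings_map, RenderSpec(layer="Zone"))

    def test_empty_map_rejected(self):
        empty = make_map()
        with pytest.raises(ValueError):
            plot_map(empty)

    def test_same_level_same_color_distinct_levels_distinct(self, rings_map):
        fig = plot_map(rings_map)
        fills = {}
        for patch in patches_of(fig):
            level = patch.get_label().split(".")[0]
            fills.setdefault(level, set()).add(to_hex(patch.get_facecolor()))
        assert all(len(s) == 1 for s in fills.values())
        assert fills["C1"] != fills["C2"]

    def test_custom_layer_column_drives_fill(self, rings_map):
        m = rings_map.copy()
        m["Zone"] = np.where(m["ROI.id"] % 2 == 0, "even", "odd")
        fig = plot_map(m, RenderSpec(layer="Zone"))
        colors = {to_hex(p.get_facecolor()) for p in patches_of(fig)}
        assert len(colors) == 2


class TestOrientation:
    def test_larger_image_y_renders_lower_on_canvas(self, rings_map):
        fig = plot_map(rings_map, RenderSpec(show_legend=False))
        ax = fig.axes[0]
        # display coordinates: y grows upward; image convention: y grows downward
        y_top = ax.transData.transform((256.0, 100.0))[1]
        y_bottom = ax.transData.transform((256.0, 400.0))[1]
        assert y_top > y_bottom


class TestHeatmap:
    @pytest.fixture
    def merged(self, rings_map):
        quant = generate_synthetic_quant(["C1", "C2"], model="gradient")
        return merge_quant(rings_map, quant)

    def test_patch_count_and_colorbar(self, merged):
        fig = plot_heatmap(merged, "value")
        assert len(patches_of(fig)) == 8
        assert len(fig.axes) == 2  # map axes + colorbar

    def test_no_legend_means_no_colorbar(self, merged):
        fig = plot_heatmap(merged, "value", RenderSpec(show_legend=False))
        assert len(fig.axes) == 1

    def test_constant_values_render_single_color(self, rings_map):
        quant = generate_synthetic_quant(["C1", "C2"], model="constant")
        merged = merge_quant(rings_map, quant)
        fig = plot_heatmap(merged, "value")
        colors = {to_hex(p.get_facecolor()) for p in patches_of(fig)}
        assert len(colors) == 1

    def test_endpoint_values_hit_palette_endpoints(self, two_roi_map):
        quant = pd.DataFrame({"ROI.name": ["C1", "C2"], "value": [0.0, 1.0]})
        merged = merge_quant(two_roi_map, quant)
        fig = plot_heatmap(merged, "value", RenderSpec(show_legend=False))
        cmap = matplotlib.colormaps["viridis"]
        got = [to_hex(p.get_facecolor()) for p in patches_of(fig)]
        assert got == [to_hex(cmap(0.0)), to_hex(cmap(1.0))]

    def test_fill_equals_independent_colormap_lookup(self):
        """Byte-exact agreement with a hand-rolled normalise-then-lookup oracle."""
        spec = FixtureSpec(preset="grid", n_layers=2, cells_per_layer=5, seed=3)
        map_df, _ = generate_synthetic_map(spec)
        rng = np.random.default_rng(8)
        levels = sorted(map_df["ROI.name"].unique())
        quant = pd.DataFrame({"ROI.name": levels, "value": rng.uniform(2, 9, len(levels))})
        merged = merge_quant(map_df, quant)
        fig = plot_heatmap(merged, "value", RenderSpec(show_legend=False))

        cmap = matplotlib.colormaps["viridis"]
        vals = merged.groupby("ROI.id", sort=False)["value"].first().to_numpy()
        lo, hi = vals.min(), vals.max()
        expected = [to_rgba(to_hex(cmap((v - lo) / (hi - lo)))) for v in vals]
        got = [p.get_facecolor() for p in patches_of(fig)]
        assert got == expected

    def test_monotone_in_value(self):
        spec = FixtureSpec(preset="grid", n_layers=1, cells_per_layer=6, seed=1)
        map_df, _ = generate_synthetic_map(spec)
        # one ROI per level here, so give each its own value via roi name
        map_df["ROI.name"] = [f"L{rid}" for rid in map_df["ROI.id"]]
        quant = pd.DataFrame({"ROI.name": [f"L{i}" for i in range(1, 7)],
                              "value": [3.0, 1.0, 6.0, 2.0, 5.0, 4.0]})
        merged = merge_quant(map_df, quant)
        from plantmap.colors import normalize_values
        frac = normalize_values(quant["value"])
        order = np.argsort(quant["value"].to_numpy())
        assert (np.diff(frac[order]) > 0).all()

    def test_missing_values_filled_with_na_color(self, rings_map):
        quant = pd.DataFrame({"ROI.name": ["C1"], "value": [1.0]})
        merged = merge_quant(rings_map, quant)
        spec = RenderSpec(show_legend=False)
        fig = plot_heatmap(merged, "value", spec)
        na_patches = [p for p in patches_of(fig)
                      if to_hex(p.get_facecolor()) == to_hex(spec.na_color)]
        assert len(na_patches) == 4  # the four C2 cells

    def test_all_missing_value_column_advises_merge_check(self, rings_map):
        merged = rings_map.assign(value=np.nan)
        with pytest.raises(ValueError, match="merge"):
            plot_heatmap(merged, "value")

    def test_vmin_vmax_override_rescales(self, merged):
        fig = plot_heatmap(merged, "value", RenderSpec(show_legend=False),
                           vmin=0.0, vmax=4.0)
        cmap = matplotlib.colormaps["viridis"]
        c1_fill = to_hex(patches_of(fig)[0].get_facecolor())
        assert c1_fill == to_hex(cmap(0.25))  # value 1 on a 0–4 scale


class TestAnnotateLabels:
    def test_two_level_fixture_gets_two_labels(self, rings_map):
        fig = plot_map(rings_map, RenderSpec(show_legend=False))
        annotate_labels(fig, rings_map)
        texts = fig.axes[0].texts
        assert len(texts) == 2
        assert {t.get_text() for t in texts} == {"C1", "C2"}

    def test_square_label_at_centroid(self, square_map):
        fig = plot_map(square_map, RenderSpec(show_legend=False))
        annotate_labels(fig, square_map)
        (text,) = fig.axes[0].texts
        assert text.get_position() == pytest.approx((0.5, 0.5))

    def test_label_inside_polygon_for_convex_fixtures(self):
        from matplotlib.path import Path

        spec = FixtureSpec(preset="grid", n_layers=2, cells_per_layer=3, seed=5, jitter=2.0)
        map_df, _ = generate_synthetic_map(spec)
        fig = plot_map(map_df, RenderSpec(show_legend=False))
        annotate_labels(fig, map_df, label_col="ROI.id")
        positions = {t.get_text(): t.get_position() for t in fig.axes[0].texts}
        for rid, grp in map_df.groupby("ROI.id"):
            pts = grp[["x", "y"]].to_numpy()
            path = Path(np.vstack([pts, pts[:1]]), closed=True)
            assert path.contains_point(positions[str(rid)])
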