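import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from plantmap.map_model import CORE_COLUMNS
from plantmap.synthetic import FixtureSpec, generate_synthetic_map


def random_star_polygon(rng, n_vertices=12, radius=100.0, center=(0.0, 0.0)):
    """Random simple polygon: star-shaped about its centre by construction
    (sorted angles, positive radii)."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # keep angles distinct so no degenerate edges
    angles += np.linspace(0, 1e-6, n_vertices)
    radii = rng.uniform(0.3 * radius, radius, n_vertices)
    return np.column_stack(
        [center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)]
    )


def monte_carlo_area_centroid(points, n_samples=200_000, seed=0):
    """Independent geometry oracle: uniform rejection sampling over the
    bounding box with matplotlib's even-odd point-in-polygon test.

    Returns (area, (cx, cy), area_sigma) where area_sigma is the binomial
    standard error propagated to the area estimate.
    """
    from matplotlib.path import Path

    pts = np.asarray(points, float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    box_area = np.prod(hi - lo)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, 2))
    # closed=True consumes the final vertex as the CLOSEPOLY placeholder,
    # so the ring must be closed explicitly
    ring = np.vstack([pts, pts[:1]])
    inside = Path(ring, closed=True).contains_points(samples)
    p_hat = inside.mean()
    area = box_area * p_hat
    sigma = box_area * np.sqrt(p_hat * (1 - p_hat) / n_samples)
    centroid = samples[inside].mean(axis=0)
    return area, centroid, sigma


def make_map(*polys):
    """Assemble a PlantMap DataFrame from (name, roi_id, vertex-list) triples."""
    rows = []
    for name, rid, pts in polys:
        for i, (x, y) in enumerate(pts, start=1):
            rows.append({"ROI.name": name, "ROI.id": rid, "point": i, "x": x, "y": y})
    return pd.DataFrame(rows, columns=list(CORE_COLUMNS))


UNIT_SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]


@pytest.fixture
def square_map():
    return make_map(("A", 1, UNIT_SQUARE))


@pytest.fixture
def two_roi_map():
    return make_map(
        ("C1", 1, UNIT_SQUARE),
        ("C2", 2, [(2, 0), (3, 0), (3, 1), (2, 1)]),
    )


@pytest.fixture
def rings_map():
    map_df, _ = generate_synthetic_map(FixtureSpec(preset="rings", seed=7))
    return map_df


@pytest.fixture
def rings_truth():
    return generate_synthetic_map(FixtureSpec(preset="rings", seed=7))
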