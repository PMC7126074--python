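"""Raster model, rasterization and the two spatial primitives."""

import math

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from oracles import (
    oracle_distance_to_nearest,
    oracle_neighborhood_fraction,
    oracle_point_in_polygon,
)

import spore
from spore.grid import disk_kernel

CS = 30.0


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def test_rasterize_exact_tiling_square():
    polys = [(5, shapely.box(0, 0, 90, 90))]
    grid = spore.rasterize_landcover(polys, 30, (0, 0, 90, 90))
    assert grid.shape == (3, 3)
    assert (grid.codes == 5).all()


def test_rasterize_abutting_rectangles():
    polys = [(1, shapely.box(0, 0, 30, 30)), (2, shapely.box(30, 0, 60, 30))]
    grid = spore.rasterize_landcover(polys, 30, (0, 0, 60, 30))
    assert grid.codes.tolist() == [[1, 2]]


def test_rasterize_l_shape_matches_point_in_polygon_oracle():
    # L-shape occupying the left column and bottom row of a 90 x 90 bounds
    verts = [(0, 0), (90, 0), (90, 30), (30, 30), (30, 90), (0, 90)]
    polys = [(1, shapely.Polygon(verts))]
    grid = spore.rasterize_landcover(polys, 30, (0, 0, 90, 90))
    for r in range(3):
        for c in range(3):
            x, y = grid.cell_centre(r, c)
            expected = 1 if oracle_point_in_polygon(x, y, verts) else spore.NODATA_CODE
            assert grid.codes[r, c] == expected


def test_rasterize_priority_order_on_overlap():
    polys = [(1, shapely.box(0, 0, 60, 30)), (2, shapely.box(0, 0, 60, 30))]
    grid = spore.rasterize_landcover(polys, 30, (0, 0, 60, 30))
    assert (grid.codes == 1).all()


def test_rasterize_rejects_empty_and_degree_crs():
    with pytest.raises(spore.GridError, match="empty polygon"):
        spore.rasterize_landcover([], 30, (0, 0, 90, 90))
    with pytest.raises(spore.GridError, match="reproject"):
        spore.rasterize_landcover(
            [(1, shapely.box(0, 0, 1, 1))], 30, (0, 0, 90, 90), crs_id="EPSG:4326"
        )


def test_fidelity_exact_tiling_passes_with_zero_error():
    polys = [(5, shapely.box(0, 0, 90, 90))]
    grid = spore.rasterize_landcover(polys, 30, (0, 0, 90, 90))
    report = spore.check_rasterization_fidelity(polys, grid, tolerance=0.0)
    assert report.passed
    assert report.relative_error[5] == 0.0
    assert report.per_class_vector_area[5] == pytest.approx(8100.0)
    assert report.per_class_raster_area[5] == pytest.approx(8100.0)


def test_fidelity_circle_matches_enumerated_centre_count():
    r = 45.0
    circle = shapely.Point(60, 60).buffer(r, quad_segs=256)
    polys = [(3, circle)]
    grid = spore.rasterize_landcover(polys, 30, (0, 0, 120, 120))
    # enumerate centres inside the circle by hand
    n_in = sum(
        1
        for row in range(4)
        for col in range(4)
        if math.hypot((col + 0.5) * 30 - 60, 120 - (row + 0.5) * 30 - 60) <= r
    )
    assert (grid.codes == 3).sum() == n_in
    report = spore.check_rasterization_fidelity(polys, grid, tolerance=1.0)
    expected_err = abs(n_in * 900 - circle.area) / circle.area
    assert report.relative_error[3] == pytest.approx(expected_err, abs=1e-12)
    # zero tolerance with a non-zero error must fail
    assert not spore.check_rasterization_fidelity(polys, grid, tolerance=0.0).passed


def test_fidelity_flags_raster_class_missing_from_vector():
    polys = [(5, shapely.box(0, 0, 90, 90))]
    grid = spore.rasterize_landcover(polys, 30, (0, 0, 90, 90))
    report = spore.check_rasterization_fidelity([(4, shapely.box(0, 0, 90, 90))], grid, 0.5)
    assert not report.passed
    assert report.missing_in_vector == {5}


# ---------------------------------------------------------------------------
# resolution rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "max_dist,candidates,expected",
    [(500, [20, 30, 50], 50), (1000, [100], 100), (500, [50, 20], 50)],
)
def test_suggest_resolution_picks_coarsest_within_tenth(max_dist, candidates, expected):
    assert spore.suggest_resolution(max_dist, candidates) == expected


def test_suggest_resolution_errors_when_no_candidate_fits():
    with pytest.raises(spore.GridError, match="50"):
        spore.suggest_resolution(500, [60, 100])


# ---------------------------------------------------------------------------
# neighborhood fraction
# ---------------------------------------------------------------------------

def test_fraction_single_target_cell_is_one():
    grid = spore.LandcoverGrid(np.array([[1]]), CS)
    out = spore.neighborhood_fraction(grid, {1}, radius=1000.0)
    assert out.values[0, 0] == 1.0


def test_fraction_centre_only_target_is_one_ninth_everywhere():
    codes = np.zeros((3, 3), dtype=int)
    codes[1, 1] = 1
    grid = spore.LandcoverGrid(codes, CS)
    out = spore.neighborhood_fraction(grid, {1}, radius=3 * CS)
    assert np.allclose(out.values, 1.0 / 9.0)


def test_fraction_no_target_is_zero_and_all_target_is_one():
    grid = spore.LandcoverGrid(np.full((4, 5), 2), CS)
    assert (spore.neighborhood_fraction(grid, {7}, 100.0).values == 0.0).all()
    assert (spore.neighborhood_fraction(grid, {2}, 100.0).values == 1.0).all()
    assert (spore.neighborhood_fraction(grid, set(), 100.0).values == 0.0).all()


def test_fraction_warns_on_degenerate_radius():
    grid = spore.LandcoverGrid(np.full((2, 2), 1), CS)
    with pytest.warns(UserWarning, match="focal cell alone"):
        out = spore.neighborhood_fraction(grid, {1}, radius=10.0)
    assert (out.values == 1.0).all()


def test_fraction_excludes_nodata_from_both_counts():
    codes = np.array([[1, -1], [0, 0]])
    grid = spore.LandcoverGrid(codes, CS)
    out = spore.neighborhood_fraction(grid, {1}, radius=100.0)
    assert out.values[1, 0] == pytest.approx(1.0 / 3.0)
    assert out.nodata_mask[0, 1]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    codes=arrays(np.int32, (6, 7), elements=st.integers(-1, 3)),
    radius_cells=st.floats(1.0, 5.0),
)
def test_fraction_bounded_and_nodata_preserved(codes, radius_cells):
    grid = spore.LandcoverGrid(codes, CS)
    out = spore.neighborhood_fraction(grid, {1, 2}, radius_cells * CS)
    vals = out.values[~out.nodata_mask]
    assert ((vals >= 0.0) & (vals <= 1.0)).all()
    assert (out.nodata_mask == ~grid.valid_mask).all()


@pytest.mark.parametrize("seed", range(5))
def test_fraction_matches_bruteforce_oracle(seed):
    from conftest import random_landcover

    grid = random_landcover(seed, max_side=30)
    rng = np.random.default_rng(100 + seed)
    radius = float(rng.uniform(1, 6)) * CS
    got = spore.neighborhood_fraction(grid, {0, 2}, radius)
    want = oracle_neighborhood_fraction(grid.codes, {0, 2}, radius, CS)
    assert np.abs(got.values[~got.nodata_mask] - want[~got.nodata_mask]).max() <= 1e-9


# ---------------------------------------------------------------------------
# distance to nearest
# ---------------------------------------------------------------------------

def test_distance_basic_geometry():
    codes = np.array([[1, 0, 0]])
    grid = spore.LandcoverGrid(codes, CS)
    out = spore.distance_to_nearest(grid, {1})
    assert out.values[0, 0] == 0.0
    assert out.values[0, 1] == pytest.approx(30.0)
    codes = np.array([[1, 0], [0, 0]])
    out = spore.distance_to_nearest(spore.LandcoverGrid(codes, CS), {1})
    assert out.values[1, 1] == pytest.approx(30.0 * math.sqrt(2))


def test_distance_empty_target_gives_infinite_sentinel():
    grid = spore.LandcoverGrid(np.zeros((3, 3), dtype=int), CS)
    out = spore.distance_to_nearest(grid, {9})
    assert np.isinf(out.values).all()


def test_distance_lipschitz_property():
    from conftest import random_landcover

    grid = random_landcover(42, max_side=25)
    d = spore.distance_to_nearest(grid, {0}).values
    rows, cols = d.shape
    # compare each cell with its right and down neighbours: |d(a)-d(b)| <= dist(a,b)
    assert (np.abs(np.diff(d, axis=0)) <= CS + 1e-9).all()
    assert (np.abs(np.diff(d, axis=1)) <= CS + 1e-9).all()


@pytest.mark.parametrize("seed", range(5))
def test_distance_matches_bruteforce_oracle(seed):
    from conftest import random_landcover

    grid = random_landcover(200 + seed, max_side=30)
    got = spore.distance_to_nearest(grid, {1}).values
    want = oracle_distance_to_nearest(grid.codes, {1}, CS)
    assert np.abs(got - want).max() <= 1e-9


def test_disk_kernel_is_centre_symmetric_and_boundary_inclusive():
    k = disk_kernel(2 * CS, CS)
    assert k.shape == (5, 5)
    assert k[2, 2] and k[2, 0] and k[0, 2]  # centre and distance-2 axis cells
    assert not k[0, 0]  # corner at 2*sqrt(2) cells is outside


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def test_geotiff_roundtrip_landcover_and_score(tmp_path):
    codes = np.array([[1, 2, -1], [2, 2, 1]])
    grid = spore.LandcoverGrid(codes, CS, origin=(1000.0, 2000.0), crs_id="EPSG:32655",
                               class_names={1: "forest", 2: "grass"})
    p = tmp_path / "lc.tif"
    spore.write_landcover_geotiff(p, grid)
    back = spore.read_landcover_geotiff(p)
    assert (back.codes == grid.codes).all()
    assert back.cell_size == CS
    assert back.origin == (1000.0, 2000.0)
    assert back.class_names[1] == "forest"

    layer = spore.ScoreGrid.like(grid, np.array([[0.5, 1.0, 0.0], [0.0, 0.25, 1.0]]),
                                 ~grid.valid_mask)
    q = tmp_path / "score.tif"
    spore.write_score_geotiff(q, layer)
    back2 = spore.read_score_geotiff(q)
    assert back2.nodata_mask[0, 2]
    assert np.allclose(back2.values[~back2.nodata_mask],
                       layer.values[~layer.nodata_mask], atol=1e-7)


def test_geojson_landcover_reader(tmp_path):
    import json

    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"class_code": 2},
                "geometry": {"type": "Polygon",
                             "coordinates": [[[0, 0], [60, 0], [60, 30], [0, 30], [0, 0]]]},
            }
        ],
    }
    p = tmp_path / "lc.geojson"
    p.write_text(json.dumps(doc))
    polys = spore.read_landcover_geojson(p)
    assert len(polys) == 1 and polys[0][0] == 2
    grid = spore.rasterize_landcover(polys, 30, polys[0][1].bounds)
    assert grid.codes.tolist() == [[2, 2]]


def test_grid_validation_errors():
    with pytest.raises(spore.GridError):
        spore.LandcoverGrid(np.array([[1]]), cell_size=0)
    with pytest.raises(spore.GridError):
        spore.LandcoverGrid(np.array([1, 2]), cell_size=30)
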