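"""Road rasterization, vector import and the two artificial road modes."""

import json

import numpy as np
import pytest
from shapely.geometry import LineString, box

from lgraf import (
    create_grid,
    generate_roads_graffe,
    generate_roads_perlin,
    load_road_vector,
    rasterize_roads,
)
from lgraf.fixtures import generate_road_fixture


def brute_force_mask(polylines, grid):
    """Oracle: test every cell square against every segment."""
    mask = np.zeros(grid.shape, dtype=bool)
    c = grid.cell_length_m
    segs = [
        LineString([p, q]) for line in polylines for p, q in zip(line[:-1], line[1:])
    ]
    for row in range(grid.height):
        for col in range(grid.width):
            cell = box(col * c, row * c, (col + 1) * c, (row + 1) * c)
            mask[row, col] = any(s.intersects(cell) for s in segs)
    return mask


def test_horizontal_segment_flags_expected_cells(small_grid):
    mask = rasterize_roads([[(25.0, 25.0), (175.0, 25.0)]], small_grid)
    assert {tuple(x) for x in np.argwhere(mask)[:, ::-1]} == {(0, 0), (1, 0), (2, 0), (3, 0)}


def test_empty_polylines_give_empty_mask(small_grid):
    assert not rasterize_roads([], small_grid).any()


def test_diagonal_segment_follows_closed_square_rule(small_grid):
    # corner to corner of cell (1,1): the segment passes through grid corners
    # shared with neighboring cells, whose closed squares therefore intersect
    mask = rasterize_roads([[(50.0, 50.0), (100.0, 100.0)]], small_grid)
    oracle = brute_force_mask([[(50.0, 50.0), (100.0, 100.0)]], small_grid)
    assert np.array_equal(mask, oracle)
    assert mask[1, 1]  # the traversed cell itself is flagged


def test_random_polylines_match_brute_force_oracle(small_grid, rng):
    for _ in range(5):
        polylines = [
            [(float(x), float(y)) for x, y in rng.uniform(0, 1000, size=(3, 2))]
            for _ in range(5)
        ]
        assert np.array_equal(
            rasterize_roads(polylines, small_grid), brute_force_mask(polylines, small_grid)
        )


# -- vector import ----------------------------------------------------------

def test_load_road_vector_horizontal_line(tmp_path, small_grid):
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {},
                "geometry": {"type": "LineString", "coordinates": [[0, 500], [1000, 500]]},
            }
        ],
    }
    p = tmp_path / "road.geojson"
    p.write_text(json.dumps(doc))
    net = load_road_vector(p, small_grid)
    # after the affine fit the line spans the full width on one row
    assert net.road_mask.sum(axis=1).max() == small_grid.width


def test_load_road_vector_union_of_lines(tmp_path, small_grid):
    fixture = generate_road_fixture(small_grid, tmp_path / "f.geojson", n_lines=2, style="grid")
    net = load_road_vector(fixture, small_grid)
    masks = [rasterize_roads([line], small_grid) for line in net.polylines]
    assert np.array_equal(net.road_mask, np.logical_or.reduce(masks))
    assert len(net.polylines) >= 2


def test_load_road_vector_errors(tmp_path, small_grid):
    p = tmp_path / "empty.geojson"
    p.write_text(json.dumps({"type": "FeatureCollection", "features": []}))
    with pytest.raises(ValueError, match="no line geometries"):
        load_road_vector(p, small_grid)
    p.write_text(
        json.dumps(
            {
                "type": "FeatureCollection",
                "features": [
                    {
                        "type": "Feature",
                        "properties": {},
                        "geometry": {"type": "LineString", "coordinates": [[5, 5], [5, 5]]},
                    }
                ],
            }
        )
    )
    with pytest.raises(ValueError, match="degenerate"):
        load_road_vector(p, small_grid)


# -- straight roads ----------------------------------------------------------

def test_graffe_single_full_span_road(small_grid, rng):
    net = generate_roads_graffe(small_grid, 20, 0.0, rng)
    assert len(net.polylines) == 1
    assert net.total_road_cells == 20


def test_graffe_zero_request_is_empty(small_grid, rng):
    net = generate_roads_graffe(small_grid, 0, 0.0, rng)
    assert net.total_road_cells == 0 and net.polylines == []


def test_graffe_min_distance_respected_over_seeds():
    for seed in range(50):
        grid = create_grid(20, 20, 50.0)
        net = generate_roads_graffe(grid, 150, 5.0, np.random.default_rng(seed))
        rows = sorted(r for r in range(20) if net.road_mask[r, :].all())
        cols = sorted(c for c in range(20) if net.road_mask[:, c].all())
        for offsets in (rows, cols):
            assert all(b - a >= 5 for a, b in zip(offsets, offsets[1:]))


def test_graffe_total_close_to_request(small_grid):
    for seed in range(20):
        net = generate_roads_graffe(
            create_grid(20, 20, 50.0), 100, 2.0, np.random.default_rng(seed)
        )
        assert abs(net.total_road_cells - 100) <= 20  # within one full-span road


# -- noise-guided walker roads -----------------------------------------------

def test_perlin_deterministic_per_seed(small_grid):
    nets = [
        generate_roads_perlin(
            create_grid(20, 20, 50.0), 60, 2.0, rng=np.random.default_rng(42)
        )
        for _ in range(2)
    ]
    assert nets[0].polylines == nets[1].polylines
    assert np.array_equal(nets[0].road_mask, nets[1].road_mask)


def test_perlin_pure_distance_walk_is_monotone(small_grid):
    # dist_weight 1 on a flat elevation: every step decreases the distance
    # to the walker's target
    grid = create_grid(30, 30, 50.0)
    net = generate_roads_perlin(
        grid,
        30,
        0.0,
        cone_angle=180.0,
        dist_weight=1.0,
        rng=np.random.default_rng(3),
        elevation=np.zeros(grid.shape),
    )
    line = net.polylines[0]
    target = line[-1]
    dists = [np.hypot(x - target[0], y - target[1]) for x, y in line]
    assert all(b < a for a, b in zip(dists, dists[1:]))


def test_perlin_reaches_requested_total_over_seeds():
    for seed in range(10):
        grid = create_grid(25, 25, 50.0)
        net = generate_roads_perlin(grid, 50, 1.0, rng=np.random.default_rng(seed))
        assert net.total_road_cells >= 50
        assert net.total_road_cells <= 50 + 3 * int(np.hypot(25, 25) * 2)


def test_road_cells_lie_on_polyline_mask(small_grid, rng):
    net = generate_roads_perlin(create_grid(20, 20, 50.0), 40, 1.0, rng=rng)
    assert np.array_equal(net.road_mask, rasterize_roads(net.polylines, create_grid(20, 20, 50.0)))
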