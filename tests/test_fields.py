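"""Field establishment: search strategies, rectangle proposal, agent loop."""

import numpy as np
import pytest

from lgraf import (
    FIELD,
    OTHERS,
    Config,
    attempt_field_establishment,
    create_grid,
    establish_all_fields,
    find_start_cell,
    propose_field_cells,
)
from lgraf.config import DistributionSpec
from lgraf.settlement import Household


def make_household(homebase=(5, 5), expected=4, hid=0):
    hh = Household(id=hid, expected_area_cells=expected, village_id=0)
    hh.homebase = homebase
    hh.search_origin = homebase
    return hh


def area_cfg(**kw):
    defaults = dict(
        setup_type="households",
        n_households=1,
        field_size_dist=DistributionSpec("constant", 1.0),
        cell_length_m=50.0,
    )
    defaults.update(kw)
    return Config(**defaults)


# -- propose_field_cells -----------------------------------------------------

@pytest.mark.parametrize(
    "size,shape_factor,expected_dims",
    [(4, 1.0, (2, 2)), (8, 4.0, (1, 8)), (6, 1.0, (2, 3))],
)
def test_rectangle_dimensions(size, shape_factor, expected_dims, rng):
    grid = create_grid(20, 20, 50.0)
    cells = propose_field_cells((5, 5), size, shape_factor, grid, rng)
    assert cells is not None and len(cells) == size
    cols = {c for c, _ in cells}
    rows = {r for _, r in cells}
    assert {len(cols), len(rows)} == set(expected_dims)


def test_rectangle_respects_occupancy(rng):
    grid = create_grid(10, 10, 50.0)
    grid.landcover[:, :] = FIELD  # everything taken ...
    grid.landcover[0, 0] = OTHERS  # ... except one corner cell
    assert propose_field_cells((0, 0), 2, 1.0, grid, rng) is None
    assert propose_field_cells((0, 0), 1, 1.0, grid, rng) == [(0, 0)]


def test_rectangle_falls_back_to_other_corners(rng):
    grid = create_grid(10, 10, 50.0)
    grid.landcover[5:, :] = FIELD  # upper half blocked
    for _ in range(20):  # all random orientations / corner orders
        cells = propose_field_cells((5, 4), 4, 1.0, grid, rng)
        assert cells is not None
        assert all(grid.landcover[r, c] == OTHERS for c, r in cells)


# -- find_start_cell ---------------------------------------------------------

def test_s1_prefers_distance_one_ring(rng):
    grid = create_grid(10, 10, 50.0)
    hh = make_household()
    grid.landcover[5, 5] = FIELD  # home-base cell occupied
    start = find_start_cell(hh, "s1.homebase", grid, rng)
    assert start in {(4, 5), (6, 5), (5, 4), (5, 6)}


def test_s1_matches_brute_force_nearest(rng):
    for seed in range(20):
        r = np.random.default_rng(seed)
        grid = create_grid(20, 20, 50.0)
        grid.landcover[r.random((20, 20)) < 0.7] = FIELD
        grid.owner_id[grid.landcover == FIELD] = 999
        grid.field_id[grid.landcover == FIELD] = 999
        hh = make_household(homebase=(10, 10))
        start = find_start_cell(hh, "s1.homebase", grid, r)
        free = np.argwhere(grid.landcover == OTHERS)[:, ::-1]
        if len(free) == 0:
            assert start is None
            continue
        dmin = min(np.hypot(c - 10, w - 10) for c, w in free)
        assert start is not None
        assert np.hypot(start[0] - 10, start[1] - 10) == pytest.approx(dmin)


def test_s2_requires_owned_fields(rng):
    grid = create_grid(10, 10, 50.0)
    hh = make_household()
    assert find_start_cell(hh, "s2.fields", grid, rng) is None
    # give the household one field; the start must touch its vicinity
    grid.landcover[3, 3] = FIELD
    grid.owner_id[3, 3] = 0
    grid.field_id[3, 3] = 0
    hh.owned_fields.append(0)
    start = find_start_cell(hh, "s2.fields", grid, rng)
    assert start is not None
    assert abs(start[0] - 3) <= 1 and abs(start[1] - 3) <= 1


def test_s4_requires_fully_unoccupied_neighborhood(rng):
    grid = create_grid(5, 5, 50.0)
    # checkerboard of fields: every 'others' cell touches a field
    for row in range(5):
        for col in range(5):
            if (row + col) % 2 == 0:
                grid.landcover[row, col] = FIELD
    hh = make_household(homebase=(1, 1))
    assert find_start_cell(hh, "s4.avoid", grid, rng) is None


def test_s4_on_empty_map_avoids_boundary(rng):
    grid = create_grid(10, 10, 50.0)
    hh = make_household(homebase=(0, 0))
    start = find_start_cell(hh, "s4.avoid", grid, rng)
    assert start is not None
    assert 1 <= start[0] <= 8 and 1 <= start[1] <= 8


# -- attempt / strategy switching --------------------------------------------

def test_attempt_success_on_empty_map(rng):
    grid = create_grid(10, 10, 50.0)
    hh = make_household(expected=4)
    status, record = attempt_field_establishment(
        hh, 1, grid, ("s1.homebase",), 3, rng, next_field_id=0
    )
    assert status == "success"
    (col, row), = record.cells
    assert abs(col - 5) <= 1 and abs(row - 5) <= 1
    assert grid.owner_id[row, col] == 0 and hh.realized_area_cells == 1


def test_attempt_exhaustion_on_full_map(rng):
    grid = create_grid(10, 10, 50.0)
    grid.landcover[:, :] = FIELD
    grid.landcover[5, 5] = OTHERS  # only the home-base cell free
    hh = make_household(expected=4)
    statuses = []
    for _ in range(10):
        status, _ = attempt_field_establishment(hh, 2, grid, ("s1.homebase",), 3, rng)
        statuses.append(status)
        if status == "exhausted":
            break
    assert statuses[-1] == "exhausted"
    assert statuses[:-1] == ["failure"] * (len(statuses) - 1)


def test_strategy_switches_after_change_strategy_failures(rng):
    grid = create_grid(10, 10, 50.0)
    grid.landcover[:, :] = FIELD  # force s1 failures (no start cell at all)
    hh = make_household()
    for i in range(2):
        status, _ = attempt_field_establishment(hh, 1, grid, ("s1.homebase", "s3.nearby"), 2, rng)
    assert hh.strategy_index == 1  # switched after exactly two failures
    assert status == "failure"


# -- establishment loop -------------------------------------------------------

def run_single_household(expected_cells, field_ha, grid_size=12, **cfg_kw):
    cfg = area_cfg(field_size_dist=DistributionSpec("constant", field_ha), **cfg_kw)
    grid = create_grid(grid_size, grid_size, 50.0)
    hh = make_household(homebase=(5, 5), expected=expected_cells)
    fields = establish_all_fields(grid, [hh], cfg, np.random.default_rng(0))
    return grid, hh, fields


def test_single_household_exact_realization():
    grid, hh, fields = run_single_household(expected_cells=4, field_ha=1.0)
    assert len(fields) == 1 and fields[0].size == 4
    assert hh.realized_area_cells == hh.expected_area_cells == 4
    assert not hh.growing
    assert (grid.landcover == FIELD).sum() == 4


def test_overshoot_rule_attempts_only_when_closer():
    # expected 14 cells, constant 3-cell fields: 3,6,9,12 then 12+3=15 with
    # |15-14| < |12-14| -> accepted; next draw would move away -> stop at 15
    grid, hh, fields = run_single_household(expected_cells=14, field_ha=0.75)
    assert hh.realized_area_cells == 15
    assert [f.size for f in fields] == [3, 3, 3, 3, 3]


def test_stop_rule_rejects_worsening_draw():
    # expected 4, constant 3-cell fields: 3 then 3+3=6 with |6-4| = 2 > |3-4| -> stop
    grid, hh, fields = run_single_household(expected_cells=4, field_ha=0.75)
    assert hh.realized_area_cells == 3
    assert not hh.growing


def test_first_field_established_even_when_oversized():
    # expected 1 cell but fields are 4 cells: the household still gets a field
    grid, hh, fields = run_single_household(expected_cells=1, field_ha=1.0)
    assert len(fields) == 1 and hh.realized_area_cells == 4


def test_ownership_exclusive_and_area_conserved():
    cfg = area_cfg(
        setup_type="households",
        n_households=8,
        field_size_dist=DistributionSpec("log-normal", 0.5, 0.25),
        hh_area_dist=DistributionSpec("log-normal", 1.5, 0.5),
    )
    grid = create_grid(30, 30, 50.0)
    roster = []
    rng = np.random.default_rng(11)
    from lgraf.config import sample_sizes
    from lgraf import area_ha_to_cells

    for i in range(8):
        hh = make_household(
            homebase=(int(rng.integers(30)), int(rng.integers(30))),
            expected=area_ha_to_cells(float(sample_sizes(cfg.hh_area_dist, 1, rng)[0]), 50.0),
            hid=i,
        )
        roster.append(hh)
    fields = establish_all_fields(grid, roster, cfg, rng)
    # exclusivity: every field cell has exactly the owner of its field record
    for f in fields:
        for col, row in f.cells:
            assert grid.owner_id[row, col] == f.owner_household
            assert grid.field_id[row, col] == f.field_id
    # conservation
    assert sum(h.realized_area_cells for h in roster) == int((grid.landcover == FIELD).sum())
    assert sum(f.size for f in fields) == int((grid.landcover == FIELD).sum())
    grid.validate()


def test_fields_are_eight_connected():
    from lgraf.grid import label_patches

    grid, hh, fields = run_single_household(expected_cells=12, field_ha=1.5)
    for f in fields:
        mask = np.zeros(grid.shape, dtype=bool)
        for col, row in f.cells:
            mask[row, col] = True
        _, n = label_patches(mask, 8)
        assert n == 1


def test_compactness_increases_with_shape_factor():
    from lgraf.metrics import patch_geometry

    mean_shape = {}
    for s_f in (1.0, 2.0, 4.0):
        ratios = []
        for seed in range(50):
            cfg = area_cfg(
                field_shape_factor=s_f,
                field_size_dist=DistributionSpec("constant", 4.0),  # 16-cell fields
            )
            grid = create_grid(30, 30, 50.0)
            hh = make_household(homebase=(15, 15), expected=16)
            establish_all_fields(grid, [hh], cfg, np.random.default_rng(seed))
            for area, perim in patch_geometry(grid.landcover == FIELD, 8):
                ratios.append(perim**2 / area)
        mean_shape[s_f] = np.mean(ratios)
    assert mean_shape[1.0] < mean_shape[2.0] < mean_shape[4.0]
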