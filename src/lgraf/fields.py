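"""Field establishment: the core agent loop.

Households establish rectangular fields until each realizes its expected
household area.  An attempt comprises (1) drawing a field size, (2) moving
to a candidate start cell according to the household's current search
strategy, and (3) checking that a rectangle of the requested size fits
there.  Strategies are tried in the configured order; after ``n_strat``
consecutive failures the household switches to the next strategy, and when
every strategy is exhausted it redraws a fresh field size (bounded number
of redraws, to guarantee termination on crowded maps).

Search strategies
-----------------
s1.homebase
    nearest unoccupied 'others' cell to the household's home-base.
s2.fields
    nearest unoccupied 'others' cell to any cell of its existing fields.
s3.nearby
    expanding-radius search from the most recent search origin.
s4.avoid
    like s3 but the cell and all eight neighbors must be unoccupied
    'others' cells.

Fields may cover road cells and the household's own home-base (cells with
roads still carry a land use); inaccessible cells are never eligible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import Config, area_ha_to_cells, sample_sizes
from .grid import FIELD, OTHERS, LandscapeGrid, iter_offsets_by_ring
from .rng import as_rng
from .settlement import Household

log = logging.getLogger(__name__)

__all__ = [
    "FieldRecord",
    "establish_all_fields",
    "attempt_field_establishment",
    "find_start_cell",
    "propose_field_cells",
]

#: Consecutive freshly-drawn field sizes whose every strategy fails before a
#: household gives up and stops growing.
MAX_SIZE_REDRAWS = 3


@dataclass
class FieldRecord:
    """One established field: contiguous cells, one owner, one crop."""

    field_id: int
    owner_household: int
    cells: list[tuple[int, int]]
    crop_id: int | None = None

    @property
    def size(self) -> int:
        return len(self.cells)


def _eligible(grid: LandscapeGrid, col: int, row: int) -> bool:
    return grid.in_bounds(col, row) and grid.landcover[row, col] == OTHERS


def find_start_cell(
    household: Household,
    strategy: str,
    grid: LandscapeGrid,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, int] | None:
    """Pick a candidate start cell under one search strategy, or None."""
    rng = as_rng(rng)
    max_radius = int(math.ceil(math.hypot(grid.width, grid.height))) + 1

    if strategy == "s2.fields":
        if not household.owned_fields:
            return None
        own = grid.owner_id == household.id
        if not own.any():
            return None
        # Euclidean distance from the household's field set; nearest
        # eligible cell, ties shuffled.
        dist = ndimage.distance_transform_edt(~own)
        cand = (grid.landcover == OTHERS) & (dist > 0)
        if not cand.any():
            return None
        dvals = np.where(cand, dist, np.inf)
        dmin = dvals.min()
        rows, cols = np.nonzero(dvals == dmin)
        i = int(rng.integers(len(rows)))
        return (int(cols[i]), int(rows[i]))

    if strategy == "s1.homebase":
        origin = household.homebase
    elif strategy in ("s3.nearby", "s4.avoid"):
        origin = household.search_origin or household.homebase
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if origin is None:
        return None

    avoid = strategy == "s4.avoid"
    for ring in iter_offsets_by_ring(max_radius):
        eligible = []
        for dx, dy in ring:
            col, row = origin[0] + int(dx), origin[1] + int(dy)
            if not _eligible(grid, col, row):
                continue
            if avoid and not _surrounded_by_others(grid, col, row):
                continue
            eligible.append((col, row))
        if eligible:
            return eligible[int(rng.integers(len(eligible)))]
    return None


def _surrounded_by_others(grid: LandscapeGrid, col: int, row: int) -> bool:
    """All eight neighbors exist and are unoccupied 'others' cells."""
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            if not _eligible(grid, col + dx, row + dy):
                return False
    return True


def propose_field_cells(
    start: tuple[int, int],
    size_cells: int,
    shape_factor: float,
    grid: LandscapeGrid,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[int, int]] | None:
    """Rectangle of ``size_cells`` eligible cells anchored at ``start``.

    Target width ``w = max(1, round(sqrt(size / shape_factor)))`` and length
    ``ceil(size / w)``: shape factor 1 gives compact near-square fields,
    larger factors give narrow strips.  Orientation is random, the rectangle
    is filled row-major and trimmed to the exact size, and all four anchor
    corners are tried before giving up (the space between occupied cells may
    be too small).
    """
    if size_cells < 1:
        raise ValueError("size_cells must be >= 1")
    if shape_factor < 1:
        raise ValueError("shape_factor must be >= 1")
    rng = as_rng(rng)
    w = max(1, int(math.floor(math.sqrt(size_cells / shape_factor) + 0.5)))
    length = int(math.ceil(size_cells / w))
    if rng.random() < 0.5:
        across, along = w, length  # horizontal: long axis on columns
    else:
        across, along = length, w

    corners = [(1, 1), (-1, 1), (1, -1), (-1, -1)]
    rng.shuffle(corners)
    col0, row0 = start
    for sx, sy in corners:
        cells: list[tuple[int, int]] = []
        ok = True
        for j in range(across):
            for i in range(along):
                if len(cells) >= size_cells:
                    break
                col, row = col0 + sx * i, row0 + sy * j
                if not _eligible(grid, col, row):
                    ok = False
                    break
                cells.append((col, row))
            if not ok or len(cells) >= size_cells:
                break
        if ok and len(cells) == size_cells:
            return cells
    return None


def attempt_field_establishment(
    household: Household,
    size_cells: int,
    grid: LandscapeGrid,
    strategies: tuple[str, ...],
    change_after: int,
    rng: np.random.Generator | int | None = None,
    shape_factor: float = 1.0,
    next_field_id: int = 0,
) -> tuple[str, FieldRecord | None]:
    """One establishment try for a field of ``size_cells``.

    Picks a start cell under the household's *current* strategy and checks
    the space there.  Returns ``("success", record)`` with the cells marked
    on the grid, ``("failure", None)`` after an unsuccessful try (the failed
    -tries counter advanced, switching strategy after ``change_after``
    consecutive failures), or ``("exhausted", None)`` once the last strategy
    has failed ``change_after`` times — the caller then draws a new size.
    """
    rng = as_rng(rng)
    strategy = strategies[household.strategy_index]
    start = find_start_cell(household, strategy, grid, rng)
    cells = None
    if start is not None:
        household.search_origin = start
        cells = propose_field_cells(start, size_cells, shape_factor, grid, rng)
    if cells is not None:
        record = FieldRecord(field_id=next_field_id, owner_household=household.id, cells=cells)
        for col, row in cells:
            grid.landcover[row, col] = FIELD
            grid.owner_id[row, col] = household.id
            grid.field_id[row, col] = next_field_id
        household.realized_area_cells += size_cells
        household.owned_fields.append(next_field_id)
        household.failed_tries = 0
        return "success", record
    household.failed_tries += 1
    if household.failed_tries >= change_after:
        household.strategy_index += 1
        household.failed_tries = 0
        if household.strategy_index >= len(strategies):
            return "exhausted", None
    return "failure", None


def establish_all_fields(
    grid: LandscapeGrid,
    roster: list[Household],
    config: Config,
    rng: np.random.Generator | int | None = None,
) -> list[FieldRecord]:
    """Run the establishment loop until no household is still growing.

    Each loop visits the growing households in a fresh seeded shuffle.  A
    household attempts a field only when it brings the realized area closer
    to the expected area; otherwise it stops growing.  Under setup-type
    ``area`` the whole procedure halts once the total established field
    area reaches the configured agricultural proportion.
    """
    rng = as_rng(rng)
    fields: list[FieldRecord] = []
    field_dist = config.effective_field_size_dist()
    area_target = (
        config.prop_agricultural_area * grid.total_cells
        if config.setup_type == "area"
        else None
    )
    total_field_cells = int((grid.landcover == FIELD).sum())

    while True:
        growing = [h for h in roster if h.growing]
        if not growing:
            break
        order = np.arange(len(growing))
        rng.shuffle(order)
        for idx in order:
            hh = growing[idx]
            if not hh.growing:
                continue
            for _ in range(MAX_SIZE_REDRAWS):
                size_ha = float(sample_sizes(field_dist, 1, rng)[0])
                size = area_ha_to_cells(size_ha, config.cell_length_m)
                r, e = hh.realized_area_cells, hh.expected_area_cells
                # every household establishes at least one field; after that a
                # field is only attempted when it brings the realized area
                # closer to the expected area
                if hh.owned_fields and not (r + size < e or abs(r + size - e) < abs(r - e)):
                    hh.growing = False
                    break
                hh.strategy_index = 0
                hh.failed_tries = 0
                status = "failure"
                while status == "failure":
                    status, record = attempt_field_establishment(
                        hh,
                        size,
                        grid,
                        config.strategies,
                        config.change_strategy,
                        rng,
                        shape_factor=config.field_shape_factor,
                        next_field_id=len(fields),
                    )
                if status == "success":
                    assert record is not None
                    fields.append(record)
                    total_field_cells += record.size
                    break
                # exhausted: fall through to the next freshly drawn size
            else:
                # every strategy failed for MAX_SIZE_REDRAWS fresh sizes
                hh.growing = False
                log.debug("household %d stops growing short of target", hh.id)
            if hh.growing and hh.realized_area_cells >= hh.expected_area_cells:
                hh.growing = False
        if area_target is not None and total_field_cells >= area_target:
            for hh in roster:
                hh.growing = False
            break
    shortfall = [h for h in roster if h.realized_area_cells < h.expected_area_cells]
    if shortfall:
        log.info(
            "%d of %d households ended below their expected area", len(shortfall), len(roster)
        )
    return fields
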