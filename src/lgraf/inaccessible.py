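"""Inaccessible areas: patches excluded from smallholder agriculture.

These represent large-scale company plantations or protected (forest)
areas.  Patch sizes are drawn from the configured distribution until the
requested landscape fraction is covered; each patch starts from a random
cell (or random road cell) and is grown as a square block, skipping cells
already taken and completing on the nearest still-available cells.
"""

from __future__ import annotations

import math

import numpy as np

from .config import Config, area_ha_to_cells, draw_until_total
from .grid import INACCESSIBLE, OTHERS, LandscapeGrid, iter_offsets_by_ring
from .rng import as_rng
from .roads import RoadNetwork

__all__ = ["place_inaccessible_areas"]


def place_inaccessible_areas(
    grid: LandscapeGrid,
    road_network: RoadNetwork,
    config: Config,
    rng: np.random.Generator | int | None = None,
    max_relocations: int = 10_000,
) -> LandscapeGrid:
    """Carve inaccessible patches into the landscape, in place.

    The land-cover class becomes ``INACCESSIBLE``; an intersecting road flag
    persists (roads may cross plantations).
    """
    if config.inaccessible_fraction == 0.0:
        return grid
    if config.inaccessible_fraction >= 1.0:
        raise ValueError("inaccessible-area-fraction must be < 1")
    rng = as_rng(rng)

    target_cells = config.inaccessible_fraction * grid.total_cells
    target_ha = target_cells * grid.cell_area_ha
    sizes_ha = draw_until_total(config.inaccessible_dist, target_ha, rng)
    sizes = [area_ha_to_cells(s, grid.cell_length_m) for s in sizes_ha]

    if config.inaccessible_location == "road-connected":
        seeds_pool = np.argwhere(road_network.road_mask)[:, ::-1]
    else:
        seeds_pool = None

    for size in sizes:
        placed = False
        for _ in range(max_relocations):
            if seeds_pool is not None:
                col, row = (int(v) for v in seeds_pool[rng.integers(len(seeds_pool))])
            else:
                col, row = int(rng.integers(grid.width)), int(rng.integers(grid.height))
            if grid.landcover[row, col] != OTHERS:
                continue
            cells = _grow_square_patch(grid, (col, row), size)
            if cells is not None:
                for c, r in cells:
                    grid.landcover[r, c] = INACCESSIBLE
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place the configured inaccessible area "
                f"(patch of {size} cells) after {max_relocations} relocation attempts"
            )
    return grid


def _grow_square_patch(
    grid: LandscapeGrid, seed: tuple[int, int], size: int
) -> list[tuple[int, int]] | None:
    """Square block of ``size`` others-cells anchored at ``seed``.

    The block (side ``ceil(sqrt(size))``) is filled row-major and trimmed to
    the exact size; occupied or out-of-bounds cells are skipped and the
    patch completes on the nearest available others-cells by expanding
    search.  Returns None when the landscape cannot host the patch.
    """
    col0, row0 = seed
    side = int(math.ceil(math.sqrt(size)))
    cells: list[tuple[int, int]] = []
    taken = set()
    for dy in range(side):
        for dx in range(side):
            if len(cells) >= size:
                break
            c, r = col0 + dx, row0 + dy
            if grid.in_bounds(c, r) and grid.landcover[r, c] == OTHERS:
                cells.append((c, r))
                taken.add((c, r))
    if len(cells) < size:
        max_radius = int(math.ceil(math.hypot(grid.width, grid.height))) + 1
        for ring in iter_offsets_by_ring(max_radius):
            for dx, dy in ring:
                c, r = col0 + int(dx), row0 + int(dy)
                if (
                    (c, r) not in taken
                    and grid.in_bounds(c, r)
                    and grid.landcover[r, c] == OTHERS
                ):
                    cells.append((c, r))
                    taken.add((c, r))
                    if len(cells) >= size:
                        break
            if len(cells) >= size:
                break
    return cells if len(cells) >= size else None
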