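"""Household roster construction and placement of villages and home-bases.

Three setup types decide which quantity is fixed at initialization: the
number of households, the number of villages, or the total agricultural
proportion — the other two emerge from the configured household-area and
village-size distributions.  Households live on road cells ("home-bases")
clustered around village centers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .config import Config, area_ha_to_cells, sample_sizes
from .grid import LandscapeGrid, iter_offsets_by_ring
from .rng import as_rng

log = logging.getLogger(__name__)

__all__ = [
    "Household",
    "Village",
    "build_household_roster",
    "place_villages",
    "place_homebases",
]


@dataclass
class Household:
    """One smallholder household agent."""

    id: int
    expected_area_cells: int
    village_id: int
    realized_area_cells: int = 0
    homebase: tuple[int, int] | None = None
    growing: bool = True
    strategy_index: int = 0
    failed_tries: int = 0
    owned_fields: list[int] = dc_field(default_factory=list)
    # origin of the most recent location search (strategy s3 anchor)
    search_origin: tuple[int, int] | None = None


@dataclass
class Village:
    id: int
    center: tuple[int, int] | None = None
    target_size: int = 0


def _village_sizes_for(n_households: int, config: Config, rng: np.random.Generator) -> list[int]:
    """Sampled village sizes covering exactly ``n_households`` households.

    Sizes are drawn in order from the village-size distribution; the final
    village absorbs the remainder so the household total is exact.
    """
    sizes: list[int] = []
    remaining = n_households
    while remaining > 0:
        draw = max(1, int(round(float(sample_sizes(config.village_size_dist, 1, rng)[0]))))
        sizes.append(min(draw, remaining))
        remaining -= sizes[-1]
    return sizes


def build_household_roster(
    config: Config,
    grid: LandscapeGrid,
    rng: np.random.Generator | int | None = None,
) -> list[Household]:
    """Create the preliminary household list (no home-bases yet).

    Expected household areas are sampled from the household-area
    distribution (converted ha -> cells); village ids are assigned by
    filling sampled village sizes sequentially.
    """
    rng = as_rng(rng)

    def draw_area_cells() -> int:
        area_ha = float(sample_sizes(config.hh_area_dist, 1, rng)[0])
        return area_ha_to_cells(area_ha, config.cell_length_m)

    expected: list[int] = []
    if config.setup_type == "households":
        expected = [draw_area_cells() for _ in range(config.n_households)]
        village_sizes = _village_sizes_for(len(expected), config, rng)
    elif config.setup_type == "villages":
        village_sizes = [
            max(1, int(round(float(s))))
            for s in sample_sizes(config.village_size_dist, config.n_villages, rng)
        ]
        expected = [draw_area_cells() for _ in range(sum(village_sizes))]
    else:  # area
        target = config.prop_agricultural_area * grid.total_cells
        total = 0
        while total < target:
            cells = draw_area_cells()
            expected.append(cells)
            total += cells
        village_sizes = _village_sizes_for(len(expected), config, rng)

    capacity = grid.total_cells * (1.0 - config.inaccessible_fraction)
    if sum(expected) > capacity:
        warnings.warn(
            "expected household area exceeds landscape capacity; "
            "field establishment will fall short",
            stacklevel=2,
        )

    roster: list[Household] = []
    vid = 0
    in_village = 0
    for i, cells in enumerate(expected):
        if in_village >= village_sizes[vid]:
            vid += 1
            in_village = 0
        roster.append(Household(id=i, expected_area_cells=cells, village_id=vid))
        in_village += 1
    return roster


def place_villages(
    roster: list[Household],
    road_mask: np.ndarray,
    vlg_min_distance: float,
    rng: np.random.Generator | int | None = None,
    max_tries: int = 10_000,
) -> list[Village]:
    """Put one village center on a random road cell per distinct village id.

    Centers must be pairwise at least ``vlg_min_distance`` apart; each
    center is sampled by rejection, and on exhaustion the constraint is
    relaxed to the best (largest minimum distance) candidate found.
    """
    rng = as_rng(rng)
    road_cells = np.argwhere(road_mask)[:, ::-1]  # (col, row)
    if len(road_cells) == 0:
        raise ValueError("cannot place villages: the road network has no road cells")
    village_ids = sorted({h.village_id for h in roster})
    sizes = {vid: sum(1 for h in roster if h.village_id == vid) for vid in village_ids}

    villages: list[Village] = []
    centers: list[tuple[int, int]] = []
    for vid in village_ids:
        best: tuple[int, int] | None = None
        best_min = -1.0
        chosen = None
        for _ in range(max_tries):
            col, row = (int(v) for v in road_cells[rng.integers(len(road_cells))])
            if not centers:
                chosen = (col, row)
                break
            dmin = min(np.hypot(col - c0, row - r0) for c0, r0 in centers)
            if dmin >= vlg_min_distance:
                chosen = (col, row)
                break
            if dmin > best_min:
                best_min, best = dmin, (col, row)
        if chosen is None:
            warnings.warn(
                f"village {vid}: minimum distance {vlg_min_distance} infeasible, "
                f"relaxed to {best_min:.2f}",
                stacklevel=2,
            )
            chosen = best
        centers.append(chosen)  # type: ignore[arg-type]
        villages.append(Village(id=vid, center=chosen, target_size=sizes[vid]))
    return villages


def place_homebases(
    roster: list[Household],
    villages: list[Village],
    road_mask: np.ndarray,
    grid: LandscapeGrid,
    cap: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Assign each household a home-base road cell near its village center.

    The search expands ring by ring from the center; within the nearest ring
    that still has capacity (fewer than ``cap`` home-bases on a road cell)
    the cell is drawn uniformly.  Returns the home-base count layer and
    fills ``Household.homebase`` in place.
    """
    rng = as_rng(rng)
    n_road = int(road_mask.sum())
    if n_road * cap < len(roster):
        raise ValueError(
            f"road network capacity {n_road * cap} is below the household count {len(roster)}"
        )
    counts = np.zeros(grid.shape, dtype=np.int16)
    by_village = {v.id: v for v in villages}
    max_radius = int(np.ceil(np.hypot(grid.width, grid.height))) + 1

    for hh in roster:
        center = by_village[hh.village_id].center
        assert center is not None
        placed = False
        for ring in iter_offsets_by_ring(max_radius):
            eligible = []
            for dx, dy in ring:
                col, row = center[0] + int(dx), center[1] + int(dy)
                if (
                    grid.in_bounds(col, row)
                    and road_mask[row, col]
                    and counts[row, col] < cap
                ):
                    eligible.append((col, row))
            if eligible:
                col, row = eligible[int(rng.integers(len(eligible)))]
                hh.homebase = (col, row)
                hh.search_origin = (col, row)
                counts[row, col] += 1
                placed = True
                break
        if not placed:  # pragma: no cover - capacity pre-check makes this unreachable
            raise RuntimeError(f"no home-base cell available for household {hh.id}")
    grid.homebase_count = counts
    return counts
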