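"""Map products and tabular outputs.

Seven raster products summarize one generated landscape: a composite
land-use map, a crop-type map, the binary agriculture map, field- and
household-patch maps, the habitat-patches map (patches of class 'others'
with roads acting as separators) and the road mask.  Tables export the
household roster and the class-level metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import FieldRecord
from .grid import FIELD, INACCESSIBLE, OTHERS, LandscapeGrid, label_patches
from .metrics import ClassMetrics, compute_class_metrics
from .settlement import Household

__all__ = [
    "MapProduct",
    "render_layers",
    "habitat_mask",
    "roster_table",
    "metrics_table",
    "standard_class_masks",
]

# composite land-use codes; display precedence home-base > road > landcover
LU_OTHERS = 0
LU_AGRICULTURE = 1
LU_INACCESSIBLE = 2
LU_ROAD = 3
LU_HOMEBASE = 4


@dataclass(frozen=True)
class MapProduct:
    name: str
    layer: np.ndarray
    legend: dict[int, str]


def habitat_mask(grid: LandscapeGrid) -> np.ndarray:
    """'Others' cells excluding roads — roads separate habitat patches."""
    return (grid.landcover == OTHERS) & ~grid.road_flag


def render_layers(
    grid: LandscapeGrid,
    roster: list[Household],
    fields: list[FieldRecord],
    connectivity: int = 8,
) -> list[MapProduct]:
    """Build the standard map products from a completed pipeline state."""
    land_use = np.full(grid.shape, LU_OTHERS, dtype=np.int32)
    land_use[grid.landcover == FIELD] = LU_AGRICULTURE
    land_use[grid.landcover == INACCESSIBLE] = LU_INACCESSIBLE
    land_use[grid.road_flag] = LU_ROAD
    land_use[grid.homebase_count > 0] = LU_HOMEBASE

    crop_type = np.where(grid.crop_id >= 0, grid.crop_id + 1, 0).astype(np.int32)
    agri_binary = (grid.landcover == FIELD).astype(np.int32)
    field_patches = (grid.field_id + 1).astype(np.int32)
    household_patches = (grid.owner_id + 1).astype(np.int32)
    habitat, _ = label_patches(habitat_mask(grid), connectivity)

    crops_present = sorted({f.crop_id for f in fields if f.crop_id is not None})
    return [
        MapProduct(
            "land_use",
            land_use,
            {
                LU_OTHERS: "others",
                LU_AGRICULTURE: "agriculture",
                LU_INACCESSIBLE: "inaccessible",
                LU_ROAD: "road",
                LU_HOMEBASE: "home-base",
            },
        ),
        MapProduct(
            "crop_type",
            crop_type,
            {0: "non-field", **{c + 1: f"crop-{c}" for c in crops_present}},
        ),
        MapProduct("agri_binary", agri_binary, {0: "non-agriculture", 1: "agriculture"}),
        MapProduct("field_patches", field_patches, {0: "no field"}),
        MapProduct("household_patches", household_patches, {0: "unowned"}),
        MapProduct("habitat_patches", habitat.astype(np.int32), {0: "non-habitat"}),
        MapProduct("road_mask", grid.road_flag.astype(np.int32), {0: "no road", 1: "road"}),
    ]


def roster_table(roster: list[Household], grid: LandscapeGrid) -> pd.DataFrame:
    """Household roster as a table (areas in ha, home-base coordinates)."""
    cell_ha = grid.cell_area_ha
    return pd.DataFrame(
        {
            "household_id": [h.id for h in roster],
            "village_id": [h.village_id for h in roster],
            "homebase_col": [h.homebase[0] if h.homebase else -1 for h in roster],
            "homebase_row": [h.homebase[1] if h.homebase else -1 for h in roster],
            "expected_area_ha": [h.expected_area_cells * cell_ha for h in roster],
            "realized_area_ha": [h.realized_area_cells * cell_ha for h in roster],
            "n_fields": [len(h.owned_fields) for h in roster],
        }
    )


def standard_class_masks(grid: LandscapeGrid) -> dict[str, np.ndarray]:
    """The class masks the metrics are routinely computed on."""
    masks = {"fields": grid.landcover == FIELD, "others": habitat_mask(grid)}
    for crop in sorted(set(grid.crop_id[grid.crop_id >= 0].tolist())):
        masks[f"crop_{crop}"] = grid.crop_id == crop
    return masks


def metrics_table(
    grid: LandscapeGrid, seed: int | None = None, connectivity: int = 8
) -> pd.DataFrame:
    """One row per (class, metric): the five statistics per standard class."""
    rows = []
    for cls, mask in standard_class_masks(grid).items():
        m: ClassMetrics = compute_class_metrics(mask, grid, connectivity)
        for metric, value in (
            ("n_patches", m.n_patches),
            ("mean_patch_area_ha", m.mean_patch_area_ha),
            ("lsi", m.lsi),
            ("lpi", m.lpi),
            ("cohesion", m.cohesion),
        ):
            rows.append({"class": cls, "metric": metric, "value": value, "seed": seed})
    return pd.DataFrame(rows)
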