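"""End-to-end generation: roads -> settlement -> inaccessible areas ->
fields -> crops -> metrics -> export.

One master seed fans out into independent per-stage substreams, so a rerun
with the same configuration and seed is byte-identical, and altering one
stage's draws leaves the other stages' sequences untouched.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import secrets
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import ascii_grid
from .config import Config
from .crops import assign_crops
from .fields import FieldRecord, establish_all_fields
from .grid import FIELD, LandscapeGrid, create_grid
from .inaccessible import place_inaccessible_areas
from .outputs import MapProduct, metrics_table, render_layers, roster_table
from .rng import stage_rng
from .roads import (
    RoadNetwork,
    generate_roads_graffe,
    generate_roads_perlin,
    load_road_vector,
)
from .settlement import Household, Village, build_household_roster, place_homebases, place_villages

log = logging.getLogger(__name__)

__all__ = ["GenerationResult", "generate_landscape", "run_generate"]


@dataclass
class GenerationResult:
    """Everything one generator run produces, in memory."""

    config: Config
    seed: int
    grid: LandscapeGrid
    roads: RoadNetwork
    roster: list[Household]
    villages: list[Village]
    fields: list[FieldRecord]

    @property
    def agricultural_fraction(self) -> float:
        return float((self.grid.landcover == FIELD).mean())

    def products(self) -> list[MapProduct]:
        return render_layers(self.grid, self.roster, self.fields)

    def metrics(self) -> pd.DataFrame:
        return metrics_table(self.grid, seed=self.seed)


def generate_landscape(config: Config, seed: int | None = None) -> GenerationResult:
    """Run the full generation pipeline for one landscape.

    The seed precedence is: explicit ``seed`` argument, then the configured
    seed when the reproducible flag is set, else fresh OS entropy (always
    recorded on the result).
    """
    if seed is None:
        seed = config.seed if config.reproducible else secrets.randbelow(2**31)
    seed = int(seed)

    grid = create_grid(config.width, config.height, config.cell_length_m)

    if config.road_type == "shapefile":
        roads = load_road_vector(config.road_file, grid)  # type: ignore[arg-type]
    elif config.road_type == "artificial.graffe":
        roads = generate_roads_graffe(
            grid, config.total_road_length, config.min_dist_roads, stage_rng(seed, "roads")
        )
    else:
        roads = generate_roads_perlin(
            grid,
            config.total_road_length,
            config.min_dist_roads,
            octaves=config.perlin_octaves,
            persistence=config.perlin_persistence,
            cone_angle=config.cone_angle,
            dist_weight=config.dist_weight,
            rng=stage_rng(seed, "roads"),
        )
    grid.road_flag = roads.road_mask.copy()
    log.info("roads: %d cells (target %s)", roads.total_road_cells, config.total_road_length)

    rng_settle = stage_rng(seed, "settlement")
    roster = build_household_roster(config, grid, rng_settle)
    villages = place_villages(roster, roads.road_mask, config.vlg_min_distance, rng_settle)
    place_homebases(roster, villages, roads.road_mask, grid, config.households_per_cell, rng_settle)
    log.info("settlement: %d households in %d villages", len(roster), len(villages))

    place_inaccessible_areas(grid, roads, config, stage_rng(seed, "inaccessible"))

    fields = establish_all_fields(grid, roster, config, stage_rng(seed, "fields"))
    realized = float((grid.landcover == FIELD).mean())
    log.info(
        "fields: %d fields, agricultural fraction %.3f (target %s)",
        len(fields),
        realized,
        config.prop_agricultural_area if config.setup_type == "area" else "emergent",
    )

    assign_crops(grid, fields, roster, config, stage_rng(seed, "crops"))

    grid.validate(homebase_cap=config.households_per_cell)
    return GenerationResult(
        config=config,
        seed=seed,
        grid=grid,
        roads=roads,
        roster=roster,
        villages=villages,
        fields=fields,
    )


def run_generate(
    config: Config,
    out_dir: str | Path,
    seed_override: int | None = None,
) -> GenerationResult:
    """Generate one landscape and write all artifacts into ``out_dir``.

    Artifacts: seven ASCII rasters (one per map product), the roster and
    metrics tables (CSV), and a provenance record (resolved configuration
    and seed, JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = generate_landscape(config, seed_override)

    for product in result.products():
        ascii_grid.write_ascii_grid(
            product.layer, out / f"{product.name}.asc", result.grid.cell_length_m
        )
    roster_table(result.roster, result.grid).to_csv(out / "households.csv", index=False)
    result.metrics().to_csv(out / "metrics.csv", index=False)

    provenance = {
        "seed": result.seed,
        "config": _config_to_jsonable(config),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    return result


def _config_to_jsonable(config: Config) -> dict:
    def conv(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {f.name: conv(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if isinstance(v, tuple):
            return [conv(x) for x in v]
        return v

    return conv(config)  # type: ignore[return-value]
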