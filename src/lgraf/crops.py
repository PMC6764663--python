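"""Crop type assignment.

Every established field receives exactly one of up to five crop types.  Two
modes exist: *landscape-level-fraction* approximates configured landscape
fractions of agricultural area per crop, and *household-level-specialization*
additionally enforces, per crop, a minimum fraction of the households
cultivating that crop that cultivate it exclusively ("specialists").  A
specialization level of 0.7 for crop 1 therefore means at least 70% of the
households growing crop 1 grow nothing else; households owning a single
field are specialists by construction, so realized levels can exceed the
configured minimum.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import Config, CropSpec
from .fields import FieldRecord
from .grid import LandscapeGrid
from .rng import as_rng
from .settlement import Household

log = logging.getLogger(__name__)

__all__ = ["assign_crops", "realized_specialization"]


def _quotas(crops: tuple[CropSpec, ...], fill_up: int, total_cells: int) -> dict[int, float]:
    """Target cell quota per crop; the fill-up crop absorbs any shortfall."""
    quotas = {c.crop_id: round(c.fraction * total_cells) for c in crops}
    shortfall = total_cells - sum(quotas.values())
    if shortfall > 0:
        quotas[fill_up] = quotas.get(fill_up, 0) + shortfall
    return {k: float(v) for k, v in quotas.items()}


def assign_crops(
    grid: LandscapeGrid,
    fields: list[FieldRecord],
    roster: list[Household],
    config: Config,
    rng: np.random.Generator | int | None = None,
) -> None:
    """Assign one crop id to every field, in place (fields and grid layers)."""
    rng = as_rng(rng)
    if not fields:
        return
    total_cells = sum(f.size for f in fields)
    quotas = _quotas(config.crops, config.fill_up_crop, total_cells)
    assigned = {cid: 0.0 for cid in quotas}
    by_household: dict[int, list[FieldRecord]] = {}
    for f in fields:
        by_household.setdefault(f.owner_household, []).append(f)

    def set_crop(field: FieldRecord, crop: int) -> None:
        if field.crop_id is not None:
            assigned[field.crop_id] -= field.size
        field.crop_id = crop
        assigned[crop] += field.size
        for col, row in field.cells:
            grid.crop_id[row, col] = crop

    def make_specialist(hid: int, crop: int) -> None:
        for f in by_household[hid]:
            set_crop(f, crop)

    if config.land_use_assignment == "household-level-specialization":
        # phase 1: seed specialists per crop until their area reaches the
        # configured share of the crop's cell quota
        unassigned = [hid for hid in by_household]
        order = np.array(unassigned)
        rng.shuffle(order)
        pointer = 0
        specialists: dict[int, set[int]] = {cid: set() for cid in quotas}
        for crop in sorted(quotas):
            spec_level = _spec_level(config, crop)
            if spec_level <= 0:
                continue
            while assigned[crop] < spec_level * quotas[crop] and pointer < len(order):
                hid = int(order[pointer])
                pointer += 1
                make_specialist(hid, crop)
                specialists[crop].add(hid)

    # greedy quota fill of the remaining fields: each field takes the crop
    # with the largest remaining cell deficit
    remaining = [f for f in fields if f.crop_id is None]
    order = np.arange(len(remaining))
    rng.shuffle(order)
    for idx in order:
        field = remaining[idx]
        crop = max(quotas, key=lambda cid: quotas[cid] - assigned[cid])
        set_crop(field, crop)

    if config.land_use_assignment == "household-level-specialization":
        _enforce_specialization(config, fields, by_household, set_crop, make_specialist, rng)

    for crop in sorted(quotas):
        if assigned[crop] > quotas[crop] + max(f.size for f in fields):
            log.info(
                "crop %d overshoots its quota (%.0f > %.0f cells); realized "
                "specialization levels can exceed the configured input",
                crop,
                assigned[crop],
                quotas[crop],
            )


def _spec_level(config: Config, crop_id: int) -> float:
    for c in config.crops:
        if c.crop_id == crop_id:
            return c.specialization
    return 0.0


def _enforce_specialization(config, fields, by_household, set_crop, make_specialist, rng) -> None:
    """Promote mixed cultivators to specialists until every crop meets its
    configured minimum household-level specialization."""
    for crop in [c.crop_id for c in config.crops]:
        level = _spec_level(config, crop)
        if level <= 0:
            continue
        while True:
            pure, mixed = _cultivators(by_household, crop)
            n = len(pure) + len(mixed)
            if n == 0 or len(pure) / n >= level:
                break
            ids = sorted(mixed)
            hid = ids[int(rng.integers(len(ids)))]
            make_specialist(hid, crop)


def _cultivators(by_household, crop: int) -> tuple[set[int], set[int]]:
    pure, mixed = set(), set()
    for hid, hh_fields in by_household.items():
        crops = {f.crop_id for f in hh_fields}
        if crops == {crop}:
            pure.add(hid)
        elif crop in crops:
            mixed.add(hid)
    return pure, mixed


def realized_specialization(
    roster: list[Household],
    fields: list[FieldRecord],
    crop_id: int,
) -> float | None:
    """Fraction of the households cultivating ``crop_id`` whose every field
    is ``crop_id``; None when no household cultivates it."""
    by_household: dict[int, set[int | None]] = {}
    for f in fields:
        by_household.setdefault(f.owner_household, set()).add(f.crop_id)
    cultivating = [hid for hid, crops in by_household.items() if crop_id in crops]
    if not cultivating:
        return None
    pure = [hid for hid in cultivating if by_household[hid] == {crop_id}]
    return len(pure) / len(cultivating)
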