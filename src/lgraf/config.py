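"""Configuration parsing and stochastic size sampling.

The generator is driven by a flat key/value document (YAML) whose keys are
the parameter names shown on the original model GUI, e.g. ``hh-area-mean_ha``
or ``field-strategies-id``.  All size distributions (household area, village
size, field size, inaccessible-area patches) share one interface: a
distribution *kind* plus a natural-scale mean and standard deviation.  The
log-normal kind is moment-matched on the natural scale, i.e. the configured
mean/sd are the mean/sd of the draws, not of their logarithms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .rng import as_rng

__all__ = [
    "ConfigError",
    "DistributionSpec",
    "CropSpec",
    "Config",
    "parse_config",
    "load_config",
    "sample_sizes",
    "draw_until_total",
    "area_ha_to_cells",
]

DIST_KINDS = ("constant", "uniform", "normal", "log-normal")
SETUP_TYPES = ("households", "villages", "area")
ROAD_TYPES = ("shapefile", "artificial.perlin", "artificial.graffe")
FIELD_TYPES = ("distribution", "percentage")
STRATEGY_NAMES = ("s1.homebase", "s2.fields", "s3.nearby", "s4.avoid")
ASSIGNMENT_MODES = ("landscape-level-fraction", "household-level-specialization")
INACCESSIBLE_LOCATIONS = ("random", "road-connected")

#: Redraw floor for truncated normal draws, in the unit of the distribution
#: (ha for areas, households for village sizes).  Areas must be positive.
NORMAL_FLOOR = 0.01

FRACTION_TOL = 1e-9


class ConfigError(ValueError):
    """Raised for missing, unknown or out-of-range configuration values."""


@dataclass(frozen=True)
class DistributionSpec:
    """A named size distribution with natural-scale mean and sd.

    ``sd == 0`` behaves identically to ``constant`` for every kind.
    """

    kind: str
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in DIST_KINDS:
            raise ConfigError(f"unknown distribution kind {self.kind!r}")
        if not self.mean > 0:
            raise ConfigError(f"distribution mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ConfigError(f"distribution sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class CropSpec:
    """One crop type: landscape fraction and household specialization level."""

    crop_id: int
    name: str
    fraction: float
    specialization: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError(f"crop fraction for {self.name!r} must be in [0,1]")
        if not 0.0 <= self.specialization <= 1.0:
            raise ConfigError(f"specialization for {self.name!r} must be in [0,1]")


@dataclass(frozen=True)
class Config:
    """Validated full parameter set of the generator."""

    # landscape / setup
    setup_type: str = "area"
    n_households: int = 50
    n_villages: int = 3
    prop_agricultural_area: float = 0.3
    households_per_cell: int = 4
    seed: int = 0
    reproducible: bool = True
    width: int = 100
    height: int = 100
    cell_length_m: float = 50.0
    # roads
    road_type: str = "artificial.graffe"
    road_file: str | None = None
    total_road_length: int = 500
    min_dist_roads: float = 5.0
    perlin_octaves: int = 4
    perlin_persistence: float = 0.5
    cone_angle: float = 90.0
    dist_weight: float = 0.7
    # villages
    village_size_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("log-normal", 20.0, 10.0)
    )
    vlg_min_distance: float = 10.0
    # households
    hh_area_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("log-normal", 2.0, 1.0)
    )
    # inaccessible areas
    inaccessible_fraction: float = 0.0
    inaccessible_location: str = "random"
    inaccessible_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("constant", 10.0, 0.0)
    )
    # fields
    field_type: str = "distribution"
    field_size_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("log-normal", 1.0, 0.5)
    )
    field_size_percentage: float = 0.5
    field_shape_factor: float = 1.0
    strategies: tuple[str, ...] = STRATEGY_NAMES
    change_strategy: int = 3
    # crops
    land_use_assignment: str = "landscape-level-fraction"
    crops: tuple[CropSpec, ...] = (CropSpec(1, "crop-1", 1.0),)
    fill_up_crop: int = 1

    def __post_init__(self) -> None:
        _check_enum("setup-type", self.setup_type, SETUP_TYPES)
        _check_enum("road-type", self.road_type, ROAD_TYPES)
        _check_enum("field-type", self.field_type, FIELD_TYPES)
        _check_enum("land-use-assignment", self.land_use_assignment, ASSIGNMENT_MODES)
        _check_enum(
            "inaccessible-area-location", self.inaccessible_location, INACCESSIBLE_LOCATIONS
        )
        _check_positive_int("number-of-farmers", self.n_households)
        _check_positive_int("number-of-villages", self.n_villages)
        _check_positive_int("households-per-cell", self.households_per_cell)
        _check_positive_int("width", self.width)
        _check_positive_int("height", self.height)
        _check_positive_int("change-strategy", self.change_strategy)
        if not self.cell_length_m > 0:
            raise ConfigError("cell-length-meter must be > 0")
        if self.setup_type == "area" and not 0.0 < self.prop_agricultural_area < 1.0:
            raise ConfigError("prop-agricultural-area must be in (0,1)")
        if self.road_type == "shapefile" and not self.road_file:
            raise ConfigError("road-map-file is required when road-type is 'shapefile'")
        if self.road_type != "shapefile":
            if self.total_road_length < 0:
                raise ConfigError("total-road-length must be >= 0")
            if self.min_dist_roads < 0:
                raise ConfigError("min-dist-roads must be >= 0")
        if self.road_type == "artificial.perlin":
            if self.perlin_octaves < 1:
                raise ConfigError("perlin-octaves must be >= 1")
            if not 0.0 < self.perlin_persistence <= 1.0:
                raise ConfigError("perlin-persistence must be in (0,1]")
            if not 0.0 < self.cone_angle <= 180.0:
                raise ConfigError("cone-angle must be in (0,180]")
            if not 0.0 <= self.dist_weight <= 1.0:
                raise ConfigError("dist-weight must be in [0,1]")
        if self.hh_area_dist.kind not in ("normal", "log-normal"):
            raise ConfigError(
                "hh-area-distribution must be 'normal' or 'log-normal', "
                f"got {self.hh_area_dist.kind!r}"
            )
        if not 0.0 <= self.inaccessible_fraction < 1.0:
            raise ConfigError("inaccessible-area-fraction must be in [0,1)")
        if self.field_type == "percentage" and not 0.0 < self.field_size_percentage <= 1.0:
            raise ConfigError("field-size-percentage must be in (0,1]")
        if self.field_shape_factor < 1.0:
            raise ConfigError(
                "field-shape-factor must be >= 1 "
                "(rectangular at 1, narrower fields above 1)"
            )
        if not self.strategies:
            raise ConfigError("field establishment strategy list must be non-empty")
        for s in self.strategies:
            _check_enum("field strategy", s, STRATEGY_NAMES)
        if not self.crops:
            raise ConfigError("at least one crop type is required")
        if len(self.crops) > 5:
            raise ConfigError("at most five crop types are supported")
        total = sum(c.fraction for c in self.crops)
        if total > 1.0 + FRACTION_TOL:
            raise ConfigError(f"crop fractions must sum up to 1, got {total:g}")
        ids = [c.crop_id for c in self.crops]
        if len(set(ids)) != len(ids):
            raise ConfigError("crop ids must be unique")
        if total < 1.0 - FRACTION_TOL and self.fill_up_crop not in ids:
            raise ConfigError(
                "LUT-fill-up must name a declared crop when fractions sum below 1"
            )

    # -- derived quantities -------------------------------------------------
    @property
    def cell_area_ha(self) -> float:
        return (self.cell_length_m / 100.0) ** 2

    @property
    def total_cells(self) -> int:
        return self.width * self.height

    def effective_field_size_dist(self) -> DistributionSpec:
        """Field size distribution after the percentage adjustment.

        Under ``field-type: percentage`` the mean of the field size
        distribution is set to the configured percentage of the household
        area mean before any sampling.
        """
        if self.field_type == "percentage":
            return replace(
                self.field_size_dist,
                mean=self.field_size_percentage * self.hh_area_dist.mean,
            )
        return self.field_size_dist


def _check_enum(key: str, value: str, allowed: Sequence[str]) -> None:
    if value not in allowed:
        raise ConfigError(f"{key}: {value!r} is not one of {list(allowed)}")


def _check_positive_int(key: str, value: int) -> None:
    if not (isinstance(value, (int, np.integer)) and value >= 1):
        raise ConfigError(f"{key} must be a positive integer, got {value!r}")


# ---------------------------------------------------------------------------
# document parsing

_SCALARS = {
    "setup-type": ("setup_type", str),
    "number-of-farmers": ("n_households", int),
    "number-of-villages": ("n_villages", int),
    "prop-agricultural-area": ("prop_agricultural_area", float),
    "households-per-cell": ("households_per_cell", int),
    "rnd-seed": ("seed", int),
    "reproducable?": ("reproducible", bool),
    "width": ("width", int),
    "height": ("height", int),
    "cell-length-meter": ("cell_length_m", float),
    "road-type": ("road_type", str),
    "road-map-file": ("road_file", str),
    "total-road-length": ("total_road_length", int),
    "min-dist-roads": ("min_dist_roads", float),
    "perlin-octaves": ("perlin_octaves", int),
    "perlin-persistence": ("perlin_persistence", float),
    "cone-angle": ("cone_angle", float),
    "dist-weight": ("dist_weight", float),
    "vlg-min-distance": ("vlg_min_distance", float),
    "inaccessible-area-fraction": ("inaccessible_fraction", float),
    "inaccessible-area-location": ("inaccessible_location", str),
    "field-type": ("field_type", str),
    "field-size-percentage": ("field_size_percentage", float),
    "field-shape-factor": ("field_shape_factor", float),
    "change-strategy": ("change_strategy", int),
    "land-use-assignment": ("land_use_assignment", str),
    "LUT-fill-up": ("fill_up_crop", int),
}

_DISTS = {
    "vlg-size": ("village_size_dist", "vlg-size-distribution", "vlg-size-mean_ha", "vlg-size-sd_ha"),
    "hh-area": ("hh_area_dist", "hh-area-distribution", "hh-area-mean_ha", "hh-area-sd_ha"),
    "inaccessible-area": (
        "inaccessible_dist",
        "inaccessible-area-distribution",
        "inaccessible-area-mean",
        "inaccessible-area-sd",
    ),
    # the two field-size keys are printed with underscores on the GUI table
    "field-size": ("field_size_dist", "field-size-distribution", "field_size_mean_ha", "field_size_sd_ha"),
}

_STRATEGY_FLAGS = {f"s{i}": name for i, name in enumerate(STRATEGY_NAMES, start=1)}


def parse_config(document: dict) -> Config:
    """Validate a flat key/value mapping into a :class:`Config`.

    Unknown keys are rejected; only the parameters relevant to the chosen
    enum branches are required, everything else falls back to the package
    defaults.
    """
    if not isinstance(document, dict):
        raise ConfigError("configuration document must be a mapping")
    doc = dict(document)
    kwargs: dict = {}

    for key, (attr, typ) in _SCALARS.items():
        if key in doc:
            value = doc.pop(key)
            try:
                kwargs[attr] = typ(value) if not isinstance(value, bool) or typ is bool else value
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{key}: cannot interpret {value!r}") from exc

    for (attr, kkind, kmean, ksd) in _DISTS.values():
        if any(k in doc for k in (kkind, kmean, ksd)):
            defaults: DistributionSpec = getattr(Config, "__dataclass_fields__")[attr].default_factory()  # type: ignore[misc]
            kwargs[attr] = DistributionSpec(
                kind=str(doc.pop(kkind, defaults.kind)),
                mean=float(doc.pop(kmean, defaults.mean)),
                sd=float(doc.pop(ksd, defaults.sd)),
            )

    kwargs.update(_pop_strategies(doc))
    crops = _pop_crops(doc)
    if crops is not None:
        kwargs["crops"] = crops

    if doc:
        raise ConfigError(f"unknown configuration keys: {sorted(doc)}")
    return Config(**kwargs)


def _pop_strategies(doc: dict) -> dict:
    out: dict = {}
    stype = doc.pop("strategies-type", None)
    if stype is not None and stype not in ("manual", "id"):
        raise ConfigError(f"strategies-type: {stype!r} is not one of ['manual', 'id']")
    listed = doc.pop("field-strategies-id", None)
    flags = [name for name in STRATEGY_NAMES if doc.pop(name, False)]
    if stype == "id" or (stype is None and listed is not None):
        if listed is None:
            raise ConfigError("field-strategies-id is required when strategies-type is 'id'")
        if isinstance(listed, str):
            listed = [s.strip() for s in listed.split(",") if s.strip()]
        out["strategies"] = tuple(_STRATEGY_FLAGS.get(s, s) for s in listed)
    elif stype == "manual" or flags:
        if not flags:
            raise ConfigError("manual strategy selection requires at least one strategy flag")
        out["strategies"] = tuple(flags)
    return out


def _pop_crops(doc: dict) -> tuple[CropSpec, ...] | None:
    found = {}
    for l in range(1, 6):
        name = doc.pop(f"LUT-{l}-name", None)
        fraction = doc.pop(f"LUT-{l}-fraction", None)
        spec = doc.pop(f"LUT-{l}-specialize", None)
        if name is None and fraction is None and spec is None:
            continue
        if fraction is None:
            raise ConfigError(f"LUT-{l}-fraction is required for declared crop {l}")
        found[l] = CropSpec(
            crop_id=l,
            name=str(name) if name is not None else f"crop-{l}",
            fraction=float(fraction),
            specialization=float(spec) if spec is not None else 0.0,
        )
    if not found:
        return None
    return tuple(found[l] for l in sorted(found))


def load_config(path: str | Path) -> Config:
    """Read and validate a YAML configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc or {})


# ---------------------------------------------------------------------------
# sampling

def sample_sizes(
    dist: DistributionSpec,
    n: int,
    rng: np.random.Generator | int | None = None,
    floor: float = NORMAL_FLOOR,
) -> np.ndarray:
    """Draw ``n`` positive sizes from ``dist``.

    constant
        returns the mean exactly.
    uniform
        moment-matched to (mean, sd): support ``[mean - sqrt(3) sd,
        mean + sqrt(3) sd]``; an error if the lower bound is not positive.
    normal
        truncated below at ``floor`` by redraw.
    log-normal
        natural-scale moment matching,
        ``mu_log = ln(mean^2 / sqrt(sd^2 + mean^2))``,
        ``sigma_log = sqrt(ln(1 + sd^2 / mean^2))``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = as_rng(rng)
    if n == 0:
        return np.empty(0)
    if dist.sd == 0.0 or dist.kind == "constant":
        return np.full(n, float(dist.mean))
    if dist.kind == "uniform":
        half = math.sqrt(3.0) * dist.sd
        lo, hi = dist.mean - half, dist.mean + half
        if lo <= 0:
            raise ConfigError(
                f"uniform distribution lower bound {lo:g} is not positive "
                f"(mean={dist.mean:g}, sd={dist.sd:g})"
            )
        return rng.uniform(lo, hi, size=n)
    if dist.kind == "normal":
        if not floor > 0:
            raise ValueError("truncation floor must be positive")
        out = rng.normal(dist.mean, dist.sd, size=n)
        bad = out < floor
        while bad.any():
            out[bad] = rng.normal(dist.mean, dist.sd, size=int(bad.sum()))
            bad = out < floor
        return out
    # log-normal
    mu = math.log(dist.mean**2 / math.sqrt(dist.sd**2 + dist.mean**2))
    sigma = math.sqrt(math.log(1.0 + dist.sd**2 / dist.mean**2))
    return rng.lognormal(mu, sigma, size=n)


def draw_until_total(
    dist: DistributionSpec,
    target_total: float,
    rng: np.random.Generator | int | None = None,
) -> list[float]:
    """Draw sizes until their sum reaches ``target_total``.

    The result is minimal: dropping the last draw puts the sum below the
    target.  Always terminates because every draw is positive.
    """
    if not target_total > 0:
        raise ValueError("target_total must be > 0")
    rng = as_rng(rng)
    out: list[float] = []
    total = 0.0
    while total < target_total:
        draw = float(sample_sizes(dist, 1, rng)[0])
        out.append(draw)
        total += draw
    return out


def area_ha_to_cells(area_ha: float, cell_length_m: float) -> int:
    """Convert an area in hectares to a whole number of grid cells.

    Nearest integer with a floor of one cell: the cell side is chosen to
    roughly match the smallest field, so any positive area occupies at
    least one cell.
    """
    if not (area_ha > 0 and cell_length_m > 0):
        raise ValueError("area_ha and cell_length_m must be > 0")
    cell_area = (cell_length_m / 100.0) ** 2
    return max(1, int(math.floor(area_ha / cell_area + 0.5)))
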