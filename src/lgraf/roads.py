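"""Road network creation.

Roads are dimensionless polylines in landscape coordinates (meters).  A grid
cell counts as a road cell iff at least one polyline segment intersects its
*closed* square — a supercover rasterization, so diagonal road runs leave no
gaps.  Networks come from three sources: an external GeoJSON line layer, the
full-span straight-road algorithm (axis-aligned roads with alternating
orientation), or a noise-guided walker over a fractal
elevation surface ("perlin" mode).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, box, shape

from .grid import LandscapeGrid
from .rng import as_rng

__all__ = [
    "RoadNetwork",
    "rasterize_roads",
    "load_road_vector",
    "generate_roads_graffe",
    "generate_roads_perlin",
]

Polyline = list[tuple[float, float]]


@dataclass
class RoadNetwork:
    """Polylines plus the derived road-cell mask."""

    polylines: list[Polyline]
    road_mask: np.ndarray

    @property
    def total_road_cells(self) -> int:
        return int(self.road_mask.sum())

    @classmethod
    def from_polylines(cls, polylines: list[Polyline], grid: LandscapeGrid) -> "RoadNetwork":
        return cls(polylines=polylines, road_mask=rasterize_roads(polylines, grid))


def rasterize_roads(polylines: list[Polyline], grid: LandscapeGrid) -> np.ndarray:
    """Boolean road mask: cell flagged iff a segment intersects its closed square."""
    mask = np.zeros(grid.shape, dtype=bool)
    c = grid.cell_length_m
    for line in polylines:
        for (x0, y0), (x1, y1) in zip(line[:-1], line[1:]):
            seg = LineString([(x0, y0), (x1, y1)])
            cmin = max(0, int(math.floor(min(x0, x1) / c)))
            cmax = min(grid.width - 1, int(math.floor(max(x0, x1) / c)))
            rmin = max(0, int(math.floor(min(y0, y1) / c)))
            rmax = min(grid.height - 1, int(math.floor(max(y0, y1) / c)))
            # a segment endpoint exactly on a cell edge touches the next cell's
            # closed square too; widen the candidate window by one cell
            for row in range(max(0, rmin - 1), min(grid.height, rmax + 2)):
                for col in range(max(0, cmin - 1), min(grid.width, cmax + 2)):
                    if mask[row, col]:
                        continue
                    cell = box(col * c, row * c, (col + 1) * c, (row + 1) * c)
                    if seg.intersects(cell):
                        mask[row, col] = True
    return mask


def load_road_vector(path: str | Path, grid: LandscapeGrid) -> RoadNetwork:
    """Read a GeoJSON line layer and fit it onto the landscape extent.

    Coordinates are mapped by an affine fit of the data bounding box onto the
    grid extent, then clipped to the grid.
    """
    with open(path) as fh:
        doc = json.load(fh)
    geoms = []
    features = doc.get("features", [doc]) if isinstance(doc, dict) else []
    for feat in features:
        geom = feat.get("geometry", feat)
        if geom is None:
            continue
        g = shape(geom)
        if g.geom_type == "LineString":
            geoms.append(g)
        elif g.geom_type == "MultiLineString":
            geoms.extend(g.geoms)
    if not geoms:
        raise ValueError(f"no line geometries found in {path}")

    xs = [x for g in geoms for x in g.xy[0]]
    ys = [y for g in geoms for y in g.xy[1]]
    x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
    if x1 == x0 and y1 == y0:
        raise ValueError("degenerate (zero-extent) road bounding box")
    w = grid.width * grid.cell_length_m
    h = grid.height * grid.cell_length_m
    # map onto the open extent; shrink slightly so the far edge stays in-grid.
    # An axis with zero extent (a single straight line) is centered instead.
    eps = 1e-9
    sx = (w * (1 - eps)) / (x1 - x0) if x1 > x0 else 0.0
    sy = (h * (1 - eps)) / (y1 - y0) if y1 > y0 else 0.0

    def tx(x: float) -> float:
        return (x - x0) * sx if sx else (int(grid.width / 2) + 0.5) * grid.cell_length_m

    def ty(y: float) -> float:
        return (y - y0) * sy if sy else (int(grid.height / 2) + 0.5) * grid.cell_length_m

    extent = box(0, 0, w, h)
    polylines: list[Polyline] = []
    for g in geoms:
        mapped = LineString([(tx(x), ty(y)) for x, y in zip(*g.xy)])
        clipped = mapped.intersection(extent)
        parts = [clipped] if clipped.geom_type == "LineString" else list(getattr(clipped, "geoms", []))
        for part in parts:
            if part.geom_type == "LineString" and len(part.coords) >= 2:
                polylines.append([(float(x), float(y)) for x, y in part.coords])
    if not polylines:
        raise ValueError("all road geometries fell outside the landscape extent")
    return RoadNetwork.from_polylines(polylines, grid)


# ---------------------------------------------------------------------------
# straight roads

def generate_roads_graffe(
    grid: LandscapeGrid,
    total_road_length: int,
    min_dist: float,
    rng: np.random.Generator | int | None = None,
) -> RoadNetwork:
    """Full-span straight roads with alternating orientation.

    Roads are appended — horizontal/vertical alternating, starting from a
    random orientation, each at a uniformly drawn row/column offset at least
    ``min_dist`` from every existing same-orientation road — until the road
    mask holds ``total_road_length`` cells or no admissible offset remains.
    """
    if total_road_length > 0.5 * grid.total_cells:
        raise ValueError("total-road-length may not exceed half the landscape cells")
    rng = as_rng(rng)
    polylines: list[Polyline] = []
    used = {"h": [], "v": []}  # occupied row / column offsets
    c = grid.cell_length_m
    orientation = "h" if rng.random() < 0.5 else "v"
    mask = np.zeros(grid.shape, dtype=bool)

    while mask.sum() < total_road_length:
        placed = False
        for orient in (orientation, "h" if orientation == "v" else "v"):
            n = grid.height if orient == "h" else grid.width
            admissible = [
                k for k in range(n)
                if all(abs(k - u) >= min_dist for u in used[orient])
            ]
            if not admissible:
                continue
            k = int(rng.choice(admissible))
            used[orient].append(k)
            if orient == "h":
                y = (k + 0.5) * c
                line = [(0.0, y), (grid.width * c - 1e-9, y)]
            else:
                x = (k + 0.5) * c
                line = [(x, 0.0), (x, grid.height * c - 1e-9)]
            polylines.append(line)
            mask |= rasterize_roads([line], grid)
            placed = True
            break
        if not placed:
            break  # constrained landscape: accept the shortfall
        orientation = "h" if orientation == "v" else "v"

    return RoadNetwork(polylines=polylines, road_mask=mask)


# ---------------------------------------------------------------------------
# noise-guided walker roads ("perlin" mode)

def fractal_noise(
    shape: tuple[int, int],
    octaves: int,
    persistence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fractal value-noise elevation in [0, 1] over the grid cells.

    Octave ``o`` contributes bilinearly interpolated white noise on a lattice
    of spacing ``2**(octaves - o)`` cells with amplitude ``persistence**o``.
    """
    h, w = shape
    out = np.zeros(shape)
    amp_sum = 0.0
    for o in range(octaves):
        spacing = max(1, 2 ** (octaves - o - 1))
        gh, gw = h // spacing + 2, w // spacing + 2
        lattice = rng.random((gh, gw))
        ys = np.arange(h) / spacing
        xs = np.arange(w) / spacing
        y0 = ys.astype(int)
        x0 = xs.astype(int)
        fy = (ys - y0)[:, None]
        fx = (xs - x0)[None, :]
        a = lattice[np.ix_(y0, x0)]
        b = lattice[np.ix_(y0, x0 + 1)]
        cc = lattice[np.ix_(y0 + 1, x0)]
        d = lattice[np.ix_(y0 + 1, x0 + 1)]
        octv = a * (1 - fx) * (1 - fy) + b * fx * (1 - fy) + cc * (1 - fx) * fy + d * fx * fy
        amp = persistence**o
        out += amp * octv
        amp_sum += amp
    out /= amp_sum
    lo, hi = out.min(), out.max()
    return (out - lo) / (hi - lo) if hi > lo else np.zeros(shape)


_NEIGHBORS = [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)]


def _random_boundary_cell(grid: LandscapeGrid, rng: np.random.Generator) -> tuple[int, int]:
    side = rng.integers(4)
    if side == 0:
        return int(rng.integers(grid.width)), 0
    if side == 1:
        return int(rng.integers(grid.width)), grid.height - 1
    if side == 2:
        return 0, int(rng.integers(grid.height))
    return grid.width - 1, int(rng.integers(grid.height))


def _opposite_boundary_cell(
    grid: LandscapeGrid, start: tuple[int, int], rng: np.random.Generator
) -> tuple[int, int]:
    col, row = start
    if row == 0:
        return int(rng.integers(grid.width)), grid.height - 1
    if row == grid.height - 1:
        return int(rng.integers(grid.width)), 0
    if col == 0:
        return grid.width - 1, int(rng.integers(grid.height))
    return 0, int(rng.integers(grid.height))


def generate_roads_perlin(
    grid: LandscapeGrid,
    total_road_length: int,
    min_dist: float,
    octaves: int = 4,
    persistence: float = 0.5,
    cone_angle: float = 90.0,
    dist_weight: float = 0.7,
    rng: np.random.Generator | int | None = None,
    elevation: np.ndarray | None = None,
) -> RoadNetwork:
    """Roads carved by walkers over a fractal elevation surface.

    The first walker starts at a random boundary cell heading inward toward a
    target on the opposite boundary.  At each step the candidate neighbor
    cells inside the forward cone of half-angle ``cone_angle / 2`` are scored
    ``dist_weight * (normalized distance to target) + (1 - dist_weight) *
    (normalized elevation)`` and the walker moves to the minimum.  Subsequent
    walkers branch from random existing road cells; once a branching walker
    has moved more than ``min_dist`` from its origin, candidate steps within
    ``min_dist`` of foreign road cells are avoided when an alternative exists.
    Walkers are added until the rasterized mask holds ``total_road_length``
    cells.
    """
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    if not 0.0 < persistence <= 1.0:
        raise ValueError("persistence must be in (0,1]")
    if not 0.0 < cone_angle <= 180.0:
        raise ValueError("cone-angle must be in (0,180]")
    if not 0.0 <= dist_weight <= 1.0:
        raise ValueError("dist-weight must be in [0,1]")
    rng = as_rng(rng)
    if elevation is None:
        elevation = fractal_noise(grid.shape, octaves, persistence, rng)
    c = grid.cell_length_m
    diag = math.hypot(grid.width, grid.height)
    polylines: list[Polyline] = []
    mask = np.zeros(grid.shape, dtype=bool)
    road_cells: list[tuple[int, int]] = []
    half_cone = math.radians(cone_angle) / 2.0
    max_walkers = 4 * (grid.width + grid.height)  # generous stopping guard

    for walker in range(max_walkers):
        if total_road_length <= 0 or mask.sum() >= total_road_length:
            break
        if walker == 0 or not road_cells:
            start = _random_boundary_cell(grid, rng)
            branching = False
        else:
            start = road_cells[int(rng.integers(len(road_cells)))]
            branching = True
        target = _opposite_boundary_cell(grid, start, rng) if not branching else _random_boundary_cell(grid, rng)
        if start == target:
            continue
        own: set[tuple[int, int]] = {start}
        path = [start]
        pos = start
        heading = math.atan2(target[1] - pos[1], target[0] - pos[0])
        for _ in range(int(3 * diag)):
            if pos == target or (
                len(path) > 1 and (pos[0] in (0, grid.width - 1) or pos[1] in (0, grid.height - 1))
            ):
                break
            candidates = []
            for dx, dy in _NEIGHBORS:
                col, row = pos[0] + dx, pos[1] + dy
                if not grid.in_bounds(col, row) or (col, row) in own:
                    continue
                ang = math.atan2(dy, dx)
                diff = abs((ang - heading + math.pi) % (2 * math.pi) - math.pi)
                if diff > half_cone + 1e-12:
                    continue
                dist = math.hypot(target[0] - col, target[1] - row)
                score = dist_weight * (dist / diag) + (1 - dist_weight) * float(elevation[row, col])
                foreign_near = branching and _near_foreign_road(
                    (col, row), mask, own, min_dist, grid
                )
                candidates.append((foreign_near, score, (col, row), (dx, dy)))
            if not candidates:
                break
            left_origin = math.hypot(pos[0] - start[0], pos[1] - start[1]) > min_dist
            if branching and left_origin and any(not f for f, *_ in candidates):
                candidates = [cand for cand in candidates if not cand[0]]
            candidates.sort(key=lambda cand: cand[1])
            _, _, nxt, (dx, dy) = candidates[0]
            heading = math.atan2(dy, dx)
            own.add(nxt)
            path.append(nxt)
            pos = nxt
        if len(path) < 2:
            continue
        line = [((col + 0.5) * c, (row + 0.5) * c) for col, row in path]
        polylines.append(line)
        mask |= rasterize_roads([line], grid)
        road_cells = [tuple(int(v) for v in rc) for rc in np.argwhere(mask)[:, ::-1]]  # (col,row)

    return RoadNetwork(polylines=polylines, road_mask=mask)


def _near_foreign_road(
    cell: tuple[int, int],
    mask: np.ndarray,
    own: set[tuple[int, int]],
    min_dist: float,
    grid: LandscapeGrid,
) -> bool:
    col, row = cell
    r = int(math.ceil(min_dist))
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dx * dx + dy * dy > min_dist * min_dist:
                continue
            cc, rr = col + dx, row + dy
            if grid.in_bounds(cc, rr) and mask[rr, cc] and (cc, rr) not in own:
                return True
    return False
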