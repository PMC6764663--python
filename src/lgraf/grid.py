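"""The cell lattice and its layers.

Layers are numpy arrays of shape ``(height, width)`` indexed ``[row, col]``
with row 0 the *bottom* row: cell coordinates are ``(col, row)``, 0-based,
origin at the lower-left corner, and the world extent in meters is the
half-open box ``[0, width * cell_length_m) x [0, height * cell_length_m)``.
The world is bounded (non-wrapping).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .rng import as_rng

# land-cover class codes
OTHERS = 0
FIELD = 1
INACCESSIBLE = 2


@dataclass
class LandscapeGrid:
    """Aligned per-cell layers of one landscape."""

    width: int
    height: int
    cell_length_m: float
    landcover: np.ndarray = dc_field(repr=False, default=None)  # type: ignore[assignment]
    owner_id: np.ndarray = dc_field(repr=False, default=None)  # type: ignore[assignment]
    field_id: np.ndarray = dc_field(repr=False, default=None)  # type: ignore[assignment]
    crop_id: np.ndarray = dc_field(repr=False, default=None)  # type: ignore[assignment]
    road_flag: np.ndarray = dc_field(repr=False, default=None)  # type: ignore[assignment]
    homebase_count: np.ndarray = dc_field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def total_cells(self) -> int:
        return self.width * self.height

    @property
    def cell_area_ha(self) -> float:
        return (self.cell_length_m / 100.0) ** 2

    @property
    def area_ha(self) -> float:
        return self.total_cells * self.cell_area_ha

    def in_bounds(self, col: int, row: int) -> bool:
        return 0 <= col < self.width and 0 <= row < self.height

    def validate(self, homebase_cap: int | None = None) -> None:
        """Assert the cross-layer invariants; raises AssertionError on violation."""
        shapes = {
            layer.shape
            for layer in (
                self.landcover,
                self.owner_id,
                self.field_id,
                self.crop_id,
                self.road_flag,
                self.homebase_count,
            )
        }
        assert shapes == {self.shape}, "layer shapes differ"
        is_field = self.landcover == FIELD
        assert np.array_equal(self.owner_id >= 0, is_field), "owner_id <-> field mismatch"
        assert np.array_equal(self.field_id >= 0, is_field), "field_id <-> field mismatch"
        assert not np.any((self.crop_id >= 0) & (self.field_id < 0)), "crop outside fields"
        assert np.all(self.homebase_count >= 0)
        if homebase_cap is not None:
            assert np.all(self.homebase_count <= homebase_cap), "home-base cap exceeded"


def create_grid(width: int, height: int, cell_length_m: float) -> LandscapeGrid:
    """A fresh landscape completely covered by cells of the class 'others'."""
    if width < 1 or height < 1:
        raise ValueError("grid dimensions must be >= 1")
    if not cell_length_m > 0:
        raise ValueError("cell_length_m must be > 0")
    shape = (height, width)
    return LandscapeGrid(
        width=width,
        height=height,
        cell_length_m=float(cell_length_m),
        landcover=np.full(shape, OTHERS, dtype=np.int8),
        owner_id=np.full(shape, -1, dtype=np.int32),
        field_id=np.full(shape, -1, dtype=np.int32),
        crop_id=np.full(shape, -1, dtype=np.int32),
        road_flag=np.zeros(shape, dtype=bool),
        homebase_count=np.zeros(shape, dtype=np.int16),
    )


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_patches(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Connected-component labels (1..n; 0 = background) of a boolean mask."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    return labels, int(n)


@lru_cache(maxsize=8)
def _sorted_offsets(max_radius: int) -> tuple[np.ndarray, np.ndarray]:
    """(dx, dy) offsets with |offset| <= max_radius sorted by distance.

    Returns the offset array of shape (k, 2) plus the start index of each
    distance-tie group (so callers can shuffle within ties).
    """
    r = int(max_radius)
    dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    d2 = dx**2 + dy**2
    keep = d2 <= r * r
    dx, dy, d2 = dx[keep], dy[keep], d2[keep]
    order = np.lexsort((dy, dx, d2))
    offsets = np.stack([dx[order], dy[order]], axis=1)
    d2s = d2[order]
    starts = np.flatnonzero(np.r_[True, d2s[1:] != d2s[:-1]])
    return offsets, np.append(starts, len(d2s))


def iter_offsets_by_ring(max_radius: int):
    """Yield groups of (dx, dy) offsets sharing one center distance, nearest first."""
    offsets, bounds = _sorted_offsets(max_radius)
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield offsets[a:b]


def cells_within_radius(
    grid: LandscapeGrid,
    center: tuple[int, int],
    r: float,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[int, int]]:
    """In-bounds cells within Euclidean center distance ``r`` of ``center``.

    Sorted by distance; cells at equal distance are shuffled with ``rng``
    (deterministic order when ``rng`` is None).
    """
    col, row = center
    if not grid.in_bounds(col, row):
        raise ValueError(f"center {center} outside grid")
    if r < 0:
        raise ValueError("radius must be >= 0")
    rng = as_rng(rng) if rng is not None else None
    out: list[tuple[int, int]] = []
    r2 = r * r
    for ring in iter_offsets_by_ring(int(np.ceil(r)) + 1):
        if ring[0, 0] ** 2 + ring[0, 1] ** 2 > r2:
            break
        idx = np.arange(len(ring))
        if rng is not None and len(ring) > 1:
            rng.shuffle(idx)
        for i in idx:
            c, w = col + int(ring[i, 0]), row + int(ring[i, 1])
            if grid.in_bounds(c, w):
                out.append((c, w))
    return out
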