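"""Class-level landscape metrics in the FRAGSTATS raster tradition.

Five statistics characterize one land-cover class on one grid: number of
patches, mean patch area, landscape shape index (LSI), largest patch index
(LPI) and patch cohesion index (PCI).  Patches are connected components of
the class mask (8-connectivity by default, 4 available); edge and perimeter
accounting is rook (4-neighbor) and includes the landscape boundary.

Formulas, with ``a_ij`` patch areas in cells, ``p_ij`` patch perimeters in
cell edges, ``E = sum(p_ij)`` the total class edge, ``n`` the class cell
count and ``Z`` the total landscape cell count:

``LSI = E / min_E`` where ``min_E`` is the edge of a maximally compact
arrangement of ``n`` cells: with ``m = floor(sqrt(n))``, ``min_E = 4m`` if
``m^2 = n``, ``4m + 2`` if ``n <= m(m+1)``, else ``4m + 4``.

``LPI = 100 * max(a_ij) / Z``

``PCI = 100 * [1 - E / sum(p_ij * sqrt(a_ij))] / [1 - 1 / sqrt(Z)]``
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import LandscapeGrid, label_patches

__all__ = ["ClassMetrics", "patch_geometry", "compute_class_metrics"]


@dataclass(frozen=True)
class ClassMetrics:
    """The five class-level statistics for one class on one grid.

    All metric fields are None when the class mask is empty (and cohesion
    additionally on a single-cell landscape, where it is undefined).
    """

    class_cells: int
    n_patches: int
    mean_patch_area_ha: float | None
    lsi: float | None
    lpi: float | None
    cohesion: float | None


def patch_geometry(
    mask: np.ndarray, connectivity: int = 8
) -> list[tuple[int, int]]:
    """Per-patch (area in cells, perimeter in cell edges).

    The perimeter counts rook-adjacent edges to non-class cells, including
    the landscape boundary.
    """
    labels, n = label_patches(mask, connectivity)
    if n == 0:
        return []
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    # internal rook adjacencies within the same patch
    internal = np.zeros(n + 1, dtype=np.int64)
    same_h = (labels[:, 1:] == labels[:, :-1]) & (labels[:, 1:] > 0)
    same_v = (labels[1:, :] == labels[:-1, :]) & (labels[1:, :] > 0)
    np.add.at(internal, labels[:, 1:][same_h], 1)
    np.add.at(internal, labels[1:, :][same_v], 1)
    return [
        (int(a), int(4 * a - 2 * internal[i + 1]))
        for i, a in enumerate(areas)
    ]


def _min_edge(n: int) -> int:
    """Edge length of a maximally compact arrangement of n raster cells."""
    m = int(math.isqrt(n))
    if m * m == n:
        return 4 * m
    if n <= m * (m + 1):
        return 4 * m + 2
    return 4 * m + 4


def compute_class_metrics(
    mask: np.ndarray,
    grid: LandscapeGrid,
    connectivity: int = 8,
) -> ClassMetrics:
    """All five class-level metrics for one boolean class mask."""
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match the grid")
    geometry = patch_geometry(mask, connectivity)
    n_cells = int(mask.sum())
    if not geometry:
        return ClassMetrics(0, 0, None, None, None, None)
    areas = np.array([a for a, _ in geometry], dtype=float)
    perims = np.array([p for _, p in geometry], dtype=float)
    z = grid.total_cells
    total_edge = perims.sum()
    lsi = total_edge / _min_edge(n_cells)
    lpi = 100.0 * areas.max() / z
    mean_area = n_cells * grid.cell_area_ha / len(geometry)
    if z > 1:
        cohesion = (
            100.0
            * (1.0 - total_edge / float((perims * np.sqrt(areas)).sum()))
            / (1.0 - 1.0 / math.sqrt(z))
        )
    else:
        cohesion = None
    return ClassMetrics(
        class_cells=n_cells,
        n_patches=len(geometry),
        mean_patch_area_ha=mean_area,
        lsi=lsi,
        lpi=lpi,
        cohesion=cohesion,
    )
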