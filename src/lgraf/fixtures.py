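"""Synthetic road-network fixtures.

Stand-ins for real road-map vector inputs: deterministic GeoJSON line
layers within a grid extent, either a regular grid of full-span lines or
seeded random walks.
"""

from __future__ import annotations

import json
from pathlib import Path

from .grid import LandscapeGrid
from .rng import as_rng

__all__ = ["generate_road_fixture"]


def generate_road_fixture(
    grid: LandscapeGrid,
    path: str | Path,
    n_lines: int = 2,
    style: str = "grid",
    seed: int = 0,
) -> Path:
    """Write a GeoJSON line layer covering the grid extent.

    ``style='grid'`` alternates horizontal and vertical full-span lines at
    evenly spaced offsets; ``style='random-walk'`` draws jittered walks from
    one side of the landscape to the other.  Deterministic per seed.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if style not in ("grid", "random-walk"):
        raise ValueError("style must be 'grid' or 'random-walk'")
    rng = as_rng(seed)
    w = grid.width * grid.cell_length_m
    h = grid.height * grid.cell_length_m
    lines: list[list[tuple[float, float]]] = []
    c = grid.cell_length_m

    def snap(v: float) -> float:  # cell-center alignment avoids double-flagged rows
        return (min(int(v / c), grid.width - 1) + 0.5) * c

    if style == "grid":
        n_h = (n_lines + 1) // 2
        n_v = n_lines - n_h
        for i in range(n_h):
            y = snap(h * (i + 1) / (n_h + 1))
            lines.append([(0.0, y), (w * (1 - 1e-9), y)])
        for i in range(n_v):
            x = snap(w * (i + 1) / (n_v + 1))
            lines.append([(x, 0.0), (x, h * (1 - 1e-9))])
    else:
        for _ in range(n_lines):
            horizontal = rng.random() < 0.5
            n_pts = 8
            if horizontal:
                xs = [w * k / (n_pts - 1) * (1 - 1e-9) for k in range(n_pts)]
                y0 = float(rng.uniform(0.1 * h, 0.9 * h))
                ys = [min(h * (1 - 1e-9), max(0.0, y0 + float(rng.normal(0, 0.05 * h)))) for _ in xs]
                lines.append(list(zip(xs, ys)))
            else:
                ys = [h * k / (n_pts - 1) * (1 - 1e-9) for k in range(n_pts)]
                x0 = float(rng.uniform(0.1 * w, 0.9 * w))
                xs = [min(w * (1 - 1e-9), max(0.0, x0 + float(rng.normal(0, 0.05 * w)))) for _ in ys]
                lines.append(list(zip(xs, ys)))

    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"line_id": i},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[round(x, 6), round(y, 6)] for x, y in line],
                },
            }
            for i, line in enumerate(lines)
        ],
    }
    out = Path(path)
    out.write_text(json.dumps(doc, indent=1) + "\n")
    return out
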