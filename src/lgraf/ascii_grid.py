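"""ESRI ASCII grid raster export/import.

Header: ncols, nrows, xllcorner (0), yllcorner (0), cellsize, NODATA_value
(-9999); data rows written top-to-bottom, values space-separated integers.
Write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

NODATA = -9999

__all__ = ["NODATA", "write_ascii_grid", "read_ascii_grid"]


def write_ascii_grid(
    layer: np.ndarray,
    path: str | Path,
    cell_length_m: float,
    nodata: int = NODATA,
) -> None:
    """Write an integer layer (row 0 = bottom) as an ESRI ASCII grid file."""
    rows, cols = layer.shape
    lines = [
        f"ncols {cols}",
        f"nrows {rows}",
        "xllcorner 0",
        "yllcorner 0",
        f"cellsize {cell_length_m:g}",
        f"NODATA_value {nodata}",
    ]
    for row in layer[::-1]:  # top row of the file is the top of the map
        lines.append(" ".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, int]:
    """Read an ESRI ASCII grid; returns (layer row-0-bottom, cellsize, nodata)."""
    text = Path(path).read_text().strip().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "cellsize",
            "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.array([[int(v) for v in line.split()] for line in text[i:]], dtype=np.int32)
    if data.shape != (nrows, ncols):
        raise ValueError(f"expected {nrows}x{ncols} values in {path}, got {data.shape}")
    return data[::-1], header.get("cellsize", 1.0), int(header.get("nodata_value", NODATA))
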