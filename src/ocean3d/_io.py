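"""Text-format readers and writers: ESRI ASCII grids and CSV tables.

Rasters travel as ESRI ASCII grid (``.asc``) — a plain-text header
(ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value) followed by rows
of values ordered north to south.  Internally rows run south to north, so
the array is flipped on read and write.
"""

from __future__ import annotations

import numpy as np

from .grid_geometry import GridSpec
from .realms import BathymetryGrid

__all__ = ["read_ascii_grid", "write_ascii_grid"]

_NODATA = -99999.0


def write_ascii_grid(grid: BathymetryGrid, path) -> None:
    spec = grid.spec
    data = np.where(np.isfinite(grid.elevation), grid.elevation, _NODATA)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.lon0!r}\n")
        fh.write(f"yllcorner {spec.lat0!r}\n")
        fh.write(f"cellsize {spec.resolution_deg!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        for row in data[::-1]:  # .asc stores the northernmost row first
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> BathymetryGrid:
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header field {key!r}")
    nodata = header.get("nodata_value", _NODATA)
    values = np.array(" ".join(lines[i:]).split(), dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.size != n_rows * n_cols:
        raise ValueError("ASCII grid body does not match ncols × nrows")
    data = values.reshape(n_rows, n_cols)[::-1]
    data = np.where(data == nodata, np.nan, data)
    spec = GridSpec(
        resolution_deg=header["cellsize"],
        lat0=header["yllcorner"],
        lon0=header["xllcorner"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return BathymetryGrid(spec, data)
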