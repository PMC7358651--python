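"""Minimal geographic raster container and ESRI ASCII grid I/O.

Grids are plain-text ESRI ASCII rasters (``ncols``/``nrows``/``xllcorner``/
``yllcorner``/``cellsize``/``NODATA_value`` header followed by rows of cell
values, northernmost row first) on a WGS84 geographic grid.  This is the one
raster format the pipeline reads and writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """A single-band geographic raster.

    ``data`` is a (nrows, ncols) float array with the *northernmost* row
    first, matching the ESRI ASCII layout.  ``xll``/``yll`` are the
    coordinates of the lower-left corner of the lower-left cell, in decimal
    degrees; ``cellsize`` is the square cell side in degrees.
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max)."""
        return (
            self.xll,
            self.xll + self.ncols * self.cellsize,
            self.yll,
            self.yll + self.nrows * self.cellsize,
        )

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def contains(self, lat: float, lon: float) -> bool:
        lon_min, lon_max, lat_min, lat_max = self.extent
        return lon_min <= lon < lon_max and lat_min <= lat < lat_max

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; floor convention.

        A point exactly on a cell boundary belongs to the cell to its
        north-east in grid coordinates (i.e. ``floor`` of the fractional
        offset from the lower-left corner).
        """
        if not self.contains(lat, lon):
            raise ValueError(f"point ({lat}, {lon}) outside raster extent {self.extent}")
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yll) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        return row, col

    def sample_nearest(self, lat: float, lon: float) -> float:
        """Value of the cell containing the point; NaN for nodata."""
        row, col = self.cell_index(lat, lon)
        value = self.data[row, col]
        if np.isclose(value, self.nodata):
            return float("nan")
        return float(value)

    def cell_latitudes(self) -> np.ndarray:
        """Latitude of each row's cell centers (north to south)."""
        top = self.yll + self.nrows * self.cellsize
        return top - (np.arange(self.nrows) + 0.5) * self.cellsize


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {key!r}")
    body = "\n".join(lines[i:])
    data = np.array(body.split(), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.size != nrows * ncols:
        raise ValueError(f"{path}: expected {nrows * ncols} values, got {data.size}")
    return Raster(
        data=data.reshape(nrows, ncols),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.6g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.10g}\n")
        fh.write(f"yllcorner {raster.yll:.10g}\n")
        fh.write(f"cellsize {raster.cellsize:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:.10g}\n")
        for row in raster.data:
            fh.write(" ".join(fmt % v for v in row) + "\n")
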