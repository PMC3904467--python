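"""Lightweight georeferenced raster container with ESRI ASCII grid I/O.

A :class:`Grid` is a north-up, square-pixel raster on a projected
coordinate system (metres by default). Values are held as a 2-D float
array with NaN marking nodata; categorical grids use integer codes
stored as floats and are converted on access. The on-disk format is the
ESRI ASCII grid (``.asc``), a plain-text interchange format understood
by every desktop GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Grid", "read_ascii_grid", "write_ascii_grid", "read_legend", "write_legend"]


@dataclass
class Grid:
    """A single-band raster.

    Parameters
    ----------
    values
        2-D array; NaN is nodata.
    pixel_size
        Cell edge length in the units of the coordinate system.
    xll, yll
        Coordinates of the lower-left corner of the lower-left cell.
    crs_units
        ``"m"`` for projected/metric grids (required for area work),
        ``"deg"`` for geographic grids.
    """

    values: np.ndarray
    pixel_size: float = 30.0
    xll: float = 0.0
    yll: float = 0.0
    crs_units: str = "m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.crs_units not in ("m", "deg"):
            raise ValueError("crs_units must be 'm' or 'deg'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return ~np.isnan(self.values)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.pixel_size == other.pixel_size
            and self.xll == other.xll
            and self.yll == other.yll
            and self.crs_units == other.crs_units
        )

    def require_same_geometry(self, other: "Grid", what: str = "rasters") -> None:
        if not self.same_geometry(other):
            raise ValueError(f"{what} are not co-registered (shape/origin/pixel size differ)")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped like values.

        Row 0 is the northernmost row, per the ASCII-grid convention.
        """
        nrows, ncols = self.shape
        xs = self.xll + (np.arange(ncols) + 0.5) * self.pixel_size
        ys = self.yll + (nrows - np.arange(nrows) - 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def with_values(self, values: np.ndarray) -> "Grid":
        return replace(self, values=np.asarray(values, dtype=float))

    def as_int(self, nodata: int = -1) -> np.ndarray:
        """Integer view of a categorical grid; nodata cells become `nodata`."""
        out = np.where(self.mask, self.values, nodata)
        return out.astype(int)


_NODATA = -9999.0


def write_ascii_grid(grid: Grid, path) -> None:
    """Write an ESRI ASCII grid (.asc). NaN cells become the nodata value."""
    nrows, ncols = grid.shape
    body = np.where(grid.mask, grid.values, _NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.pixel_size!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        fh.write(f"# crs_units {grid.crs_units}\n")
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` or a GIS."""
    header: dict[str, float] = {}
    crs_units = "m"
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line:
            stripped = line.strip()
            if stripped.startswith("#"):
                parts = stripped.lstrip("#").split()
                if len(parts) == 2 and parts[0] == "crs_units":
                    crs_units = parts[1]
                pos = fh.tell()
                line = fh.readline()
                continue
            key = stripped.split()[0].lower() if stripped else ""
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"):
                header[key] = float(stripped.split()[1])
                pos = fh.tell()
                line = fh.readline()
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", _NODATA)
    values = np.where(values == nodata, np.nan, values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid body shape {values.shape} disagrees with header in {path}")
    return Grid(
        values=values,
        pixel_size=header["cellsize"],
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        crs_units=crs_units,
    )


def write_legend(legend: dict[int, str], path) -> None:
    """Write a category legend as two-column CSV (code, label)."""
    with open(path, "w") as fh:
        fh.write("code,label\n")
        for code in sorted(legend):
            fh.write(f"{code},{legend[code]}\n")


def read_legend(path) -> dict[int, str]:
    legend: dict[int, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("code"):
            raise ValueError(f"legend file {path} lacks a 'code,label' header")
        for line in fh:
            if not line.strip():
                continue
            code, label = line.rstrip("\n").split(",", 1)
            legend[int(code)] = label
    return legend
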