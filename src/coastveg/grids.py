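"""Raster containers and plain-text raster I/O.

All stages of the pipeline exchange :class:`RasterGrid` objects: a float64
array plus a boolean NoData mask and a :class:`GridGeometry` describing the
projected placement of the cells.  Grids are serialised as ESRI ASCII grid
files (``.asc``) with a ``.prj`` sidecar carrying the CRS identifier, so
every artifact on disk is human-readable text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0

__all__ = [
    "NODATA",
    "GridGeometry",
    "RasterGrid",
    "Scene",
    "read_ascii_grid",
]


@dataclass(frozen=True)
class GridGeometry:
    """Placement of a north-up raster in a projected CRS.

    ``x_origin``/``y_origin`` are the coordinates of the *top-left corner*
    of the top-left cell, in metres.  Rows run north to south.
    """

    rows: int
    cols: int
    cell_size: float
    x_origin: float = 0.0
    y_origin: float = 0.0
    crs: str = "EPSG:32650"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError(f"cell size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, each shaped (rows, cols)."""
        xs = self.x_origin + (np.arange(self.cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(self.rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.cell_size).astype(int)
        return row, col


@dataclass
class RasterGrid:
    """A single-band raster: float64 values, NoData mask, geometry."""

    values: np.ndarray
    geometry: GridGeometry
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match geometry {self.geometry.shape}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")
            self.mask = self.mask | ~np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def finite_values(self) -> np.ndarray:
        """1-D array of the valid (non-NoData) cell values."""
        return self.values[~self.mask]

    def like(self, values: np.ndarray, extra_mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid on the same geometry; NoData is inherited and may grow."""
        mask = self.mask if extra_mask is None else (self.mask | extra_mask)
        return RasterGrid(np.asarray(values, dtype=float), self.geometry, mask.copy())

    def filled(self, fill: float = NODATA) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = fill
        return out

    def assert_coregistered(self, other: "RasterGrid") -> None:
        if self.geometry != other.geometry:
            raise ValueError("grids are not co-registered (geometry differs)")

    # ------------------------------------------------------------------ I/O

    def to_ascii(self, path: str | Path, fmt: str = "%.10g") -> Path:
        """Write as ESRI ASCII grid plus a ``.prj`` sidecar with the CRS."""
        path = Path(path)
        g = self.geometry
        header = (
            f"ncols {g.cols}\n"
            f"nrows {g.rows}\n"
            f"xllcorner {g.x_origin!r}\n"
            f"yllcorner {g.y_origin - g.rows * g.cell_size!r}\n"
            f"cellsize {g.cell_size!r}\n"
            f"NODATA_value {NODATA:g}\n"
        )
        body = self.filled()
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt=fmt)
        path.with_suffix(".prj").write_text(g.crs + "\n")
        return path


def read_ascii_grid(path: str | Path, crs: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid written by :meth:`RasterGrid.to_ascii`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
            pos = fh.tell()
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    if crs is None:
        prj = path.with_suffix(".prj")
        crs = prj.read_text().strip() if prj.exists() else "unknown"
    geom = GridGeometry(
        rows=rows,
        cols=cols,
        cell_size=cell,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + rows * cell,
        crs=crs,
    )
    nodata = header.get("nodata_value", NODATA)
    mask = values == nodata
    values = values.astype(float)
    values[mask] = np.nan
    return RasterGrid(values, geom, mask)


@dataclass
class Scene:
    """Co-registered multiband scene: red/NIR reflectance plus a thermal band.

    Reflectances are unitless surface reflectance in [0, 1]; the thermal
    band is either raw digital numbers (``thermal_kind="dn"``) or spectral
    radiance in W·m⁻²·sr⁻¹·µm⁻¹ (``thermal_kind="radiance"``), as flagged.
    """

    red: RasterGrid
    nir: RasterGrid
    thermal: RasterGrid | None = None
    thermal_kind: str = "dn"
    season: str = "summer"
    date: str = ""
    sensor_id: str = "oli_tirs"

    def __post_init__(self) -> None:
        if self.thermal_kind not in ("dn", "radiance"):
            raise ValueError(f"thermal_kind must be 'dn' or 'radiance', got {self.thermal_kind!r}")
        if self.season not in ("summer", "winter"):
            raise ValueError(f"season must be 'summer' or 'winter', got {self.season!r}")
        self.red.assert_coregistered(self.nir)
        if self.thermal is not None:
            self.red.assert_coregistered(self.thermal)
        for name, band in (("red", self.red), ("nir", self.nir)):
            vals = band.finite_values()
            if vals.size and (vals.min() < -0.01 or vals.max() > 1.01):
                raise ValueError(f"{name} reflectance outside [-0.01, 1.01]")

    @property
    def geometry(self) -> GridGeometry:
        return self.red.geometry
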