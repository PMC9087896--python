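"""Coastline-distance zoning, fishnet aggregation and LST~FVC regression.

The study area is stratified by Euclidean distance to the coastline into
an offshore (≤10 km), middle (10–25 km) and inland (>25 km) zone.  FVC
and LST are averaged on a square fishnet grid (cells snapped to the
raster origin), each retained cell is assigned a zone from its centre
distance, and an ordinary-least-squares line of mean LST on mean FVC is
fitted per zone.  A more negative slope means a stronger vegetation
cooling effect in that zone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import LineString, mapping, shape

from .grids import RasterGrid

#: Coastline-distance zone edges in kilometres: offshore ≤ 10 < middle ≤ 25 < inland.
ZONE_EDGES_KM = (10.0, 25.0)
ZONE_NAMES = ("offshore", "middle", "inland")

#: Minimum fraction of valid pixels for a fishnet cell to be retained.
MIN_VALID_FRACTION = 0.5


@dataclass(frozen=True)
class CoastlineGeometry:
    """A coastline polyline in a projected CRS (metres)."""

    line: LineString
    crs: str = "EPSG:32650"

    def __post_init__(self) -> None:
        coords = np.asarray(self.line.coords)
        if len(coords) < 2:
            raise ValueError("coastline needs at least two vertices")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coastline coordinates must be finite")

    def to_geojson(self, path: str | Path) -> Path:
        path = Path(path)
        feature = {
            "type": "Feature",
            "properties": {"crs": self.crs},
            "geometry": mapping(self.line),
        }
        path.write_text(json.dumps({"type": "FeatureCollection", "features": [feature]}))
        return path

    @classmethod
    def from_geojson(cls, path: str | Path) -> "CoastlineGeometry":
        doc = json.loads(Path(path).read_text())
        feature = doc["features"][0] if doc.get("type") == "FeatureCollection" else doc
        geom = shape(feature["geometry"])
        crs = feature.get("properties", {}).get("crs", "unknown")
        return cls(LineString(geom.coords), crs=crs)


def distance_to_coast(
    x: np.ndarray, y: np.ndarray, coast: CoastlineGeometry, crs: str | None = None
) -> np.ndarray:
    """Euclidean distance (km) from points to the nearest coastline point.

    ``crs``, when given, is checked against the coastline's CRS.
    """
    if crs is not None and crs != coast.crs:
        raise ValueError(f"CRS mismatch: points {crs!r} vs coastline {coast.crs!r}")
    pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return shapely.distance(pts, coast.line) / 1000.0


def assign_zone(
    distance_km: np.ndarray | float, edges_km: tuple[float, float] = ZONE_EDGES_KM
) -> np.ndarray | str:
    """Zone label from coastline distance; offshore ≤ 10 < middle ≤ 25 < inland."""
    d = np.asarray(distance_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    lo, hi = edges_km
    if not 0 < lo < hi:
        raise ValueError("zone edges must be positive and strictly increasing")
    zones = np.where(d <= lo, "offshore", np.where(d <= hi, "middle", "inland"))
    return zones if zones.ndim else str(zones)


def build_fishnet(
    fvc: RasterGrid,
    lst: RasterGrid,
    coast: CoastlineGeometry,
    cell_length: float = 100.0,
    min_valid_fraction: float = MIN_VALID_FRACTION,
    edges_km: tuple[float, float] = ZONE_EDGES_KM,
) -> pd.DataFrame:
    """Aggregate FVC and LST on a square fishnet and assign coastal zones.

    The fishnet is snapped to the raster origin; ``cell_length`` must be a
    positive integer multiple of the raster cell size.  Per cell, means
    are taken over non-NoData pixels of both grids jointly; cells whose
    valid-pixel fraction falls below ``min_valid_fraction`` are dropped.
    A trailing partial row/column of pixels is ignored.
    """
    fvc.assert_coregistered(lst)
    geom = fvc.geometry
    if geom.crs != coast.crs:
        raise ValueError(f"CRS mismatch: raster {geom.crs!r} vs coastline {coast.crs!r}")
    ratio = cell_length / geom.cell_size
    block = int(round(ratio))
    if block < 1 or abs(ratio - block) > 1e-9:
        raise ValueError(
            f"fishnet length {cell_length} m is not a positive integer multiple "
            f"of the raster cell size {geom.cell_size} m"
        )
    nrow, ncol = geom.rows // block, geom.cols // block
    if nrow == 0 or ncol == 0:
        raise ValueError("fishnet cell larger than the raster extent")

    def blocks(grid: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
        vals = np.where(grid.mask, 0.0, grid.values)[: nrow * block, : ncol * block]
        ok = (~grid.mask)[: nrow * block, : ncol * block]
        vals = vals.reshape(nrow, block, ncol, block)
        ok = ok.reshape(nrow, block, ncol, block)
        return vals.sum(axis=(1, 3)), ok.sum(axis=(1, 3))

    fvc_sum, fvc_n = blocks(fvc)
    lst_sum, lst_n = blocks(lst)
    valid = np.minimum(fvc_n, lst_n)  # joint validity per cell (pixel masks coincide
    # in this pipeline; the min keeps the count conservative when they do not)
    retained = valid >= min_valid_fraction * block * block
    if not retained.any():
        raise ValueError("no fishnet cell meets the minimum valid-pixel fraction")

    rows_idx, cols_idx = np.nonzero(retained)
    cx = geom.x_origin + (cols_idx + 0.5) * cell_length
    cy = geom.y_origin - (rows_idx + 0.5) * cell_length
    dist_km = distance_to_coast(cx, cy, coast, crs=geom.crs)
    with np.errstate(invalid="ignore"):
        mean_fvc = fvc_sum[retained] / fvc_n[retained]
        mean_lst = lst_sum[retained] / lst_n[retained]
    return pd.DataFrame(
        {
            "cell_id": rows_idx * ncol + cols_idx,
            "x": cx,
            "y": cy,
            "mean_fvc": mean_fvc,
            "mean_lst_k": mean_lst,
            "n_valid": valid[retained],
            "dist_km": dist_km,
            "zone": assign_zone(dist_km, edges_km),
        }
    )


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of mean LST (K) on mean FVC within one coastal zone."""

    zone: str
    slope: float  # kelvin per unit FVC
    intercept: float  # kelvin
    r2: float
    n: int
    slope_stderr: float = float("nan")
    date: str = ""

    def to_dict(self) -> dict:
        return {
            "zone": self.zone,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "n": self.n,
            "slope_stderr": self.slope_stderr,
            "date": self.date,
        }


def fit_zone_regression(table: pd.DataFrame, zone: str, date: str = "") -> RegressionFit:
    """OLS of mean LST on mean FVC over the fishnet cells of one zone."""
    if zone not in ZONE_NAMES:
        raise ValueError(f"unknown zone {zone!r}; expected one of {ZONE_NAMES}")
    sub = table[table["zone"] == zone]
    if len(sub) < 3:
        raise ValueError(f"zone {zone!r} has {len(sub)} cells; need at least 3")
    x = sub["mean_fvc"].to_numpy()
    y = sub["mean_lst_k"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError(f"zone {zone!r} has constant FVC; regression is degenerate")
    res = stats.linregress(x, y)
    return RegressionFit(
        zone=zone,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(sub),
        slope_stderr=float(res.stderr),
        date=date,
    )


def fit_all_zones(table: pd.DataFrame, date: str = "") -> pd.DataFrame:
    """Per-zone fits as a tidy frame; zones with too few cells are skipped."""
    rows = []
    for zone in ZONE_NAMES:
        try:
            rows.append(fit_zone_regression(table, zone, date=date).to_dict())
        except ValueError:
            continue
    if not rows:
        raise ValueError("no zone had enough fishnet cells to fit")
    return pd.DataFrame(rows)
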