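"""Synthetic coastal Landsat-like scenes with known ground truth.

The generator lays out a coastal landscape — sea on the west of a
piecewise-linear coastline, mountain forest nearest the coast, then an
urban belt, agriculture and bare land further inland — draws a true FVC
field per cover class, and constructs a true LST field as a
coastline-zone-dependent linear response to FVC plus pixel noise.

The bands are then manufactured as the *exact inverse* of the analysis
chain rather than by a physical simulator: NDVI is chosen so that the
dimidiate-pixel inversion with the configured endpoints returns the true
FVC, reflectances encode that NDVI at a fixed band sum, and the thermal
DN comes from true LST → Planck radiance → forward radiative transfer →
inverse calibration.  Because DN is quantized, the stored true LST is the
temperature implied by the quantized DN, which makes the round-trip
recovery tests sharp (exact to floating-point error) instead of
tolerance-bound.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .coastal_zoning import CoastlineGeometry, assign_zone, distance_to_coast
from .grids import NODATA, GridGeometry, RasterGrid, Scene, read_ascii_grid
from .sensors import (
    DEFAULT_ATMOSPHERE,
    AtmosphericParameters,
    SensorProfile,
    get_sensor_profile,
)
from .thermal import (
    EPS_FVC_THRESHOLD,
    EPS_SOIL,
    EPS_VEGETATION,
    calibrate_dn,
    planck_radiance,
    radiance_from_dn_inverse,
    radiance_to_temperature,
    solve_surface_radiance,
)
from .vegetation import FIXED_ENDPOINTS

#: Per-class true-FVC mean and spread (clipped normal) by season.  Winter
#: values reflect leaf-off deciduous forest and fallow cropland.
FVC_CLASS_PARAMS = {
    "summer": {
        "forest": (0.88, 0.08),
        "urban": (0.18, 0.08),
        "agriculture": (0.68, 0.12),
        "bare": (0.06, 0.04),
    },
    "winter": {
        "forest": (0.88, 0.08),  # evergreen part; deciduous handled below
        "urban": (0.15, 0.07),
        "agriculture": (0.25, 0.10),
        "bare": (0.05, 0.03),
    },
}
#: Mean FVC of leaf-off deciduous canopy in winter.
DECIDUOUS_WINTER_MEAN = 0.30

#: Per-zone LST construction: intercept (K) and slope (K per unit FVC) for
#: (offshore, middle, inland).  Summer shows the vegetation cooling effect
#: steepening inland; winter responses are near zero.
LST_ZONE_PARAMS = {
    "summer": {"intercepts": (304.0, 305.5, 307.5), "slopes": (-3.0, -4.5, -6.0)},
    "winter": {"intercepts": (276.0, 276.5, 277.5), "slopes": (0.3, -0.2, 0.8)},
}

_LAND_CLASSES = ("forest", "urban", "agriculture", "bare")


@dataclass(frozen=True)
class LandscapeSpec:
    """Layout and stochastic parameters of one synthetic scene.

    Cover fractions are over the *land* part of the scene and must sum to
    1; ``water_fraction`` sets where the coastline falls.  ``lst_slopes``/
    ``lst_intercepts`` override the seasonal defaults per coastal zone
    (offshore, middle, inland).
    """

    rows: int = 160
    cols: int = 220
    cell_size: float = 200.0
    coastline_points: tuple[tuple[float, float], ...] | None = None
    forest_fraction: float = 0.25
    urban_fraction: float = 0.22
    agriculture_fraction: float = 0.38
    bare_fraction: float = 0.15
    water_fraction: float = 0.15
    season: str = "summer"
    seed: int = 0
    date: str = ""
    deciduous_fraction: float = 0.6
    lst_slopes: tuple[float, float, float] | None = None
    lst_intercepts: tuple[float, float, float] | None = None
    lst_noise_sd: float = 0.5
    class_mix_sd_km: float = 6.0
    reflectance_sum: float = 0.5
    crs: str = "EPSG:32650"
    #: optional per-class (mean, sd) FVC override, e.g. {"bare": (0.0, 0.0)};
    #: classes not listed keep the seasonal defaults
    fvc_class_params: tuple[tuple[str, tuple[float, float]], ...] | None = None

    def __post_init__(self) -> None:
        if self.rows < 16 or self.cols < 16:
            raise ValueError("grid must be at least 16×16")
        if not self.cell_size > 0:
            raise ValueError("cell size must be positive")
        if self.season not in ("summer", "winter"):
            raise ValueError(f"season must be 'summer' or 'winter', got {self.season!r}")
        fracs = self.land_fractions
        if any(f < 0 for f in fracs):
            raise ValueError("cover fractions must be nonnegative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"land cover fractions must sum to 1, got {sum(fracs)}")
        if not (0 <= self.water_fraction < 1):
            raise ValueError("water fraction must be in [0, 1)")
        if not (0 <= self.deciduous_fraction <= 1):
            raise ValueError("deciduous fraction must be in [0, 1]")
        if self.lst_noise_sd < 0:
            raise ValueError("LST noise sd must be nonnegative")

    @property
    def land_fractions(self) -> tuple[float, float, float, float]:
        return (
            self.forest_fraction,
            self.urban_fraction,
            self.agriculture_fraction,
            self.bare_fraction,
        )

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            rows=self.rows,
            cols=self.cols,
            cell_size=self.cell_size,
            x_origin=0.0,
            y_origin=self.rows * self.cell_size,
            crs=self.crs,
        )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic scene."""

    fvc: RasterGrid
    lst: RasterGrid  # kelvin; consistent with the quantized thermal band
    emissivity: RasterGrid
    atmosphere: AtmosphericParameters
    sensor: SensorProfile
    coastline: CoastlineGeometry
    land_cover: RasterGrid  # codes: index into _LAND_CLASSES + 1, NoData = water
    dist_km: RasterGrid
    scene_id: str = ""


@dataclass(frozen=True)
class StationRecord:
    """One station observation at satellite overpass time."""

    station_id: str
    x: float
    y: float
    temperature_k: float
    scene_id: str = ""

    def __post_init__(self) -> None:
        if not (220.0 <= self.temperature_k <= 340.0):
            raise ValueError(
                f"station temperature {self.temperature_k} K outside [220, 340] K"
            )


def default_coastline(spec: LandscapeSpec) -> CoastlineGeometry:
    """A gently wiggling north–south coastline with sea to the west.

    The base easting is ``water_fraction`` of the scene width; fixed
    relative offsets bend the line so the water mask is not a straight
    column strip.
    """
    geom = spec.geometry
    width = geom.cols * geom.cell_size
    height = geom.rows * geom.cell_size
    base = geom.x_origin + spec.water_fraction * width
    wiggle = (0.0, 0.04, -0.03, 0.05, 0.0)
    ys = np.linspace(geom.y_origin, geom.y_origin - height, len(wiggle))
    pts = [(base + w * width, y) for w, y in zip(wiggle, ys)]
    return CoastlineGeometry(LineString(pts), crs=spec.crs)


def _water_mask(coast: CoastlineGeometry, geom: GridGeometry) -> np.ndarray:
    """True where the cell centre lies seaward (west) of the coastline."""
    pad = max(geom.cols, geom.rows) * geom.cell_size
    coords = list(coast.line.coords)
    first_y, last_y = coords[0][1], coords[-1][1]
    west = geom.x_origin - pad
    poly = Polygon(
        [(west, first_y + pad), *coords, (west, last_y - pad)]
    )
    xs, ys = geom.cell_centers()
    return shapely.contains_xy(poly, xs, ys)


def generate_scene(
    spec: LandscapeSpec,
    sensor: SensorProfile | str = "oli_tirs",
    atmosphere: AtmosphericParameters | None = None,
) -> tuple[Scene, SyntheticTruth]:
    """Generate a synthetic scene and its ground truth.

    Identical ``spec`` (including its seed) gives bit-identical output.
    """
    if isinstance(sensor, str):
        sensor = get_sensor_profile(sensor)
    if atmosphere is None:
        atmosphere = DEFAULT_ATMOSPHERE[spec.season]
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    coast = (
        CoastlineGeometry(LineString(spec.coastline_points), crs=spec.crs)
        if spec.coastline_points is not None
        else default_coastline(spec)
    )

    water = _water_mask(coast, geom)
    land = ~water
    n_land = int(land.sum())
    if n_land == 0:
        raise ValueError("landscape has no land cells; lower the water fraction")

    xs, ys = geom.cell_centers()
    dist = np.asarray(
        distance_to_coast(xs.ravel(), ys.ravel(), coast, crs=geom.crs)
    ).reshape(geom.shape)

    # --- land-cover allocation: coast-distance gradient plus seeded mixing noise
    score = dist + rng.normal(0.0, spec.class_mix_sd_km, size=geom.shape)
    land_scores = score[land]
    order = np.argsort(land_scores, kind="stable")
    cover_codes = np.zeros(n_land, dtype=int)
    cum = np.cumsum(spec.land_fractions)
    bounds = np.rint(cum * n_land).astype(int)
    start = 0
    for code, stop in enumerate(bounds, start=1):
        cover_codes[order[start:stop]] = code
        start = stop
    cover_codes[cover_codes == 0] = len(_LAND_CLASSES)  # rounding remainder → bare
    cover = np.full(geom.shape, np.nan)
    cover[land] = cover_codes

    # --- true FVC per cover class (clipped normal), leaf-off handling in winter
    params = dict(FVC_CLASS_PARAMS[spec.season])
    if spec.fvc_class_params is not None:
        params.update(dict(spec.fvc_class_params))
    fvc_raw = np.full(geom.shape, np.nan)
    gauss = rng.standard_normal(geom.shape)
    for code, cls in enumerate(_LAND_CLASSES, start=1):
        mean, sd = params[cls]
        if cls == "forest" and spec.season == "winter":
            mean = (
                (1 - spec.deciduous_fraction) * mean
                + spec.deciduous_fraction * DECIDUOUS_WINTER_MEAN
            )
        sel = cover == code
        fvc_raw[sel] = mean + sd * gauss[sel]
    fvc_raw = np.clip(fvc_raw, 0.0, 1.0)

    # --- true LST: zone-dependent linear response to FVC plus pixel noise
    zones = np.zeros(geom.shape, dtype=int)
    zone_names = assign_zone(dist)
    zones[zone_names == "middle"] = 1
    zones[zone_names == "inland"] = 2
    season_lst = LST_ZONE_PARAMS[spec.season]
    slopes = spec.lst_slopes or season_lst["slopes"]
    intercepts = spec.lst_intercepts or season_lst["intercepts"]
    slope_grid = np.choose(zones, slopes)
    intercept_grid = np.choose(zones, intercepts)
    lst_cont = intercept_grid + slope_grid * fvc_raw
    lst_cont = lst_cont + rng.normal(0.0, spec.lst_noise_sd, size=geom.shape)

    # --- encode bands: NDVI → reflectance pair, LST → DN via the forward chain
    soil, veg = FIXED_ENDPOINTS
    ndvi = soil + (veg - soil) * fvc_raw
    s = spec.reflectance_sum
    nir = s * (1.0 + ndvi) / 2.0
    red = s * (1.0 - ndvi) / 2.0

    eps = np.where(fvc_raw >= EPS_FVC_THRESHOLD, EPS_VEGETATION, EPS_SOIL)
    b_true = planck_radiance(lst_cont, sensor)
    l_sen = (eps * b_true + (1.0 - eps) * atmosphere.l_down) * atmosphere.tau + atmosphere.l_up
    dn = radiance_from_dn_inverse(l_sen, sensor)

    red_grid = RasterGrid(np.where(water, np.nan, red), geom, water.copy())
    nir_grid = RasterGrid(np.where(water, np.nan, nir), geom, water.copy())
    dn_grid = RasterGrid(np.where(water, np.nan, dn), geom, water.copy())
    scene_id = f"synthetic-{spec.season}-{spec.seed}"
    scene = Scene(
        red=red_grid,
        nir=nir_grid,
        thermal=dn_grid,
        thermal_kind="dn",
        season=spec.season,
        date=spec.date,
        sensor_id=sensor.sensor_id,
    )

    # Truth FVC from the target NDVI (pre-encoding), truth LST from the
    # quantized DN through the analysis chain: manufactured consistency.
    truth_fvc = (ndvi - soil) / (veg - soil)
    eps_grid = RasterGrid(np.where(water, np.nan, eps), geom, water.copy())
    truth_lst = radiance_to_temperature(
        solve_surface_radiance(calibrate_dn(dn_grid, sensor), eps_grid, atmosphere),
        sensor,
    )
    truth = SyntheticTruth(
        fvc=RasterGrid(np.where(water, np.nan, truth_fvc), geom, water.copy()),
        lst=truth_lst,
        emissivity=eps_grid,
        atmosphere=atmosphere,
        sensor=sensor,
        coastline=coast,
        land_cover=RasterGrid(cover, geom, water.copy()),
        dist_km=RasterGrid(dist, geom),
        scene_id=scene_id,
    )
    return scene, truth


def generate_stations(
    truth: SyntheticTruth, n: int = 15, noise_sd: float = 2.0, seed: int = 0
) -> list[StationRecord]:
    """Point-sample the true LST at ``n`` distinct random land cells.

    Each observation is the cell's true LST plus N(0, noise_sd²) noise;
    station coordinates are the cell centres (point sampling — no
    footprint averaging).
    """
    if n < 1:
        raise ValueError("need at least one station")
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    land_rows, land_cols = np.nonzero(~truth.lst.mask)
    if land_rows.size == 0:
        raise ValueError("truth grid has no land cells to place stations on")
    if n > land_rows.size:
        raise ValueError(f"cannot place {n} distinct stations on {land_rows.size} land cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(land_rows.size, size=n, replace=False)
    noise = rng.normal(0.0, noise_sd, size=n)
    geom = truth.lst.geometry
    records = []
    for i, (k, dt) in enumerate(zip(pick, noise)):
        r, c = int(land_rows[k]), int(land_cols[k])
        x = geom.x_origin + (c + 0.5) * geom.cell_size
        y = geom.y_origin - (r + 0.5) * geom.cell_size
        records.append(
            StationRecord(
                station_id=f"S{i + 1:03d}",
                x=x,
                y=y,
                temperature_k=float(truth.lst.values[r, c] + dt),
                scene_id=truth.scene_id,
            )
        )
    return records


# ------------------------------------------------------------------ disk I/O

def write_stations_csv(stations: Sequence[StationRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["station_id", "x", "y", "temperature_k", "scene_id"])
        for st in stations:
            writer.writerow([st.station_id, repr(st.x), repr(st.y), repr(st.temperature_k), st.scene_id])
    return path


def read_stations_csv(path: str | Path) -> list[StationRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                StationRecord(
                    station_id=row["station_id"],
                    x=float(row["x"]),
                    y=float(row["y"]),
                    temperature_k=float(row["temperature_k"]),
                    scene_id=row.get("scene_id", ""),
                )
            )
    return records


def write_scene_dir(
    scene: Scene,
    truth: SyntheticTruth,
    outdir: str | Path,
    stations: Sequence[StationRecord] | None = None,
) -> Path:
    """Write a scene directory: bands and truth as ASCII grids, coastline
    as GeoJSON, stations as CSV, and a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene.red.to_ascii(outdir / "red.asc", fmt="%.17g")
    scene.nir.to_ascii(outdir / "nir.asc", fmt="%.17g")
    scene.thermal.to_ascii(outdir / "thermal.asc", fmt="%.17g")
    truth.fvc.to_ascii(outdir / "truth_fvc.asc", fmt="%.17g")
    truth.lst.to_ascii(outdir / "truth_lst.asc", fmt="%.17g")
    truth.emissivity.to_ascii(outdir / "truth_emissivity.asc", fmt="%.17g")
    truth.coastline.to_geojson(outdir / "coastline.geojson")
    if stations is not None:
        write_stations_csv(stations, outdir / "stations.csv")
    meta = {
        "scene_id": truth.scene_id,
        "season": scene.season,
        "date": scene.date,
        "sensor_id": scene.sensor_id,
        "thermal_kind": scene.thermal_kind,
        "crs": scene.geometry.crs,
        "atmosphere": {
            "tau": truth.atmosphere.tau,
            "l_up": truth.atmosphere.l_up,
            "l_down": truth.atmosphere.l_down,
        },
        "nodata": NODATA,
    }
    (outdir / "scene.json").write_text(json.dumps(meta, indent=2))
    return outdir


def read_scene_dir(path: str | Path) -> tuple[Scene, AtmosphericParameters]:
    """Read back a scene directory written by :func:`write_scene_dir`."""
    path = Path(path)
    meta = json.loads((path / "scene.json").read_text())
    crs = meta.get("crs")
    scene = Scene(
        red=read_ascii_grid(path / "red.asc", crs=crs),
        nir=read_ascii_grid(path / "nir.asc", crs=crs),
        thermal=read_ascii_grid(path / "thermal.asc", crs=crs),
        thermal_kind=meta["thermal_kind"],
        season=meta["season"],
        date=meta["date"],
        sensor_id=meta["sensor_id"],
    )
    atm = AtmosphericParameters(**meta["atmosphere"])
    return scene, atm


def with_season(spec: LandscapeSpec, season: str, date: str = "") -> LandscapeSpec:
    """The same landscape re-tagged to another season (same seed)."""
    return replace(spec, season=season, date=date or spec.date)
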