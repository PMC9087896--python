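"""Configured end-to-end pipeline and report generation.

A :class:`PipelineConfig` (usually loaded from YAML) names the input
scenes — either directories on disk or synthetic-landscape parameters —
and the analysis settings: dimidiate endpoints, sensor profile,
atmosphere, emissivity scheme, fishnet length and coastal-zone edges.
:func:`run_pipeline` executes synthesis → vegetation → thermal →
heat-island → coastal zoning for every scene, writes all artifacts under
the output directory, and returns a :class:`RunReport` whose content is
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .coastal_zoning import (
    MIN_VALID_FRACTION,
    ZONE_EDGES_KM,
    CoastlineGeometry,
    build_fishnet,
    fit_all_zones,
)
from .grids import RasterGrid, Scene
from .heat_island import (
    classify_lst_zones,
    compute_uri,
    uri_from_zone_table,
    uri_trend_table,
)
from .scene_synth import (
    LandscapeSpec,
    generate_scene,
    generate_stations,
    read_scene_dir,
    read_stations_csv,
    write_scene_dir,
    write_stations_csv,
)
from .sensors import DEFAULT_ATMOSPHERE, AtmosphericParameters, get_sensor_profile
from .thermal import constant_emissivity, emissivity_from_fvc, retrieve_lst, validate_lst
from .vegetation import (
    FIXED_ENDPOINTS,
    DimidiateEndpoints,
    class_area_table,
    classify_fvc,
    compute_fvc,
    compute_ndvi,
    select_endpoints,
)


@dataclass
class SceneConfig:
    """One scene: either a directory on disk or synthesis parameters."""

    scene_dir: str | None = None
    synth: dict[str, Any] | None = None
    date: str = ""
    season: str = "summer"
    atmosphere: dict[str, float] | None = None
    stations: int = 0  # synthetic stations to generate (0 = none)
    station_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if (self.scene_dir is None) == (self.synth is None):
            raise ValueError("each scene needs exactly one of scene_dir or synth")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    scenes: list[SceneConfig] = field(default_factory=list)
    endpoint_mode: str = "fixed"  # "fixed" or "quantile"
    endpoint_values: tuple[float, float] = FIXED_ENDPOINTS  # or (lower_pct, upper_pct)
    sensor: str = "oli_tirs"
    emissivity_mode: str = "fvc"  # "fvc" (two-value by FVC threshold) or "const:<value>"
    fishnet_length_m: float = 100.0
    min_valid_fraction: float = MIN_VALID_FRACTION
    zone_edges_km: tuple[float, float] = ZONE_EDGES_KM
    out_dir: str = "coastveg_out"
    seed: int = 0
    units: str = "K"  # reporting units: "K" or "C"

    def __post_init__(self) -> None:
        if not self.scenes:
            raise ValueError("config lists no scenes")
        if self.endpoint_mode not in ("fixed", "quantile"):
            raise ValueError("endpoint_mode must be 'fixed' or 'quantile'")
        a, b = self.zone_edges_km
        if not (0 < a < b):
            raise ValueError("zone edges must be strictly increasing and positive")
        if self.units not in ("K", "C"):
            raise ValueError("units must be 'K' or 'C'")
        if not (self.emissivity_mode == "fvc" or self.emissivity_mode.startswith("const:")):
            raise ValueError("emissivity_mode must be 'fvc' or 'const:<value>'")
        for sc in self.scenes:
            if sc.scene_dir is not None:
                d = Path(sc.scene_dir)
                if not d.is_dir():
                    raise ValueError(f"scene directory not found: {sc.scene_dir}")
                for fname in ("scene.json", "coastline.geojson"):
                    if not (d / fname).exists():
                        raise ValueError(f"scene {sc.scene_dir} is missing {fname}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        scenes = [SceneConfig(**sc) for sc in doc.pop("scenes", [])]
        for key in ("endpoint_values", "zone_edges_km"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(scenes=scenes, **doc)

    def canonical_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, sort_keys=True, default=str))

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SceneReport:
    """Stage outputs of one scene."""

    scene_id: str
    date: str
    season: str
    endpoints: DimidiateEndpoints
    fvc_areas: pd.DataFrame
    lst_areas: pd.DataFrame
    uri: float
    zone_fits: pd.DataFrame
    validation: dict | None = None

    def to_dict(self) -> dict:
        return {
            "scene_id": self.scene_id,
            "date": self.date,
            "season": self.season,
            "endpoints": [self.endpoints.ndvi_soil, self.endpoints.ndvi_veg],
            "fvc_areas": self.fvc_areas.to_dict("records"),
            "lst_areas": self.lst_areas.to_dict("records"),
            "uri": self.uri,
            "zone_fits": self.zone_fits.to_dict("records"),
            "validation": self.validation,
        }


@dataclass
class RunReport:
    """Full pipeline output: per-scene reports, trend table, provenance."""

    scenes: list[SceneReport]
    uri_trend: pd.DataFrame
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "scenes": [s.to_dict() for s in self.scenes],
            "uri_trend": self.uri_trend.to_dict("records"),
            "provenance": self.provenance,
        }


def _endpoints_for(config: PipelineConfig, ndvi: RasterGrid) -> DimidiateEndpoints:
    if config.endpoint_mode == "fixed":
        soil, veg = config.endpoint_values
        return DimidiateEndpoints(soil, veg, provenance="fixed")
    lo, hi = config.endpoint_values
    return select_endpoints(ndvi, lo, hi)


def _emissivity_for(config: PipelineConfig, fvc: RasterGrid) -> RasterGrid:
    if config.emissivity_mode == "fvc":
        return emissivity_from_fvc(fvc)
    value = float(config.emissivity_mode.split(":", 1)[1])
    return constant_emissivity(fvc, value)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage for every configured scene and write artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = get_sensor_profile(config.sensor)
    scene_reports: list[SceneReport] = []
    trend_entries = []

    for i, sc in enumerate(config.scenes):
        scene_seed = (config.seed + 1000003 * i) % (2**31 - 1)
        if sc.synth is not None:
            synth_kwargs = dict(sc.synth)
            synth_kwargs.setdefault("seed", scene_seed)
            synth_kwargs.setdefault("season", sc.season)
            synth_kwargs.setdefault("date", sc.date)
            spec = LandscapeSpec(**synth_kwargs)
            atm = (
                AtmosphericParameters(**sc.atmosphere)
                if sc.atmosphere
                else DEFAULT_ATMOSPHERE[spec.season]
            )
            scene, truth = generate_scene(spec, sensor=profile, atmosphere=atm)
            coast = truth.coastline
            stations = (
                generate_stations(truth, sc.stations, sc.station_noise_sd, seed=scene_seed)
                if sc.stations
                else None
            )
        else:
            scene_dir = Path(sc.scene_dir)
            if not (scene_dir / "coastline.geojson").exists():
                raise ValueError(f"scene {scene_dir} has no coastline.geojson")
            scene, atm = read_scene_dir(scene_dir)
            coast = CoastlineGeometry.from_geojson(scene_dir / "coastline.geojson")
            stations_csv = scene_dir / "stations.csv"
            stations = read_stations_csv(stations_csv) if stations_csv.exists() else None
            truth = None

        date = sc.date or scene.date
        season = scene.season
        scene_id = f"scene_{i:02d}_{date or season}"
        scene_out = out / scene_id
        scene_out.mkdir(parents=True, exist_ok=True)
        if truth is not None:
            write_scene_dir(scene, truth, scene_out / "scene", stations)

        # vegetation
        ndvi = compute_ndvi(scene)
        endpoints = _endpoints_for(config, ndvi)
        fvc = compute_fvc(ndvi, endpoints)
        fvc_classes = classify_fvc(fvc)
        fvc_areas = class_area_table(fvc_classes, date=date, season=season)

        # thermal
        emissivity = _emissivity_for(config, fvc)
        lst = retrieve_lst(scene, emissivity, atm, profile=profile)
        validation = None
        if stations:
            validation = validate_lst(lst, stations).to_dict()

        # heat island
        zones, params, lst_areas = classify_lst_zones(lst, date=date, season=season)
        uri = uri_from_zone_table(lst_areas).uri

        # coastal zoning
        ratio = config.fishnet_length_m / scene.geometry.cell_size
        snapped = max(1, round(ratio)) * scene.geometry.cell_size
        fishnet = build_fishnet(
            fvc,
            lst,
            coast,
            cell_length=snapped,
            min_valid_fraction=config.min_valid_fraction,
            edges_km=config.zone_edges_km,
        )
        fits = fit_all_zones(fishnet, date=date)

        # artifacts
        ndvi.to_ascii(scene_out / "ndvi.asc")
        fvc.to_ascii(scene_out / "fvc.asc")
        fvc_classes.to_ascii(scene_out / "fvc_classes.asc", fmt="%g")
        lst.to_ascii(scene_out / "lst.asc")
        zones.to_ascii(scene_out / "lst_zones.asc", fmt="%g")
        fvc_areas.to_csv(scene_out / "fvc_areas.csv", index=False)
        lst_areas.to_csv(scene_out / "lst_areas.csv", index=False)
        fishnet.to_csv(scene_out / "fishnet.csv", index=False)
        fits.to_csv(scene_out / "zone_fits.csv", index=False)
        summary = {
            "scene_id": scene_id,
            "uri": uri,
            "mean_sd": {"mu": params.mu, "std": params.std},
            "validation": validation,
            "units_note": "temperatures in kelvin" if config.units == "K" else "report °C",
        }
        (scene_out / "summary.json").write_text(json.dumps(summary, indent=2))

        scene_reports.append(
            SceneReport(
                scene_id=scene_id,
                date=date,
                season=season,
                endpoints=endpoints,
                fvc_areas=fvc_areas,
                lst_areas=lst_areas,
                uri=uri,
                zone_fits=fits,
                validation=validation,
            )
        )
        trend_entries.append((date or f"{2000 + i}", season, lst_areas))

    trend = uri_trend_table(trend_entries)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    trend.to_csv(out / "uri_trend.csv", index=False)
    report = RunReport(scenes=scene_reports, uri_trend=trend, provenance=provenance)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, default=str))
    return report


# ------------------------------------------------------- packaged area fixture

_FVC_COLS = {
    "blw_km2": "BL&W",
    "l_fvc_km2": "L-FVC",
    "sl_fvc_km2": "SL-FVC",
    "m_fvc_km2": "M-FVC",
    "h_fvc_km2": "H-FVC",
}
_LST_COLS = {
    "htz_km2": "HTZ",
    "shtz_km2": "SHTZ",
    "mtz_km2": "MTZ",
    "sltz_km2": "SLTZ",
    "ltz_km2": "LTZ",
}


def load_published_areas(csv_path: str | Path | None = None) -> pd.DataFrame:
    """The packaged per-scene class-area table (km²), wide format."""
    if csv_path is None:
        ref = importlib.resources.files("coastveg") / "data" / "published_class_areas.csv"
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p, dtype={"date": str})
    return pd.read_csv(csv_path, dtype={"date": str})


def summarize_published_areas(csv_path: str | Path | None = None) -> pd.DataFrame:
    """Per-scene class proportions (%) and URI from the packaged area table.

    Returns one row per (season, date) with FVC-class and LST-zone
    proportions (rounded to 2 decimals at this reporting boundary) and
    the URI recomputed from the unrounded LST proportions.
    """
    wide = load_published_areas(csv_path)
    required = {"season", "date", *_FVC_COLS, *_LST_COLS}
    missing = required - set(wide.columns)
    if missing:
        raise ValueError(f"area table is missing columns: {sorted(missing)}")
    rows = []
    for _, r in wide.iterrows():
        fvc_total = sum(r[c] for c in _FVC_COLS)
        lst_total = sum(r[c] for c in _LST_COLS)
        if fvc_total <= 0 or lst_total <= 0:
            raise ValueError(f"row {r['date']} has nonpositive total area")
        row: dict[str, Any] = {"season": r["season"], "date": r["date"]}
        for col, label in _FVC_COLS.items():
            row[f"p_{label}"] = round(100.0 * r[col] / fvc_total, 2)
        lst_props = {}
        for col, label in _LST_COLS.items():
            lst_props[label] = 100.0 * r[col] / lst_total
            row[f"p_{label}"] = round(lst_props[label], 2)
        row["uri"] = compute_uri(lst_props).uri
        rows.append(row)
    return pd.DataFrame(rows)
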