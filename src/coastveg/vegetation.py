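"""NDVI, dimidiate-pixel FVC inversion, FVC classes and area accounting.

The dimidiate pixel model treats every pixel as a linear mix of a pure
bare-soil endmember and a pure full-vegetation endmember; fractional
vegetation cover (FVC) is the mixing coefficient recovered from NDVI::

    FVC = (NDVI - NDVI_soil) / (NDVI_veg - NDVI_soil)

Endpoints can be fixed constants (0.06 / 0.6, a common choice for
temperate coastal scenes), scene quantiles of the NDVI cumulative
frequency (default 5% / 95%), or derived from known FVC extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import RasterGrid, Scene

#: Fixed dimidiate endpoints used by the default analysis configuration.
FIXED_ENDPOINTS = (0.06, 0.6)

#: FVC class codes and labels: [0,0.2) bare land & water, then four 0.2-wide
#: vegetation classes; the top bin [0.8, 1.0] is closed.
FVC_CLASS_LABELS: dict[int, str] = {
    1: "BL&W",
    2: "L-FVC",
    3: "SL-FVC",
    4: "M-FVC",
    5: "H-FVC",
}
_FVC_BIN_EDGES = np.array([0.0, 0.2, 0.4, 0.6, 0.8])


@dataclass(frozen=True)
class DimidiateEndpoints:
    """The (NDVI_soil, NDVI_veg) pair driving the FVC inversion."""

    ndvi_soil: float
    ndvi_veg: float
    provenance: str = "fixed"

    def __post_init__(self) -> None:
        if not (-1 <= self.ndvi_soil <= 1 and -1 <= self.ndvi_veg <= 1):
            raise ValueError("endpoints must lie within [-1, 1]")
        if not self.ndvi_soil < self.ndvi_veg:
            raise ValueError(
                f"degenerate endpoints: NDVI_soil={self.ndvi_soil} must be "
                f"< NDVI_veg={self.ndvi_veg}"
            )


def compute_ndvi(scene: Scene) -> RasterGrid:
    """Normalized difference vegetation index, (NIR − red)/(NIR + red).

    Pixels where either band is NoData, or where the denominator is zero,
    become NoData; finite values are clamped to [−1, 1].
    """
    red, nir = scene.red, scene.nir
    red.assert_coregistered(nir)
    denom = nir.values + red.values
    bad = red.mask | nir.mask | (denom == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir.values - red.values) / denom
    ndvi = np.clip(ndvi, -1.0, 1.0)
    ndvi[bad] = np.nan
    return RasterGrid(ndvi, red.geometry, bad)


def select_endpoints(
    ndvi: RasterGrid, lower_pct: float = 5.0, upper_pct: float = 95.0
) -> DimidiateEndpoints:
    """Endpoints as quantiles of the scene NDVI cumulative frequency.

    Quantiles are linearly interpolated on the sorted finite values.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    finite = ndvi.finite_values()
    if finite.size == 0:
        raise ValueError("cannot select endpoints from an all-NoData NDVI grid")
    lo, hi = np.percentile(finite, [lower_pct, upper_pct])
    if lo == hi:
        raise ValueError(
            f"degenerate endpoints: the {lower_pct}% and {upper_pct}% quantiles coincide at {lo}"
        )
    return DimidiateEndpoints(
        float(lo), float(hi), provenance=f"quantile:{lower_pct:g},{upper_pct:g}"
    )


def endpoints_from_extremes(
    ndvi_min: float, ndvi_max: float, fvc_min: float, fvc_max: float
) -> DimidiateEndpoints:
    """Endpoints from known NDVI extremes and the FVC they correspond to.

    When the scene's darkest pixel is not pure soil (FVC_min > 0) or its
    greenest pixel not full canopy (FVC_max < 1), the pure-endmember NDVI
    values are extrapolated::

        NDVI_soil = (FVC_max·NDVI_min − FVC_max·NDVI_max) / (FVC_max − FVC_min)
        NDVI_veg  = ((1−FVC_min)·NDVI_max − (1−FVC_max)·NDVI_min) / (FVC_max − FVC_min)

    These are the published forms of the endpoint equations; this is an
    alternative path — the default analysis uses fixed or quantile
    endpoints instead.
    """
    if fvc_max == fvc_min:
        raise ZeroDivisionError("fvc_max and fvc_min must differ")
    if not (ndvi_min < ndvi_max and fvc_min < fvc_max):
        raise ValueError("need ndvi_min < ndvi_max and fvc_min < fvc_max")
    denom = fvc_max - fvc_min
    soil = (fvc_max * ndvi_min - fvc_max * ndvi_max) / denom
    veg = ((1 - fvc_min) * ndvi_max - (1 - fvc_max) * ndvi_min) / denom
    return DimidiateEndpoints(soil, veg, provenance="extremes")


def compute_fvc(ndvi: RasterGrid, endpoints: DimidiateEndpoints) -> RasterGrid:
    """Invert FVC by the dimidiate pixel model; results are clamped to [0, 1]."""
    fvc = (ndvi.values - endpoints.ndvi_soil) / (endpoints.ndvi_veg - endpoints.ndvi_soil)
    fvc = np.clip(fvc, 0.0, 1.0)
    return ndvi.like(fvc)


def classify_fvc(fvc: RasterGrid) -> RasterGrid:
    """Five-class FVC map on bins [0,.2), [.2,.4), [.4,.6), [.6,.8), [.8,1]."""
    finite = fvc.finite_values()
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("FVC values must lie in [0, 1]; clamp before classifying")
    codes = np.searchsorted(_FVC_BIN_EDGES, fvc.values, side="right").astype(float)
    return fvc.like(codes)


def class_area_table(
    class_map: RasterGrid,
    cell_area_km2: float | None = None,
    labels: dict[int, str] = FVC_CLASS_LABELS,
    date: str = "",
    season: str = "",
) -> pd.DataFrame:
    """Per-class area (km²) and proportion (%) over the non-NoData pixels.

    Works for any integer-coded class map (FVC classes or temperature
    zones) given its code→label table.  Classes absent from the map get a
    zero row so tables from different scenes align.
    """
    if cell_area_km2 is None:
        cell_area_km2 = class_map.geometry.cell_area_km2
    if not cell_area_km2 > 0:
        raise ValueError("cell area must be positive")
    codes = class_map.finite_values().astype(int)
    if codes.size == 0:
        raise ValueError("class map contains no valid pixels")
    counts = {code: int(np.sum(codes == code)) for code in labels}
    total_area = codes.size * cell_area_km2
    rows = []
    for code, label in labels.items():
        area = counts[code] * cell_area_km2
        rows.append(
            {
                "date": date,
                "season": season,
                "class": label,
                "area_km2": area,
                "proportion_pct": 100.0 * area / total_area,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["total_area_km2"] = total_area
    return table


def proportions_from_areas(areas: "pd.Series | dict[str, float]") -> pd.Series:
    """Class proportions (%) from a label → area (km²) mapping."""
    s = pd.Series(areas, dtype=float)
    if (s < 0).any():
        raise ValueError("areas must be nonnegative")
    total = s.sum()
    if total <= 0:
        raise ValueError("total area must be positive")
    return 100.0 * s / total
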