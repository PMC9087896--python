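"""Mean–standard-deviation temperature zoning and the heat-island ratio index.

A scene's LST field is split into five temperature zones around the scene
mean μ with half- and full-SD offsets (HTZ above μ+std down to LTZ at or
below μ−std).  The urban-heat-island ratio index (URI) then condenses the
zone composition into one number::

    URI = (1 / (100·m)) · Σ ωᵢ·pᵢ ,  m = 5

with weights ω = 5…1 from the hottest to the coldest zone and pᵢ the zone
area percentages.  URI lies in [0.2, 1.0]; larger means a more developed
heat island.

Zoning depends on the LST values only through (LST − μ)/std, so it is
invariant under positive affine transforms; min–max normalisation is
provided for display parity but is not needed for classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import RasterGrid
from .vegetation import class_area_table

#: Zone codes and labels, 1 = coldest … 5 = hottest.
ZONE_LABELS: dict[int, str] = {
    1: "LTZ",
    2: "SLTZ",
    3: "MTZ",
    4: "SHTZ",
    5: "HTZ",
}
#: URI weights per zone label (hottest zone weighs most).
URI_WEIGHTS: dict[str, int] = {"HTZ": 5, "SHTZ": 4, "MTZ": 3, "SLTZ": 2, "LTZ": 1}
ZONE_ORDER = ("HTZ", "SHTZ", "MTZ", "SLTZ", "LTZ")


@dataclass(frozen=True)
class MeanSdParams:
    """Scene mean and standard deviation (population convention) of LST."""

    mu: float
    std: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mean must be finite")
        if self.std < 0:
            raise ValueError("standard deviation must be nonnegative")


def normalize_lst(lst: RasterGrid) -> RasterGrid:
    """Min–max rescale the finite LST values to [0, 1]; NoData propagates."""
    finite = lst.finite_values()
    if finite.size < 2:
        raise ValueError("need at least two finite pixels to normalize")
    lo, hi = finite.min(), finite.max()
    if lo == hi:
        raise ValueError("constant LST grid cannot be min-max normalized")
    return lst.like((lst.values - lo) / (hi - lo))


def classify_mean_sd(lst: RasterGrid) -> tuple[RasterGrid, MeanSdParams]:
    """Five-zone mean-SD classification of an LST grid.

    HTZ:  LST >  μ + std
    SHTZ: μ + 0.5·std < LST ≤ μ + std
    MTZ:  μ − 0.5·std < LST ≤ μ + 0.5·std
    SLTZ: μ − std < LST ≤ μ − 0.5·std
    LTZ:  LST ≤ μ − std

    μ and std are computed over the finite pixels with the population
    (divide-by-n) convention.  A constant grid (std = 0) degenerates to
    all-MTZ with a warning.
    """
    finite = lst.finite_values()
    if finite.size < 2:
        raise ValueError("need at least two finite pixels to classify")
    mu = float(np.mean(finite))
    std = float(np.std(finite))  # population convention
    params = MeanSdParams(mu, std)
    if std == 0:
        warnings.warn("constant LST grid: every pixel classified MTZ", stacklevel=2)
        return lst.like(np.full(lst.shape, 3.0)), params
    v = lst.values
    codes = np.full(lst.shape, np.nan)
    codes = np.where(v <= mu - std, 1.0, codes)
    codes = np.where((v > mu - std) & (v <= mu - 0.5 * std), 2.0, codes)
    codes = np.where((v > mu - 0.5 * std) & (v <= mu + 0.5 * std), 3.0, codes)
    codes = np.where((v > mu + 0.5 * std) & (v <= mu + std), 4.0, codes)
    codes = np.where(v > mu + std, 5.0, codes)
    return lst.like(codes), params


def classify_lst_zones(
    lst: RasterGrid, date: str = "", season: str = ""
) -> tuple[RasterGrid, MeanSdParams, pd.DataFrame]:
    """Zone map, mean-SD parameters and the zone area/proportion table."""
    zones, params = classify_mean_sd(lst)
    table = class_area_table(zones, labels=ZONE_LABELS, date=date, season=season)
    return zones, params, table


@dataclass(frozen=True)
class UriResult:
    """URI with the zone proportions and weights it was computed from."""

    uri: float
    proportions_pct: dict[str, float] = field(default_factory=dict)
    weights: dict[str, int] = field(default_factory=lambda: dict(URI_WEIGHTS))
    m: int = 5


def compute_uri(proportions: Mapping[str, float] | Sequence[float]) -> UriResult:
    """URI from zone area percentages.

    ``proportions`` is either a label → percent mapping or a sequence in
    the order HTZ, SHTZ, MTZ, SLTZ, LTZ.  Percentages must be nonnegative
    and sum to at most 100 (plus a small tolerance).
    """
    if isinstance(proportions, Mapping):
        p = {z: float(proportions.get(z, 0.0)) for z in ZONE_ORDER}
    else:
        seq = list(proportions)
        if len(seq) != 5:
            raise ValueError("need exactly five zone proportions")
        p = dict(zip(ZONE_ORDER, map(float, seq)))
    if any(v < 0 for v in p.values()):
        raise ValueError("zone proportions must be nonnegative")
    total = sum(p.values())
    if total > 100 + 1e-6:
        raise ValueError(f"zone proportions sum to {total} > 100")
    m = 5
    uri = sum(URI_WEIGHTS[z] * p[z] for z in ZONE_ORDER) / (100.0 * m)
    return UriResult(uri=uri, proportions_pct=p, m=m)


def uri_from_zone_table(table: pd.DataFrame) -> UriResult:
    """URI from a zone area table (``class``/``proportion_pct`` columns)."""
    props = dict(zip(table["class"], table["proportion_pct"]))
    return compute_uri(props)


def _decimal_year(date: str) -> float:
    """'2020.06' → 2020 + (6−1)/12; plain '2020' → 2020.0."""
    parts = str(date).split(".")
    year = float(parts[0])
    if len(parts) > 1 and parts[1]:
        year += (float(parts[1]) - 1.0) / 12.0
    return year


def uri_trend_table(entries: Iterable[tuple[str, str, pd.DataFrame]]) -> pd.DataFrame:
    """Per-scene URI and zone proportions with a per-season linear trend.

    ``entries`` are (date, season, zone area table) triples.  The returned
    frame has one row per scene plus a ``trend_slope_per_year`` column
    (least squares URI-vs-year slope of that season; null when the season
    has a single scene).
    """
    entries = list(entries)
    if not entries:
        raise ValueError("need at least one scene entry")
    rows = []
    for date, season, table in entries:
        res = uri_from_zone_table(table)
        row = {"date": date, "season": season, "year": _decimal_year(date), "uri": res.uri}
        row.update({f"p_{z.lower()}": res.proportions_pct[z] for z in ZONE_ORDER})
        rows.append(row)
    out = pd.DataFrame(rows)
    out["trend_slope_per_year"] = np.nan
    for season, grp in out.groupby("season"):
        if len(grp) >= 2:
            slope = np.polyfit(grp["year"], grp["uri"], 1)[0]
            out.loc[grp.index, "trend_slope_per_year"] = slope
    # undefined slopes (single-scene seasons) are reported as null, not NaN
    col = out["trend_slope_per_year"]
    out["trend_slope_per_year"] = col.astype(object).where(col.notna(), None)
    return out
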