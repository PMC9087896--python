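"""Land-surface temperature retrieval from a thermal band.

The retrieval is the classic single-band radiative-transfer chain:

1. linear calibration of digital numbers to at-sensor spectral radiance,
   ``L_sen = gain · DN + offset``;
2. inversion of the thermal radiative transfer equation
   ``L_sen = (ε·B(T_s) + (1 − ε)·L_d)·τ + L_u`` for the surface blackbody
   radiance ``B(T_s)``;
3. conversion of blackbody radiance to kelvin through the inverse Planck
   relation ``T_s = K2 / ln(K1 / B + 1)``.

All temperatures are kept in kelvin internally; conversion to °C happens
only at the reporting boundary.  Retrieved values outside a plausibility
window (default [220, 340] K) are masked rather than raised, so batch
runs survive degenerate pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .grids import RasterGrid, Scene
from .sensors import AtmosphericParameters, SensorProfile, get_sensor_profile

#: Broadband thermal emissivities of the two-value scheme: full vegetation
#: canopy and bare/impervious surfaces.
EPS_VEGETATION = 0.986
EPS_SOIL = 0.970
#: FVC at or above which a pixel uses the vegetation emissivity.
EPS_FVC_THRESHOLD = 0.5

#: Default plausibility window for retrieved land-surface temperature (K).
LST_BOUNDS = (220.0, 340.0)


def calibrate_dn(thermal: RasterGrid, profile: SensorProfile) -> RasterGrid:
    """DN → at-sensor spectral radiance by the linear calibration."""
    radiance = profile.gain * thermal.values + profile.offset
    return thermal.like(radiance)


def radiance_from_dn_inverse(radiance: np.ndarray, profile: SensorProfile) -> np.ndarray:
    """Radiance → quantized DN (inverse calibration), for scene synthesis."""
    dn = np.rint((radiance - profile.offset) / profile.gain)
    return np.clip(dn, 0, 65535)


def emissivity_from_fvc(
    fvc: RasterGrid,
    eps_vegetation: float = EPS_VEGETATION,
    eps_soil: float = EPS_SOIL,
    threshold: float = EPS_FVC_THRESHOLD,
) -> RasterGrid:
    """Two-value emissivity: ε_v where FVC ≥ threshold, ε_s elsewhere."""
    for eps in (eps_vegetation, eps_soil):
        if not (0 < eps <= 1):
            raise ValueError("emissivities must lie in (0, 1]")
    eps = np.where(fvc.values >= threshold, eps_vegetation, eps_soil)
    return fvc.like(eps)


def constant_emissivity(template: RasterGrid, value: float) -> RasterGrid:
    """Spatially constant emissivity field on the template's geometry/mask."""
    if not (0 < value <= 1):
        raise ValueError(f"emissivity must lie in (0, 1], got {value}")
    return template.like(np.full(template.shape, float(value)))


def solve_surface_radiance(
    l_sen: RasterGrid, emissivity: RasterGrid, atm: AtmosphericParameters
) -> RasterGrid:
    """Invert the radiative transfer equation for B(T_s).

    ``B(T_s) = ((L_sen − L_u)/τ − (1 − ε)·L_d) / ε``; pixels where the
    result is nonpositive (physically impossible surface emission) become
    NoData.
    """
    if not atm.tau > 0:
        raise ValueError("transmissivity must be positive")
    eps = emissivity.values
    finite_eps = emissivity.finite_values()
    if finite_eps.size and finite_eps.min() <= 0:
        raise ValueError("emissivity must be positive")
    l_sen.assert_coregistered(emissivity)
    with np.errstate(invalid="ignore"):
        b = ((l_sen.values - atm.l_up) / atm.tau - (1 - eps) * atm.l_down) / eps
    nonpos = b <= 0
    b = np.where(nonpos, np.nan, b)
    return l_sen.like(b, extra_mask=emissivity.mask | nonpos)


def radiance_to_temperature(b: RasterGrid, profile: SensorProfile) -> RasterGrid:
    """Inverse Planck relation, T = K2 / ln(K1/B + 1), in kelvin."""
    vals = b.values
    with np.errstate(divide="ignore", invalid="ignore"):
        t = profile.k2 / np.log(profile.k1 / vals + 1.0)
    nonpos = ~(vals > 0)
    t = np.where(nonpos, np.nan, t)
    return b.like(t, extra_mask=nonpos)


def planck_radiance(temperature_k: np.ndarray, profile: SensorProfile) -> np.ndarray:
    """Forward Planck relation for this band, B = K1 / (exp(K2/T) − 1)."""
    t = np.asarray(temperature_k, dtype=float)
    return profile.k1 / (np.expm1(profile.k2 / t))


def retrieve_lst(
    scene: Scene,
    emissivity: RasterGrid,
    atm: AtmosphericParameters,
    profile: SensorProfile | None = None,
    bounds: tuple[float, float] = LST_BOUNDS,
) -> RasterGrid:
    """Full DN → LST chain with plausibility masking.

    ``bounds`` masks gross failures (e.g. saturated or miscalibrated
    pixels) instead of raising.
    """
    if scene.thermal is None:
        raise ValueError("scene has no thermal band")
    if profile is None:
        profile = get_sensor_profile(scene.sensor_id)
    if scene.thermal_kind == "dn":
        l_sen = calibrate_dn(scene.thermal, profile)
    else:
        l_sen = scene.thermal
    b = solve_surface_radiance(l_sen, emissivity, atm)
    lst = radiance_to_temperature(b, profile)
    lo, hi = bounds
    out_of_range = (lst.values < lo) | (lst.values > hi)
    vals = np.where(out_of_range, np.nan, lst.values)
    return lst.like(vals, extra_mask=out_of_range)


@dataclass(frozen=True)
class ValidationResult:
    """Station validation of a retrieved LST grid."""

    mae: float  # kelvin
    rmse: float  # kelvin
    n: int
    table: pd.DataFrame  # station_id, observed_k, predicted_k, residual_k

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "n": self.n}


def validate_lst(lst: RasterGrid, stations: Iterable) -> ValidationResult:
    """MAE / RMSE of retrieved LST against point station observations.

    Stations are matched to the pixel containing their coordinates (point
    sampling); stations falling outside the grid or on NoData pixels are
    dropped.  Raises if no station matches.
    """
    stations = list(stations)
    rows = []
    geom = lst.geometry
    for st in stations:
        r, c = geom.index_of(st.x, st.y)
        r, c = int(r), int(c)
        if not (0 <= r < geom.rows and 0 <= c < geom.cols):
            continue
        if lst.mask[r, c]:
            continue
        pred = float(lst.values[r, c])
        rows.append(
            {
                "station_id": st.station_id,
                "observed_k": st.temperature_k,
                "predicted_k": pred,
                "residual_k": pred - st.temperature_k,
            }
        )
    if not rows:
        raise ValueError("no station falls on a valid LST pixel")
    table = pd.DataFrame(rows)
    resid = table["residual_k"].to_numpy()
    return ValidationResult(
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=len(rows),
        table=table,
    )


def kelvin_to_celsius(values: np.ndarray | float) -> np.ndarray | float:
    """Reporting-boundary conversion; the pipeline itself stays in kelvin."""
    return np.asarray(values) - 273.15 if isinstance(values, np.ndarray) else values - 273.15
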