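"""Sensor calibration profiles and per-scene atmospheric parameters.

The thermal chain needs three pieces of configuration: the linear DN →
radiance calibration (gain, offset), the two Planck calibration constants
K1 (W·m⁻²·sr⁻¹·µm⁻¹) and K2 (K) of the thermal band, and the per-scene
atmospheric terms (transmissivity τ, upwelling and downwelling path
radiance).  Profiles for the three Landsat-era sensor generations are
shipped with the published handbook constants.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SensorProfile:
    """Thermal-band calibration of one sensor generation."""

    sensor_id: str
    gain: float  # radiance per DN
    offset: float  # radiance at DN=0
    k1: float  # W·m⁻²·sr⁻¹·µm⁻¹
    k2: float  # kelvin

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("calibration gain must be positive")
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("thermal constants K1 and K2 must be positive")


#: Published thermal-band constants: Landsat 5 TM band 6, Landsat 7 ETM+
#: band 6, Landsat 8 TIRS band 10.
SENSOR_PROFILES: dict[str, SensorProfile] = {
    "tm": SensorProfile("tm", gain=0.055375, offset=1.18243, k1=607.76, k2=1260.56),
    "etm": SensorProfile("etm", gain=0.067087, offset=3.1628, k1=666.09, k2=1282.71),
    "oli_tirs": SensorProfile(
        "oli_tirs", gain=3.342e-4, offset=0.1, k1=774.8853, k2=1321.0789
    ),
}


def get_sensor_profile(name: str) -> SensorProfile:
    try:
        return SENSOR_PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown sensor profile {name!r}; available: {sorted(SENSOR_PROFILES)}"
        ) from None


@dataclass(frozen=True)
class AtmosphericParameters:
    """Effective atmosphere of one acquisition for the thermal band.

    tau
        band-effective atmospheric transmissivity, in (0, 1].
    l_up, l_down
        upwelling / downwelling path radiance, W·m⁻²·sr⁻¹·µm⁻¹.
    """

    tau: float
    l_up: float
    l_down: float

    def __post_init__(self) -> None:
        if not (0 < self.tau <= 1):
            raise ValueError(f"transmissivity must be in (0, 1], got {self.tau}")
        if self.l_up < 0 or self.l_down < 0:
            raise ValueError("path radiances must be nonnegative")


#: Typical humid-summer and dry-winter mid-latitude values for a 10.9 µm band.
DEFAULT_ATMOSPHERE: dict[str, AtmosphericParameters] = {
    "summer": AtmosphericParameters(tau=0.85, l_up=1.81, l_down=2.99),
    "winter": AtmosphericParameters(tau=0.95, l_up=0.60, l_down=1.05),
}
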