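"""Solar geometry and terrain radiation downscaling.

Three steps turn a single global-horizontal-irradiance (GHI) measurement
into a per-cell incident shortwave field on complex terrain:

1. solar position (declination, equation of time, hour angle -> zenith and
   azimuth) from a NOAA-style series solution, accurate to well under 0.5
   degrees — ample for hourly forcing;
2. partition of GHI into direct-normal (DNI) and diffuse-horizontal (DHI)
   components through the Erbs clearness-index correlation;
3. projection onto each cell: direct beam on the tilted surface where the
   terrain horizon does not occlude the sun, diffuse sky radiation scaled
   by the sky view factor, and ground-reflected radiation from the
   obstructed part of the hemisphere.

All timestamps are UTC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .terrain import TerrainDerivatives

__all__ = [
    "SolarPosition",
    "IrradianceComponents",
    "IncidentField",
    "solar_position",
    "partition_direct_diffuse",
    "cast_shadow_mask",
    "incident_shortwave",
    "clear_sky_ghi",
]

SOLAR_CONSTANT = 1367.0  # W m-2

# Erbs et al. diffuse-fraction correlation; coefficients kept in module
# scope so an alternative split can be swapped in.
ERBS_KT_LOW = 0.22
ERBS_KT_HIGH = 0.80
ERBS_POLY = (0.9511, -0.1604, 4.388, -16.638, 12.336)
ERBS_OVERCAST_SLOPE = 0.09
ERBS_CLEAR_FRACTION = 0.165

COS_ZENITH_FLOOR = 0.01  # avoid DNI blow-up near the horizon


@dataclass(frozen=True)
class SolarPosition:
    """Sun geometry at one instant and location (degrees)."""

    zenith: float
    azimuth: float
    declination: float
    hour_angle: float
    earth_sun_factor: float

    @property
    def elevation(self) -> float:
        return 90.0 - self.zenith

    @property
    def above_horizon(self) -> bool:
        return self.zenith < 90.0


@dataclass(frozen=True)
class IrradianceComponents:
    """Global/direct/diffuse split of shortwave irradiance (W m-2)."""

    ghi: float
    dni: float
    dhi: float
    clearness_index: float


@dataclass
class IncidentField:
    """Per-cell incident shortwave flux (W m-2) with the shadow mask used."""

    flux: np.ndarray
    shadow: np.ndarray


def _day_angle(timestamp: pd.Timestamp) -> float:
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    else:
        ts = ts.tz_convert("UTC")
    frac_hour = ts.hour + ts.minute / 60 + ts.second / 3600
    return 2 * np.pi / 365.0 * (ts.dayofyear - 1 + (frac_hour - 12) / 24)


def solar_position(timestamp, latitude: float, longitude: float) -> SolarPosition:
    """Solar zenith/azimuth at a UTC instant for a site (degrees east positive).

    Uses the Spencer Fourier series for declination, the equation of time
    and the Earth-sun distance (eccentricity) correction, then the standard
    spherical-astronomy transform to horizon coordinates.
    """
    if abs(latitude) > 90:
        raise ValueError("latitude must be within [-90, 90]")
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    else:
        ts = ts.tz_convert("UTC")
    g = _day_angle(ts)

    earth_sun = (
        1.000110
        + 0.034221 * np.cos(g)
        + 0.001280 * np.sin(g)
        + 0.000719 * np.cos(2 * g)
        + 0.000077 * np.sin(2 * g)
    )
    decl = np.degrees(
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )  # minutes

    utc_minutes = ts.hour * 60 + ts.minute + ts.second / 60
    true_solar_minutes = utc_minutes + eqtime + 4 * longitude
    hour_angle = (true_solar_minutes / 4 - 180.0 + 180.0) % 360.0 - 180.0

    lat_r, dec_r, ha_r = map(np.radians, (latitude, decl, hour_angle))
    cos_zen = np.sin(lat_r) * np.sin(dec_r) + np.cos(lat_r) * np.cos(dec_r) * np.cos(ha_r)
    cos_zen = np.clip(cos_zen, -1.0, 1.0)
    zenith = np.degrees(np.arccos(cos_zen))

    sin_el = cos_zen
    cos_el = np.sqrt(max(0.0, 1 - sin_el**2))
    if cos_el < 1e-9:
        azimuth = 180.0  # sun at zenith/nadir: azimuth degenerate
    else:
        cos_az = (np.sin(dec_r) - sin_el * np.sin(lat_r)) / (cos_el * np.cos(lat_r))
        az = np.degrees(np.arccos(np.clip(cos_az, -1.0, 1.0)))
        azimuth = az if hour_angle <= 0 else 360.0 - az
    return SolarPosition(
        zenith=float(zenith),
        azimuth=float(azimuth % 360.0),
        declination=float(decl),
        hour_angle=float(hour_angle),
        earth_sun_factor=float(earth_sun),
    )


def erbs_diffuse_fraction(kt: float) -> float:
    """Diffuse fraction of GHI as a function of the clearness index."""
    if kt <= ERBS_KT_LOW:
        return 1.0 - ERBS_OVERCAST_SLOPE * kt
    if kt <= ERBS_KT_HIGH:
        return float(np.polyval(ERBS_POLY[::-1], kt))
    return ERBS_CLEAR_FRACTION


def partition_direct_diffuse(ghi: float, position: SolarPosition) -> IrradianceComponents:
    """Split GHI into DNI and DHI via the Erbs clearness-index correlation.

    kt is GHI over extraterrestrial horizontal irradiance; with the sun
    below the horizon all irradiance is treated as diffuse.
    """
    if ghi < 0:
        raise ValueError("ghi must be non-negative")
    cos_zen = np.cos(np.radians(position.zenith))
    if cos_zen <= 0 or ghi == 0:
        return IrradianceComponents(ghi=ghi, dni=0.0, dhi=ghi, clearness_index=0.0)
    e0_horizontal = SOLAR_CONSTANT * position.earth_sun_factor * cos_zen
    kt = min(ghi / e0_horizontal, 1.0)
    dhi = erbs_diffuse_fraction(kt) * ghi
    dni = max(0.0, (ghi - dhi) / max(cos_zen, COS_ZENITH_FLOOR))
    return IrradianceComponents(ghi=ghi, dni=dni, dhi=dhi, clearness_index=kt)


def horizon_angle_toward(derivatives: TerrainDerivatives, azimuth: float) -> np.ndarray:
    """Per-cell horizon angle toward an arbitrary azimuth, linearly
    interpolated (circularly) between the two adjacent search directions."""
    if derivatives.horizon_angles is None:
        raise ValueError("horizon angles must be computed first")
    n = derivatives.n_directions
    step = 360.0 / n
    pos = (azimuth % 360.0) / step
    i0 = int(np.floor(pos)) % n
    i1 = (i0 + 1) % n
    w = pos - np.floor(pos)
    return (1 - w) * derivatives.horizon_angles[i0] + w * derivatives.horizon_angles[i1]


def cast_shadow_mask(derivatives: TerrainDerivatives, position: SolarPosition) -> np.ndarray:
    """True where terrain occludes the direct beam.

    A cell is shadowed when its horizon angle toward the solar azimuth is at
    least the solar elevation; the whole grid is shadowed when the sun is
    below the astronomical horizon.
    """
    shape = derivatives.dem.shape
    if not position.above_horizon:
        return np.ones(shape, dtype=bool)
    h = horizon_angle_toward(derivatives, position.azimuth)
    shadow = h >= position.elevation
    return np.where(np.isnan(h), True, shadow).astype(bool)


def incident_shortwave(
    components: IrradianceComponents,
    derivatives: TerrainDerivatives,
    position: SolarPosition,
    ground_albedo: float = 0.15,
    shadow: np.ndarray | None = None,
) -> IncidentField:
    """Downscale the irradiance split onto the terrain.

    flux = DNI * cos(theta_i) * (1 - shadow) + DHI * SVF
           + GHI * ground_albedo * (1 - SVF)

    where cos(theta_i) is the beam incidence cosine on the tilted cell,
    clamped at 0 for self-shaded orientations.
    """
    if derivatives.slope is None or derivatives.svf is None:
        raise ValueError("terrain derivatives incomplete (need slope/aspect/svf)")
    if shadow is None:
        shadow = cast_shadow_mask(derivatives, position)
    zen_r = np.radians(position.zenith)
    slope_r = np.radians(derivatives.slope)
    rel_az = np.radians(position.azimuth - derivatives.aspect)
    cos_inc = np.cos(zen_r) * np.cos(slope_r) + np.sin(zen_r) * np.sin(slope_r) * np.cos(rel_az)
    cos_inc = np.clip(cos_inc, 0.0, None)
    direct = components.dni * cos_inc * (~shadow)
    diffuse = components.dhi * derivatives.svf
    reflected = components.ghi * ground_albedo * (1.0 - derivatives.svf)
    return IncidentField(flux=direct + diffuse + reflected, shadow=shadow)


def clear_sky_ghi(position: SolarPosition, transmittance: float = 0.75) -> float:
    """Beer-law clear-sky global horizontal irradiance (W m-2).

    ghi = S0 * E * tau^(1/cos(zenith)) * cos(zenith); zero with the sun
    below the horizon. Used for synthetic forcing only.
    """
    if not 0 < transmittance <= 1:
        raise ValueError("transmittance must be in (0, 1]")
    cos_zen = np.cos(np.radians(position.zenith))
    if cos_zen <= 0:
        return 0.0
    air_mass_exponent = 1.0 / max(cos_zen, COS_ZENITH_FLOOR)
    return float(
        SOLAR_CONSTANT * position.earth_sun_factor * transmittance**air_mass_exponent * cos_zen
    )
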