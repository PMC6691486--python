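"""Hourly surface temperature from a steady-state heat budget.

Each aerially exposed cell solves, at every hourly step, the energy balance

    alpha*I + eps*sigma*[SVF*eps_sky*T_a^4 + (1-SVF)*T_a^4]
        - eps*sigma*T_s^4 - h_c*(T_s - T_a) - g_k*(T_s - T_sub) = 0

for the surface (rock) temperature T_s (kelvin inside the balance):
absorbed shortwave, sky longwave weighted by the sky view factor plus
terrain longwave from surroundings radiating at air temperature, emitted
longwave, wind-driven convection h_c = h0 + a*u^b, and linear conduction
to the substrate at T_sub. Rock temperature stands in for the body
temperature of organisms pressed flat against it (limpets, barnacles).

The balance is steady-state per hour — no thermal inertia — matching the
hourly forcing cadence. Submerged cells (elevation at or below the still
tide level) are pinned to water temperature exactly. Evaporation and
tidepool retention are deliberately excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import IncidentField, cast_shadow_mask, incident_shortwave, partition_direct_diffuse, solar_position
from .terrain import ElevationGrid, TerrainDerivatives

__all__ = [
    "WeatherRecord",
    "HeatBudgetParams",
    "TemperatureField",
    "exposure_mask",
    "sky_emissivity",
    "solve_surface_temperature",
    "run_simulation",
    "read_weather_csv",
    "read_tide_csv",
]

STEFAN_BOLTZMANN = 5.670374419e-8  # W m-2 K-4
KELVIN = 273.15


@dataclass(frozen=True)
class WeatherRecord:
    """One hour of atmospheric forcing."""

    timestamp: pd.Timestamp
    air_temperature: float  # degC
    wind_speed: float  # m s-1
    ghi: float  # W m-2
    water_temperature: float  # degC

    def __post_init__(self) -> None:
        if self.wind_speed < 0:
            raise ValueError("wind_speed must be non-negative")
        if self.ghi < 0:
            raise ValueError("ghi must be non-negative")


@dataclass(frozen=True)
class HeatBudgetParams:
    """Coefficients of the surface energy balance.

    Defaults are standard biophysical values for dark intertidal rock:
    shortwave absorptivity 0.75, thermal emissivity 0.95, convection
    h_c = 5 + 4 u^0.8 W m-2 K-1, substrate conductance 10 W m-2 K-1.
    ``sky_emissivity_mode`` is "swinbank" (clear-sky correlation in air
    temperature) or "fixed" with ``sky_emissivity_value``.
    ``substrate_mode`` is "trailing_air_mean" (running 24 h mean of air
    temperature) or "fixed" with ``substrate_temperature`` in degC.
    """

    absorptivity: float = 0.75
    emissivity: float = 0.95
    h_conv_base: float = 5.0  # still-air floor h0, W m-2 K-1
    h_conv_wind_coeff: float = 4.0  # a in h_c = a u^b + h0
    h_conv_wind_exp: float = 0.8  # b
    substrate_conductance: float = 10.0  # g_k, W m-2 K-1
    substrate_mode: str = "trailing_air_mean"
    substrate_temperature: float | None = None  # degC, for substrate_mode="fixed"
    ground_albedo: float = 0.15
    sky_emissivity_mode: str = "swinbank"
    sky_emissivity_value: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.absorptivity <= 1 or not 0 < self.emissivity <= 1:
            raise ValueError("absorptivity and emissivity must be in (0, 1]")
        if min(self.h_conv_base, self.h_conv_wind_coeff, self.substrate_conductance) < 0:
            raise ValueError("convection/conduction coefficients must be non-negative")

    def convection_coefficient(self, wind_speed: float) -> float:
        return self.h_conv_base + self.h_conv_wind_coeff * wind_speed**self.h_conv_wind_exp


@dataclass
class TemperatureField:
    """Per-cell surface temperature (degC) and aerial-exposure mask for one hour."""

    timestamp: pd.Timestamp
    temperature: np.ndarray
    exposure: np.ndarray
    cell_size: float = 1.0

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.temperature)


def exposure_mask(dem: ElevationGrid, tide_level: float) -> np.ndarray:
    """True where a cell stands above the still-water tide level.

    A still-water approximation: no wave runup or splash.
    """
    if not np.isfinite(tide_level):
        raise ValueError("tide level must be finite")
    return dem.values > tide_level


def sky_emissivity(air_temperature_c: float, params: HeatBudgetParams) -> float:
    """Effective clear-sky emissivity (Swinbank correlation or fixed)."""
    if params.sky_emissivity_mode == "fixed":
        return params.sky_emissivity_value
    if params.sky_emissivity_mode == "swinbank":
        t_k = air_temperature_c + KELVIN
        return min(1.0, 9.37e-6 * t_k**2)
    raise ValueError(f"unknown sky emissivity mode {params.sky_emissivity_mode!r}")


def _residual(
    ts_k: np.ndarray,
    incident: np.ndarray,
    svf: np.ndarray,
    ta_k: float,
    tsub_k: float,
    h_c: float,
    eps_sky: float,
    p: HeatBudgetParams,
) -> np.ndarray:
    longwave_in = (
        p.emissivity * STEFAN_BOLTZMANN * (svf * eps_sky * ta_k**4 + (1 - svf) * ta_k**4)
    )
    return (
        p.absorptivity * incident
        + longwave_in
        - p.emissivity * STEFAN_BOLTZMANN * ts_k**4
        - h_c * (ts_k - ta_k)
        - p.substrate_conductance * (ts_k - tsub_k)
    )


def solve_surface_temperature(
    incident: IncidentField,
    weather: WeatherRecord,
    derivatives: TerrainDerivatives,
    params: HeatBudgetParams,
    exposure: np.ndarray,
    substrate_temperature_c: float | None = None,
) -> TemperatureField:
    """Solve the steady-state balance per cell by bracketed bisection.

    The residual is strictly decreasing in T_s (emission, convection and
    conduction all grow with T_s), so bisection on
    [T_a - 30, T_a + 60] K converges unconditionally; it is run to an
    interval width below 0.01 K. Cells where the bracket fails (physically
    unreachable with sane forcing) become NaN.
    """
    if derivatives.svf is None:
        raise ValueError("terrain derivatives incomplete (need svf)")
    ta_k = weather.air_temperature + KELVIN
    if substrate_temperature_c is None:
        if params.substrate_mode == "fixed" and params.substrate_temperature is not None:
            substrate_temperature_c = params.substrate_temperature
        else:
            substrate_temperature_c = weather.air_temperature
    tsub_k = substrate_temperature_c + KELVIN
    h_c = params.convection_coefficient(weather.wind_speed)
    eps_sky = sky_emissivity(weather.air_temperature, params)

    flux = incident.flux
    svf = derivatives.svf
    solvable = exposure & np.isfinite(flux) & np.isfinite(svf)

    lo = np.full(flux.shape, ta_k - 30.0)
    hi = np.full(flux.shape, ta_k + 60.0)
    r_lo = _residual(lo, flux, svf, ta_k, tsub_k, h_c, eps_sky, params)
    r_hi = _residual(hi, flux, svf, ta_k, tsub_k, h_c, eps_sky, params)
    bracketed = solvable & (r_lo >= 0) & (r_hi <= 0)

    # 44 halvings of a 90 K bracket -> interval ~5e-12 K
    for _ in range(44):
        mid = 0.5 * (lo + hi)
        r_mid = _residual(mid, flux, svf, ta_k, tsub_k, h_c, eps_sky, params)
        take_hi = r_mid > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    ts_k = 0.5 * (lo + hi)

    temperature = np.full(flux.shape, np.nan)
    temperature[bracketed] = ts_k[bracketed] - KELVIN
    temperature[exposure & ~bracketed] = np.nan
    temperature[~exposure] = weather.water_temperature
    # submerged nodata cells stay nodata
    temperature[~np.isfinite(derivatives.dem.values)] = np.nan
    return TemperatureField(
        timestamp=weather.timestamp,
        temperature=temperature,
        exposure=exposure,
        cell_size=derivatives.dem.cell_size,
    )


def read_weather_csv(path) -> pd.DataFrame:
    """Hourly weather forcing: timestamp (UTC), air_temperature_C,
    wind_speed_ms, ghi_wm2, water_temperature_C."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df = df.set_index("timestamp")
    if not df.index.is_monotonic_increasing or df.index.has_duplicates:
        raise ValueError("weather timestamps must be strictly increasing")
    return df


def read_tide_csv(path) -> pd.DataFrame:
    """Hourly still-tide level: timestamp (UTC), level_m above datum."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df = df.set_index("timestamp")
    if not df.index.is_monotonic_increasing or df.index.has_duplicates:
        raise ValueError("tide timestamps must be strictly increasing")
    return df


def _trailing_air_mean(weather: pd.DataFrame, when: pd.Timestamp) -> float:
    window = weather.loc[when - pd.Timedelta(hours=23): when, "air_temperature_C"]
    return float(window.mean())


def run_simulation(
    derivatives: TerrainDerivatives,
    weather: pd.DataFrame,
    tide: pd.DataFrame,
    params: HeatBudgetParams,
    latitude: float,
    longitude: float,
    start=None,
    end=None,
) -> list[TemperatureField]:
    """Hourly chain: solar position -> irradiance split -> cast shadows ->
    incident flux -> exposure mask -> heat-budget solve.

    Weather and tide must cover every requested hour exactly; a missing
    record is a hard error (no silent interpolation).
    """
    start = pd.Timestamp(start) if start is not None else weather.index[0]
    end = pd.Timestamp(end) if end is not None else weather.index[-1]
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    if end.tzinfo is None:
        end = end.tz_localize("UTC")
    hours = pd.date_range(start, end, freq="1h", tz="UTC")
    fields: list[TemperatureField] = []
    for when in hours:
        if when not in weather.index:
            raise KeyError(f"no weather record for {when}")
        if when not in tide.index:
            raise KeyError(f"no tide record for {when}")
        row = weather.loc[when]
        rec = WeatherRecord(
            timestamp=when,
            air_temperature=float(row["air_temperature_C"]),
            wind_speed=float(row["wind_speed_ms"]),
            ghi=float(row["ghi_wm2"]),
            water_temperature=float(row["water_temperature_C"]),
        )
        pos = solar_position(when, latitude, longitude)
        comps = partition_direct_diffuse(rec.ghi, pos)
        shadow = cast_shadow_mask(derivatives, pos)
        inc = incident_shortwave(comps, derivatives, pos, params.ground_albedo, shadow=shadow)
        exposed = exposure_mask(derivatives.dem, float(tide.loc[when, "level_m"]))
        tsub = (
            _trailing_air_mean(weather, when)
            if params.substrate_mode == "trailing_air_mean"
            else None
        )
        fields.append(
            solve_surface_temperature(inc, rec, derivatives, params, exposed, tsub)
        )
    return fields
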