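"""Synthetic terrain, weather and tide generators.

No field data ship with the package; every pipeline stage can instead be
driven by these generators, which emulate the study conditions of a
mid-latitude rocky-shore site:

* terrain: analytic surfaces (plane, sinusoid, pit, step wall) for exact
  oracles, and a self-affine Gaussian random field (spectral synthesis,
  power-law spectrum) rescaled to a target RMS roughness Rq — the default
  set-point of 0.96 m matches the roughness scale of a real rocky shore;
* weather: clear-sky diurnal irradiance from the Beer-law curve, a
  sinusoidal air-temperature cycle peaking mid-afternoon, steady or AR(1)
  wind, constant water temperature;
* tide: a single-constituent harmonic with the semidiurnal lunar period
  (12.42 h).

What these deliberately do not emulate: cloud fields, storms, wave runup,
mixed tidal constituents, and spatially correlated weather. All streams
are deterministic under a fixed seed, with independent per-generator
sub-streams so adding one generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import clear_sky_ghi, solar_position
from .terrain import ElevationGrid, surface_roughness_rq

__all__ = ["TerrainSpec", "ForcingSpec", "synthetic_dem", "synthetic_weather", "synthetic_tide"]

TERRAIN_KINDS = ("plane", "sinusoid", "gaussian_field", "pit", "step")


@dataclass(frozen=True)
class TerrainSpec:
    """Recipe for a synthetic DEM."""

    kind: str = "gaussian_field"
    shape: tuple[int, int] = (64, 64)
    cell_size: float = 0.02  # m, 2 cm cells
    amplitude: float = 1.0  # m; sinusoid amplitude, pit depth, step height
    wavelength: float = 0.5  # m, sinusoid
    slope_east: float = 0.0  # plane gradients (dimensionless dz/dx)
    slope_north: float = 0.0
    base_elevation: float = 2.0  # m above datum
    target_rq: float | None = 0.96  # m, gaussian_field set-point
    spectral_exponent: float = -2.0  # self-affine rock-like surfaces
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TERRAIN_KINDS:
            raise ValueError(f"unknown terrain kind {self.kind!r}; choose from {TERRAIN_KINDS}")
        if min(self.shape) < 3:
            raise ValueError("shape must be at least 3x3")


@dataclass(frozen=True)
class ForcingSpec:
    """Recipe for matched synthetic weather and tide series."""

    start: str = "2017-06-22"
    n_days: int = 1
    latitude: float = 42.508
    longitude: float = -70.843
    air_mean: float = 22.0  # degC
    air_amplitude: float = 6.0  # degC diurnal half-range
    transmittance: float = 0.75
    wind_mean: float = 2.0  # m s-1
    wind_ar1: float = 0.0  # 0 -> constant wind; else AR(1) persistence
    water_temperature: float = 16.0  # degC
    tide_amplitude: float = 1.5  # m
    tide_period_h: float = 12.42
    tide_phase: float = 0.0  # radians
    tide_datum_offset: float = 1.5  # m, mean level above datum
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.air_amplitude < 0 or self.tide_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")


def _coords(spec: TerrainSpec) -> tuple[np.ndarray, np.ndarray]:
    nr, nc = spec.shape
    x = np.arange(nc) * spec.cell_size  # east
    y = np.arange(nr)[::-1] * spec.cell_size  # north (row 0 = north edge)
    return np.meshgrid(x, y)


def _gaussian_field(spec: TerrainSpec) -> np.ndarray:
    """Spectral synthesis: white Gaussian noise filtered by |k|^(beta/2)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7E44A1]))
    nr, nc = spec.shape
    noise = rng.standard_normal((nr, nc))
    kr = np.fft.fftfreq(nr)[:, None]
    kc = np.fft.fftfreq(nc)[None, :]
    k = np.hypot(kr, kc)
    k[0, 0] = np.inf  # kill the mean; power-law amplitude elsewhere
    amp = k ** (spec.spectral_exponent / 2.0)
    field = np.real(np.fft.ifft2(np.fft.fft2(noise) * amp))
    return field


def synthetic_dem(spec: TerrainSpec) -> ElevationGrid:
    """Deterministic synthetic elevation grid per the spec's recipe.

    ``gaussian_field`` surfaces are rescaled after synthesis so the
    measured plane-detrended Rq equals ``target_rq`` (residuals scale
    linearly with elevation, so a single rescale lands on the set-point).
    """
    xx, yy = _coords(spec)
    if spec.kind == "plane":
        z = spec.base_elevation + spec.slope_east * xx + spec.slope_north * yy
    elif spec.kind == "sinusoid":
        z = spec.base_elevation + spec.amplitude * np.sin(2 * np.pi * xx / spec.wavelength)
    elif spec.kind == "pit":
        nr, nc = spec.shape
        extent = min(nr, nc) * spec.cell_size
        r = np.hypot(xx - xx.mean(), yy - yy.mean())
        z = spec.base_elevation - spec.amplitude * np.exp(-((r / (extent / 6)) ** 2))
    elif spec.kind == "step":
        # wall occupying the northern half, raised by `amplitude`
        z = np.full(spec.shape, spec.base_elevation)
        z[: spec.shape[0] // 2, :] += spec.amplitude
    else:  # gaussian_field
        z = _gaussian_field(spec)
        dem = ElevationGrid(z, spec.cell_size)
        rq = surface_roughness_rq(dem)
        if spec.target_rq is not None and rq > 0:
            z = z * (spec.target_rq / rq)
        z = z - z.min() + spec.base_elevation
    return ElevationGrid(z, spec.cell_size)


def synthetic_weather(spec: ForcingSpec) -> pd.DataFrame:
    """Hourly weather forcing (UTC-indexed DataFrame).

    Air temperature follows a sinusoid peaking at 15:00 local solar time;
    GHI is the clear-sky Beer-law curve at the site; wind is constant at
    the mean or an AR(1) series around it; water temperature is constant.
    """
    index = pd.date_range(
        pd.Timestamp(spec.start, tz="UTC"), periods=spec.n_days * 24, freq="1h"
    )
    # local solar hour from longitude (15 degrees per hour)
    local_hour = (index.hour + index.minute / 60 + spec.longitude / 15.0) % 24
    air = spec.air_mean + spec.air_amplitude * np.cos(2 * np.pi * (local_hour - 15.0) / 24.0)
    ghi = np.array(
        [clear_sky_ghi(solar_position(t, spec.latitude, spec.longitude), spec.transmittance)
         for t in index]
    )
    if spec.wind_ar1 > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x57D0B2]))
        wind = np.empty(len(index))
        w = spec.wind_mean
        for i in range(len(index)):
            w = spec.wind_mean + spec.wind_ar1 * (w - spec.wind_mean) + 0.3 * rng.standard_normal()
            wind[i] = max(0.0, w)
    else:
        wind = np.full(len(index), spec.wind_mean)
    return pd.DataFrame(
        {
            "air_temperature_C": air,
            "wind_speed_ms": wind,
            "ghi_wm2": ghi,
            "water_temperature_C": np.full(len(index), spec.water_temperature),
        },
        index=pd.DatetimeIndex(index, name="timestamp"),
    )


def synthetic_tide(spec: ForcingSpec) -> pd.DataFrame:
    """Hourly single-constituent harmonic tide (UTC-indexed DataFrame):
    level(t) = datum_offset + amplitude * sin(2 pi t / period + phase)."""
    index = pd.date_range(
        pd.Timestamp(spec.start, tz="UTC"), periods=spec.n_days * 24, freq="1h"
    )
    hours = (index - index[0]).total_seconds() / 3600.0
    level = spec.tide_datum_offset + spec.tide_amplitude * np.sin(
        2 * np.pi * hours / spec.tide_period_h + spec.tide_phase
    )
    return pd.DataFrame({"level_m": level}, index=pd.DatetimeIndex(index, name="timestamp"))
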