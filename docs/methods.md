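# Methods

This note documents the models, numerical choices and limitations behind
thermalscape, in the package's own terms.

## Scope and assumptions

The package maps hourly surface temperature and organismal relative
performance over a fine-scale (centimetre-resolution) digital elevation
model of an intertidal or other sun-driven site, then summarises the
resulting "physiological landscape". Core assumptions:

- Surface (rock) temperature is used as the body temperature of organisms
  with most of their body pressed against the substrate (limpets,
  barnacles, small snails). Organism-specific body models, mobile
  behaviour and energy-budget models are out of scope.
- Each hour is solved at steady state: the substrate has no thermal
  inertia within the hourly step. Slowly varying storage is represented
  only through the substrate boundary temperature (below).
- Submergence is a still-water comparison of cell elevation against the
  tide level — no wave runup, splash or tidepool retention, and no
  evaporative cooling.
- Forcing is spatially uniform over the site (one weather/tide record per
  hour); all spatial structure in temperature comes from topography.

## Terrain derivatives

Slope and aspect use the Horn 3×3 finite-difference kernel, the standard
GIS estimator and robust to grid noise at 2 cm cells. Edge cells and
cells adjacent to nodata are masked rather than extrapolated with
one-sided differences, so the radiation and temperature stages never see
fabricated gradients; on an R×C grid this costs the outer ring of cells.
Aspect is the azimuth of the downslope direction, clockwise from north;
flat cells get aspect 0 by convention.

Horizon angles are computed along `n_directions` equally spaced azimuths
(default 32) by marching each ray outward in steps of one cell size to
`max_radius` (default 5 m), sampling elevations bilinearly; the horizon
angle is the largest elevation angle seen along the ray, floored at 0.
Rays truncate at the grid edge or at nodata, so missing terrain never
raises a horizon. One-cell stepping cannot see obstructions narrower
than a cell; the test suite's independent scalar-loop oracle scans the
same sampling geometry, which is what "equality" means there.

The sky view factor weights each direction by cos²h — the fraction of an
isotropic-radiance sky band left above a horizon at angle h — giving the
familiar limits 1 (open plane) and 0 (fully obstructed) and SVF = 0.5 at
uniform 45° horizons. Both the direction count and radius are exposed as
parameters because the appropriate radius scales with the relief of the
site.

Surface roughness Rq detrends by the least-squares plane before taking
the RMS of residuals. Plane detrending (rather than subtracting the mean
alone) makes Rq invariant to overall site tilt, which is a property of
the shore platform, not of its roughness; mean-only detrending is
available via `detrend="mean"`.

## Solar radiation

Solar position uses the Spencer Fourier-series declination, equation of
time and Earth–sun distance factor plus the standard spherical transform
to zenith/azimuth — accurate to a few hundredths of a degree, far below
the 0.5° needed for hourly forcing. All timestamps are UTC; the CLI
converts local civil times at the boundary.

Global horizontal irradiance is split into direct and diffuse components
with the Erbs piecewise clearness-index correlation (kt = GHI over
extraterrestrial horizontal irradiance; diffuse fraction 1 − 0.09 kt for
kt ≤ 0.22, a quartic for 0.22 < kt ≤ 0.8, 0.165 above). The correlation
coefficients live in module constants so an alternative split can be
substituted. DNI divides by cos θ_z floored at 0.01 to avoid blow-up at
grazing sun.

Per-cell incident shortwave combines three terms: the direct beam
projected on the tilted cell and gated by the cast-shadow mask (a cell is
shadowed when the interpolated horizon angle toward the solar azimuth
meets or exceeds the solar elevation), diffuse sky radiation scaled by
SVF, and ground-reflected radiation GHI·ρ_g·(1 − SVF) with default
ground albedo 0.15 (dark rock). Multi-bounce terrain reflection and
anisotropic diffuse sky models are not included.

The fixtures' clear-sky curve is a Beer-law transmittance model,
GHI = S₀·E·τ^(1/cos θ_z)·cos θ_z with τ = 0.75 by default; at 42.5° N in
late June it peaks near 920 W m⁻², a realistic clear-summer-day value
for a mid-latitude coastal site.

## Surface heat budget

For each exposed cell the steady-state balance equates absorbed
shortwave, incoming longwave (sky longwave ε_sky·σ·T_a⁴ weighted by SVF
plus terrain longwave from surroundings assumed to radiate at air
temperature for the obstructed fraction), emitted longwave ε·σ·T_s⁴,
convection h_c·(T_s − T_a) and substrate conduction g_k·(T_s − T_sub).
Defaults: shortwave absorptivity α = 0.75 and emissivity ε = 0.95 (dark
rock), convection h_c = 5 + 4·u^0.8 W m⁻² K⁻¹ (a still-air floor plus a
wind-speed power law), substrate conductance g_k = 10 W m⁻² K⁻¹, and
substrate temperature equal to the trailing 24-hour mean air temperature
(a cheap proxy for deep-rock thermal mass; a fixed value is available).
Sky emissivity uses the Swinbank clear-sky correlation
ε_sky = 9.37×10⁻⁶·T_a² (T_a in kelvin), overridable with a fixed value —
the analytic check "no sun + ε_sky = 1 ⇒ T_s = T_a" uses the override.
No cloud correction is applied to ε_sky because the forcing GHI already
carries cloud attenuation.

The residual is strictly decreasing in T_s, so a vectorised bisection on
[T_a − 30 K, T_a + 60 K] converges unconditionally; 44 halvings leave an
interval ~5×10⁻¹² K, and the residual at the returned root is orders of
magnitude below the 0.1 W m⁻² documentation threshold. Cells whose
root falls outside the bracket (unreachable under sane forcing) are
reported as nodata rather than clamped.

## Performance curves and categories

The TPC is the asymmetric left-Gaussian / right-quadratic form common in
thermal ecology: P = exp(−((T − T_opt)/(2σ))²) below the optimum and
P = 1 − ((T − T_opt)/(T_opt − T_lethal))² between optimum and lethal
limit, zero at and above the limit. σ defaults to 7 °C so the suboptimal
ascent is broad. The packaged generic intertidal preset (T_opt 28 °C,
lethal 35 °C, breakpoints 21.2/30.1 °C) anchors the category maps; the
"predator" preset shifts the whole curve 3 °C cooler (T_opt 25 °C,
lethal 32 °C) to represent a dominant species with a lower thermal
limit. Categories are assigned by temperature interval (left-closed,
right-open; lethal strictly above the limit), deliberately independent
of the curve shape so category maps survive a change of σ.

For the two-species interaction map, "favourable" defaults to
*persistence* — any non-lethal temperature — so a 33 °C cell with a
32 °C-limited predator and a 35 °C-limited prey classifies as a
prey-only refugium: the prey endures (sublethally) where the predator
cannot survive. The stricter criterion restricting favourability to the
suboptimal/optimal bands is available via `favourability="performance"`.

## Landscape metrics

RqT and RqP are RMS deviations from the spatial mean at one timestamp,
computed over exposed cells only by default (maps blank submerged cells);
no plane detrending is applied to temperature because, unlike elevation,
a site-scale temperature tilt is signal, not datum. Refugia use a strict
`<` threshold; an optional minimum-patch-size filter (4-connected
components) approximates body-size-aware refugia and defaults off.
Histograms use half-open bins throughout, so counts conserve the exposed
cell total whenever the edges cover the data range.

## Synthetic data

The terrain generator's `gaussian_field` uses spectral synthesis: white
Gaussian noise filtered to a power-law amplitude spectrum (exponent −2,
self-affine and rock-like), then rescaled so the measured plane-detrended
Rq equals the set-point exactly (residuals scale linearly with
elevation). The default set-point, 0.96 m, places synthetic shores at
the roughness scale of a real rocky-shore survey site; the default
forcing is one clear June day at 42.5° N with a 12.42 h harmonic tide.
Generators draw from independent seeded sub-streams, so adding one never
perturbs another.

What the synthetic conditions do *not* contain: clouds and weather
fronts, spatially varying wind, mixed tidal constituents, wet surfaces
and evaporation, and biological cover. Passing tests therefore
demonstrate the internal consistency and qualitative behaviour of the
chain (e.g. ≥ 10 °C sun/shade contrast on a rugged shore at noon), not
site-specific predictive skill, which would require validation against
logger data.

## Problem sizes and determinism

The shipped examples and the acceptance script use 64×64 grids at 2 cm
cells with 32 search directions and a 5 m radius — large enough for the
full relief of the synthetic shore to shade itself, small enough that
the whole chain runs in seconds. The hourly pipeline is deterministic
given the configuration: metrics tables from identical runs are
byte-identical, and every artifact carries a hash of the effective
configuration.

## Known limitations

- The outer ring of cells carries no slope/aspect and is excluded from
  temperature maps.
- Horizon sampling at one-cell steps underestimates horizons from
  sub-cell features.
- The heat budget ignores evaporation; immediately after emersion a wet
  rock surface will be cooler than modelled.
- Steady-state hourly solutions overshoot short-lived peaks on substrates
  with high thermal mass.
- The still-water exposure mask misclassifies splash-zone cells during
  heavy seas.
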