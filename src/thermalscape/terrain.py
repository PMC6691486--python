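"""Elevation grids and terrain derivatives.

The physical substrate of the model is a square-celled digital elevation
model (DEM) of a rocky shore, with elevations in metres above a tidal datum
(typically mean lower low water, MLLW). From it we derive the per-cell
quantities that control how much solar radiation each microsite receives:

* slope and aspect (surface orientation),
* horizon angles along a fan of azimuthal search directions, and
* the sky view factor (SVF), the fraction of the sky hemisphere visible
  from the cell — 0 fully obstructed, 1 fully open.

Grids are stored row 0 = northern edge, with NaN marking nodata cells
(e.g. permanently submerged areas). I/O uses ESRI-style ASCII grids so
fixtures and pipeline stages round-trip through plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ElevationGrid",
    "TerrainDerivatives",
    "read_dem",
    "write_dem",
    "compute_slope_aspect",
    "compute_horizon_angles",
    "compute_svf",
    "surface_roughness_rq",
    "compute_derivatives",
]


@dataclass
class ElevationGrid:
    """Square-celled raster of elevations (m above datum).

    Parameters
    ----------
    values
        2-D float array, NaN where no elevation exists. Row 0 is the
        northern edge.
    cell_size
        Cell edge length in metres (> 0).
    origin
        (easting, northing) of the north-west cell corner, metres.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("elevation grid must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if not np.isfinite(self.values).any():
            raise ValueError("grid contains no valid elevation cells")

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean grid, True where no elevation exists."""
        return ~np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.values).sum())


@dataclass
class TerrainDerivatives:
    """Per-cell topographic drivers of the radiation model.

    ``slope`` and ``aspect`` are degrees ([0, 90] and [0, 360) clockwise
    from north of the downslope direction); ``horizon_angles`` has shape
    (n_directions, rows, cols) with elevation angles of the local horizon
    in degrees; ``svf`` is the sky view factor in [0, 1].
    """

    dem: ElevationGrid
    slope: np.ndarray | None = None
    aspect: np.ndarray | None = None
    horizon_angles: np.ndarray | None = None
    svf: np.ndarray | None = None
    n_directions: int = 32
    max_radius: float = 5.0
    azimuths: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.azimuths is None:
            self.azimuths = np.arange(self.n_directions) * (360.0 / self.n_directions)


def read_dem(path: str | Path) -> ElevationGrid:
    """Read an ESRI-style ASCII grid into an :class:`ElevationGrid`.

    The header must declare ``ncols``, ``nrows``, ``xllcorner``,
    ``yllcorner``, ``cellsize`` and optionally ``NODATA_value``.
    Non-square cells (separate dx/dy keys) are rejected.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    if "dx" in header or "dy" in header:
        if header.get("dx") != header.get("dy"):
            raise ValueError("non-square cells are not supported")
        header["cellsize"] = header["dx"]
    required = {"ncols", "nrows", "cellsize"}
    if not required <= set(header):
        raise ValueError(f"ASCII grid header missing keys {required - set(header)}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = np.loadtxt(lines[n_header:], dtype=float).reshape(nrows, ncols)
    if "nodata_value" in header:
        values[values == header["nodata_value"]] = np.nan
    cell = header["cellsize"]
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    # file origin is the lower-left corner; ours is the north-west corner
    return ElevationGrid(values, cell, origin=(xll, yll + nrows * cell))


def write_dem(dem: ElevationGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write an ElevationGrid as an ESRI-style ASCII grid."""
    nrows, ncols = dem.shape
    xll = dem.origin[0]
    yll = dem.origin[1] - nrows * dem.cell_size
    out = np.where(np.isfinite(dem.values), dem.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {dem.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, out, fmt="%.9g")


def compute_slope_aspect(dem: ElevationGrid) -> TerrainDerivatives:
    """Slope and aspect from a Horn 3x3 finite-difference kernel.

    Edge cells and cells with any nodata neighbour are masked (NaN) rather
    than extrapolated, so downstream radiation never sees one-sided
    gradients. Flat cells get aspect 0 by convention.
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("slope/aspect requires at least a 3x3 grid")
    z = dem.values
    c = dem.cell_size
    # 3x3 neighbourhood: rows south-positive in array space, north-positive physically
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; cc = z[:-2, 2:]
    d = z[1:-1, :-2]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    dzdx = ((cc + 2 * f + i) - (a + 2 * d + g)) / (8 * c)        # east gradient
    dzdy = ((a + 2 * b + cc) - (g + 2 * h + i)) / (8 * c)        # north gradient
    slope_i = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downslope direction = -grad z, azimuth clockwise from north
    aspect_i = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect_i = np.where(slope_i == 0.0, 0.0, aspect_i)

    slope = np.full(dem.shape, np.nan)
    aspect = np.full(dem.shape, np.nan)
    slope[1:-1, 1:-1] = slope_i
    aspect[1:-1, 1:-1] = aspect_i
    return TerrainDerivatives(dem=dem, slope=slope, aspect=aspect)


def _bilinear(z: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear sample of ``z`` at fractional (row, col); NaN outside or
    when any contributing corner is nodata."""
    nr, nc = z.shape
    out = np.full(rows.shape, np.nan)
    inside = (rows >= 0) & (rows <= nr - 1) & (cols >= 0) & (cols <= nc - 1)
    r = np.clip(rows, 0, nr - 1)
    cidx = np.clip(cols, 0, nc - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(cidx).astype(int)
    r1 = np.minimum(r0 + 1, nr - 1)
    c1 = np.minimum(c0 + 1, nc - 1)
    fr = r - r0
    fc = cidx - c0
    val = (
        z[r0, c0] * (1 - fr) * (1 - fc)
        + z[r0, c1] * (1 - fr) * fc
        + z[r1, c0] * fr * (1 - fc)
        + z[r1, c1] * fr * fc
    )
    out[inside] = val[inside]
    return out


def compute_horizon_angles(
    dem: ElevationGrid,
    n_directions: int = 32,
    max_radius: float = 5.0,
    derivatives: TerrainDerivatives | None = None,
) -> TerrainDerivatives:
    """Horizon elevation angles along ``n_directions`` equally spaced azimuths.

    For each cell and azimuth the ray is marched outward in steps of one
    cell size to ``max_radius``, sampling elevations bilinearly; the horizon
    angle is the maximum of atan((z_sample - z_cell)/distance) over the
    traversed points, floored at 0. Rays truncate where they leave the grid
    or meet nodata, so such points simply do not raise the horizon.
    """
    if n_directions < 4:
        raise ValueError("n_directions must be >= 4")
    if max_radius < dem.cell_size:
        raise ValueError("max_radius must be at least one cell size")
    z = dem.values
    nr, nc = dem.shape
    rows0, cols0 = np.meshgrid(np.arange(nr, dtype=float), np.arange(nc, dtype=float), indexing="ij")
    azimuths = np.arange(n_directions) * (360.0 / n_directions)
    n_steps = max(1, int(np.floor(max_radius / dem.cell_size)))
    horizon = np.zeros((n_directions, nr, nc))
    valid = np.isfinite(z)
    for k, az in enumerate(azimuths):
        az_r = np.radians(az)
        # azimuth clockwise from north: north decreases the row index
        dr = -np.cos(az_r)
        dc = np.sin(az_r)
        hmax = np.zeros((nr, nc))
        for s in range(1, n_steps + 1):
            dist = s * dem.cell_size
            zs = _bilinear(z, rows0 + s * dr, cols0 + s * dc)
            ang = np.degrees(np.arctan((zs - z) / dist))
            hmax = np.fmax(hmax, ang)  # fmax ignores NaN samples
        horizon[k] = np.where(valid, np.clip(hmax, 0.0, 90.0), np.nan)
    if derivatives is None:
        derivatives = TerrainDerivatives(dem=dem, n_directions=n_directions, max_radius=max_radius)
    derivatives.horizon_angles = horizon
    derivatives.n_directions = n_directions
    derivatives.max_radius = max_radius
    derivatives.azimuths = azimuths
    return derivatives


def compute_svf(derivatives: TerrainDerivatives) -> TerrainDerivatives:
    """Sky view factor from horizon angles: SVF = mean_i cos^2(h_i).

    The cos^2 weighting corresponds to an isotropic-radiance sky: a
    direction whose horizon stands at angle h loses the sky band below h.
    All-zero horizons give SVF 1 (fully open); all-90 gives 0.
    """
    if derivatives.horizon_angles is None:
        raise ValueError("horizon angles must be computed first")
    h = np.radians(derivatives.horizon_angles)
    derivatives.svf = np.mean(np.cos(h) ** 2, axis=0)
    return derivatives


def compute_derivatives(
    dem: ElevationGrid, n_directions: int = 32, max_radius: float = 5.0
) -> TerrainDerivatives:
    """Convenience: slope/aspect + horizon angles + SVF in one pass."""
    deriv = compute_slope_aspect(dem)
    deriv = compute_horizon_angles(dem, n_directions, max_radius, derivatives=deriv)
    return compute_svf(deriv)


def surface_roughness_rq(dem: ElevationGrid, detrend: str = "plane") -> float:
    """RMS surface roughness Rq (m): root mean square of elevation
    deviations from the best-fit plane (``detrend='plane'``) or from the
    mean elevation (``detrend='mean'``).
    """
    valid = np.isfinite(dem.values)
    zv = dem.values[valid]
    if zv.size < 3:
        raise ValueError("Rq requires at least 3 valid cells")
    if detrend == "mean":
        resid = zv - zv.mean()
    elif detrend == "plane":
        rows, cols = np.nonzero(valid)
        x = cols * dem.cell_size
        y = rows * dem.cell_size
        A = np.column_stack([x, y, np.ones_like(x)])
        if np.linalg.matrix_rank(A) < 3:
            raise ValueError("degenerate (collinear) cell set")
        coef, *_ = np.linalg.lstsq(A, zv, rcond=None)
        resid = zv - A @ coef
    else:
        raise ValueError(f"unknown detrend mode {detrend!r}")
    return float(np.sqrt(np.mean(resid**2)))
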