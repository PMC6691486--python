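"""Terrain derivatives: slope/aspect, horizon angles, SVF and Rq roughness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermalscape.fixtures import TerrainSpec, synthetic_dem
from thermalscape.terrain import (
    ElevationGrid,
    compute_horizon_angles,
    compute_slope_aspect,
    compute_svf,
    read_dem,
    surface_roughness_rq,
    write_dem,
)


def brute_force_horizon(dem: ElevationGrid, n_directions: int, max_radius: float) -> np.ndarray:
    """Independent oracle: exhaustive per-cell scalar-loop ray scan over the
    same one-cell sampling geometry as the vectorised implementation."""
    z = dem.values
    nr, nc = z.shape
    out = np.zeros((n_directions, nr, nc))
    n_steps = int(np.floor(max_radius / dem.cell_size))
    for k in range(n_directions):
        az = np.radians(k * 360.0 / n_directions)
        dr, dc = -np.cos(az), np.sin(az)
        for r in range(nr):
            for c in range(nc):
                best = 0.0
                for s in range(1, n_steps + 1):
                    rr = r + dr * s
                    cc = c + dc * s
                    if rr < 0 or rr > nr - 1 or cc < 0 or cc > nc - 1:
                        continue
                    r0, c0 = int(rr), int(cc)
                    r1, c1 = min(r0 + 1, nr - 1), min(c0 + 1, nc - 1)
                    fr, fc = rr - r0, cc - c0
                    zs = (z[r0, c0] * (1 - fr) * (1 - fc) + z[r0, c1] * (1 - fr) * fc
                          + z[r1, c0] * fr * (1 - fc) + z[r1, c1] * fr * fc)
                    best = max(best, np.degrees(np.arctan((zs - z[r, c]) / (s * dem.cell_size))))
                out[k, r, c] = min(best, 90.0)
    return out


class TestIO:
    def test_ascii_identity_readback(self, tmp_path):
        path = tmp_path / "flat.asc"
        path.write_text(
            "ncols 3\nnrows 3\nxllcorner 0\nyllcorner 0\ncellsize 0.02\n"
            "NODATA_value -9999\n" + ("1.0 1.0 1.0\n" * 3)
        )
        dem = read_dem(path)
        assert dem.n_valid == 9
        assert dem.cell_size == 0.02
        assert np.all(dem.values == 1.0)

    def test_nodata_cell_masked(self, tmp_path):
        path = tmp_path / "hole.asc"
        path.write_text(
            "ncols 3\nnrows 3\nxllcorner 0\nyllcorner 0\ncellsize 0.02\n"
            "NODATA_value -9999\n1 1 1\n1 -9999 1\n1 1 1\n"
        )
        dem = read_dem(path)
        assert dem.n_valid == 8
        assert dem.nodata_mask[1, 1]

    def test_round_trip(self, tmp_path, random_dem):
        write_dem(random_dem, tmp_path / "r.asc")
        back = read_dem(tmp_path / "r.asc")
        np.testing.assert_allclose(back.values, random_dem.values, rtol=1e-6)
        assert back.cell_size == random_dem.cell_size

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError):
            ElevationGrid(np.full((3, 3), np.nan), 0.02)


class TestSlopeAspect:
    def test_horizontal_plane_slope_zero(self, flat_dem):
        d = compute_slope_aspect(flat_dem)
        assert np.nanmax(d.slope) == 0.0
        assert np.nanmax(d.aspect) == 0.0  # flat convention

    @pytest.mark.parametrize(
        "east,north,exp_slope,exp_aspect",
        [
            (0.0, -0.1, np.degrees(np.arctan(0.1)), 0.0),  # descends northward
            (-1.0, 0.0, 45.0, 90.0),  # descends eastward at unit gradient
            (0.0, 0.1, np.degrees(np.arctan(0.1)), 180.0),
        ],
    )
    def test_analytic_planes(self, east, north, exp_slope, exp_aspect):
        dem = synthetic_dem(TerrainSpec(kind="plane", shape=(9, 9), slope_east=east,
                                        slope_north=north, target_rq=None))
        d = compute_slope_aspect(dem)
        interior = np.isfinite(d.slope)
        assert np.allclose(d.slope[interior], exp_slope, atol=0.01)
        assert np.allclose(d.aspect[interior], exp_aspect, atol=0.01)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            compute_slope_aspect(ElevationGrid(np.ones((2, 5)), 1.0))

    def test_edges_masked(self, flat_dem):
        d = compute_slope_aspect(flat_dem)
        assert np.isnan(d.slope[0]).all() and np.isnan(d.slope[-1]).all()


class TestHorizon:
    def test_flat_plane_zero_horizon(self, flat_dem):
        d = compute_horizon_angles(flat_dem, n_directions=8, max_radius=0.1)
        assert np.nanmax(d.horizon_angles) == 0.0

    def test_wall_geometry(self):
        # wall of height h in the northern half; cell at distance d sees atan(h/d)
        h = 1.0
        dem = synthetic_dem(TerrainSpec(kind="step", shape=(20, 20), cell_size=0.1,
                                        amplitude=h, target_rq=None))
        d = compute_horizon_angles(dem, n_directions=4, max_radius=2.0)
        north = d.horizon_angles[0]  # direction 0 = toward north
        row, col = 12, 10  # 3 cells south of the wall foot (wall rows 0-9)
        dist = (row - 9) * 0.1
        expected = np.degrees(np.arctan(h / dist))
        assert abs(north[row, col] - expected) < 1.0

    def test_matches_brute_force(self, random_dem):
        n, radius = 8, 0.12
        d = compute_horizon_angles(random_dem, n_directions=n, max_radius=radius)
        oracle = brute_force_horizon(random_dem, n, radius)
        assert np.nanmax(np.abs(d.horizon_angles - oracle)) < 1e-9


class TestSVF:
    def _deriv_with_horizons(self, angles: np.ndarray):
        from thermalscape.terrain import TerrainDerivatives
        dem = ElevationGrid(np.ones((3, 3)), 1.0)
        d = TerrainDerivatives(dem=dem, n_directions=angles.shape[0])
        d.horizon_angles = angles
        return d

    @pytest.mark.parametrize(
        "angle,expected",
        [(0.0, 1.0), (90.0, 0.0), (45.0, 0.5)],
    )
    def test_uniform_horizons_closed_form(self, angle, expected):
        d = self._deriv_with_horizons(np.full((8, 3, 3), angle))
        svf = compute_svf(d).svf
        assert np.allclose(svf, expected, atol=1e-12)

    def test_half_open_half_blocked(self):
        angles = np.zeros((8, 3, 3))
        angles[:4] = 90.0
        svf = compute_svf(self._deriv_with_horizons(angles)).svf
        assert np.allclose(svf, 0.5)

    def test_plane_interior_svf_one(self, flat_dem):
        d = compute_horizon_angles(flat_dem, n_directions=8, max_radius=0.1)
        svf = compute_svf(d).svf
        assert np.allclose(svf, 1.0)

    @given(st.lists(st.floats(0, 90), min_size=8, max_size=8),
           st.integers(0, 7), st.floats(0.1, 45))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_horizon_angle(self, angles, idx, bump):
        base = np.array(angles).reshape(8, 1, 1)
        d1 = self._deriv_with_horizons(np.broadcast_to(base, (8, 3, 3)).copy())
        raised = base.copy()
        raised[idx] = min(90.0, raised[idx, 0, 0] + bump)
        d2 = self._deriv_with_horizons(np.broadcast_to(raised, (8, 3, 3)).copy())
        s1 = compute_svf(d1).svf[0, 0]
        s2 = compute_svf(d2).svf[0, 0]
        assert s2 <= s1 + 1e-12
        assert 0.0 <= s1 <= 1.0 and 0.0 <= s2 <= 1.0


class TestRq:
    def test_any_plane_rq_zero(self):
        dem = synthetic_dem(TerrainSpec(kind="plane", shape=(16, 16), slope_east=0.3,
                                        slope_north=-0.2, target_rq=None))
        assert surface_roughness_rq(dem) < 1e-12

    def test_sinusoid_closed_form(self):
        amp, wavelength, cell = 0.5, 0.5, 0.01
        dem = synthetic_dem(TerrainSpec(kind="sinusoid", shape=(8, 400), cell_size=cell,
                                        amplitude=amp, wavelength=wavelength, target_rq=None))
        assert abs(surface_roughness_rq(dem) - amp / np.sqrt(2)) < 0.01 * amp

    def test_matches_direct_residuals(self):
        rng = np.random.default_rng(7)
        z = rng.normal(0, 0.3, size=(20, 20))
        dem = ElevationGrid(z, 0.05)
        rows, cols = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        A = np.column_stack([cols.ravel() * 0.05, rows.ravel() * 0.05, np.ones(400)])
        resid = z.ravel() - A @ np.linalg.lstsq(A, z.ravel(), rcond=None)[0]
        assert np.isclose(surface_roughness_rq(dem), np.sqrt(np.mean(resid**2)))

    @given(st.floats(-5, 5), st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    @settings(deadline=None, max_examples=30)
    def test_invariant_to_offset_and_tilt(self, offset, gx, gy):
        rng = np.random.default_rng(11)
        z = rng.normal(0, 0.2, size=(15, 15))
        xx, yy = np.meshgrid(np.arange(15) * 0.1, np.arange(15) * 0.1)
        base = surface_roughness_rq(ElevationGrid(z, 0.1))
        tilted = surface_roughness_rq(ElevationGrid(z + offset + gx * xx + gy * yy, 0.1))
        assert np.isclose(base, tilted, atol=1e-9)

    def test_degenerate_collinear_rejected(self):
        z = np.full((1, 5), 1.0)  # one row: collinear support
        with pytest.raises(ValueError):
            surface_roughness_rq(ElevationGrid(z, 1.0))
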