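"""Post-processing oracles: WSS closed forms, brute-force medians, tear
fluxes, recirculation counts and peak-velocity search."""

import numpy as np
import pytest

import dissectflow as df
from dissectflow.grid import channel_grid, rasterize
from dissectflow.post import (AbsentTearError, cell_speeds,
                              peak_velocity_location, pressure_difference,
                              recirculation_extent, regional_summary,
                              tear_flux, wall_shear_stress)
from dissectflow.solver import MM, FlowField, FluidProperties


def _zero_field(grid):
    return FlowField(0.0, np.zeros((grid.nx + 1, grid.ny)),
                     np.zeros((grid.nx, grid.ny + 1)),
                     np.zeros((grid.nx, grid.ny)))


def _parabolic_channel(spacing, u_mean=0.2, width=20.0):
    grid = channel_grid(60.0, width, spacing)
    fld = _zero_field(grid)
    w = width * MM
    y = grid.y_centers * MM
    fld.u[:] = (6 * u_mean / w**2 * y * (w - y))[np.newaxis, :]
    return grid, fld


class TestWallShearStress:
    def test_poiseuille_closed_form(self):
        # wall WSS = 6 mu U_mean / w = 6 * 0.00371 * 0.2 / 0.02 = 0.2226 Pa
        grid, fld = _parabolic_channel(0.5)
        wss = wall_shear_stress(fld, grid, FluidProperties())
        walls = wss[wss.reliable & wss.orientation.isin(["bottom", "top"])]
        assert len(walls) > 0
        np.testing.assert_allclose(walls.wss_pa, 0.2226, rtol=1e-10)

    def test_zero_field_gives_zero_wss(self):
        grid = rasterize(df.make_case(2), 1.0)
        wss = wall_shear_stress(_zero_field(grid), grid, FluidProperties())
        assert (wss[wss.reliable].wss_pa == 0).all()

    def test_quadratic_fit_error_falls_fourfold_per_refinement(self):
        # a sinusoidal profile is not in the fit space, so the one-sided
        # quadratic derivative has a genuine O(h^2) error
        mu = 0.00371
        errs = []
        for spacing in (1.0, 0.5):
            grid = channel_grid(60.0, 20.0, spacing)
            fld = _zero_field(grid)
            w = 0.02
            y = grid.y_centers * MM
            fld.u[:] = np.sin(np.pi * y / w)[np.newaxis, :]
            exact = mu * np.pi / w
            wss = wall_shear_stress(fld, grid, FluidProperties())
            got = wss[wss.reliable & (wss.orientation == "bottom")].wss_pa
            errs.append(abs(got.iloc[0] - exact))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.1)


class TestRegionalSummary:
    def test_constant_pressure_reported_in_kpa(self, fluid):
        grid = rasterize(df.make_case(5), 1.0)
        fld = _zero_field(grid)
        fld.p[:] = 1000.0
        out = regional_summary(fld, grid, grid.geom, "systole", fluid)
        assert len(out) == 12
        np.testing.assert_allclose(out.pressure_median_kpa, 1.0)

    def test_row_count_always_twelve(self, fluid):
        for cid in (1, 11):
            grid = rasterize(df.make_case(cid), 2.0)
            out = regional_summary(_zero_field(grid), grid, grid.geom,
                                   "diastole", fluid)
            assert sorted(out.region.unique()) == [1, 2, 3, 4, 5, 6]
            assert len(out) == 12

    def test_median_matches_sorted_brute_force(self, fluid):
        grid = rasterize(df.make_case(5), 2.0)
        fld = _zero_field(grid)
        rng = np.random.default_rng(3)
        fld.p[:] = rng.uniform(9.0e3, 17.0e3, fld.p.shape)
        out = regional_summary(fld, grid, grid.geom, "systole", fluid)
        from dissectflow.post import _region_ids
        regions = _region_ids(grid, grid.geom)
        for _, row in out.iterrows():
            code = 1 if row.lumen == "true" else 2
            vals = [fld.p[i, j]
                    for i in range(grid.nx) for j in range(grid.ny)
                    if grid.fluid[i, j] and grid.lumen_label[i, j] == code
                    and regions[i] == row.region]
            if not vals:
                assert np.isnan(row.pressure_median_kpa)
                continue
            vals.sort()
            n = len(vals)
            med = (vals[n // 2] if n % 2 else
                   0.5 * (vals[n // 2 - 1] + vals[n // 2]))
            assert row.pressure_median_kpa == pytest.approx(med / 1e3,
                                                            rel=1e-12)

    def test_wss_max_at_least_median(self, fluid, case2_run):
        snap = case2_run.snapshots[0]
        out = regional_summary(snap, case2_run.grid, case2_run.geom,
                               "systole", fluid)
        ok = out.dropna(subset=["wss_median_pa", "wss_max_pa"])
        assert (ok.wss_max_pa >= ok.wss_median_pa).all()


class TestPressureDifference:
    def test_subtraction_and_gap(self, fluid):
        grid = rasterize(df.make_case(5), 2.0)
        fld = _zero_field(grid)
        # true lumen at 16.3 kPa, false lumen at 16.0 kPa
        y = grid.y_centers
        tl = y < grid.geom.true_lumen_width
        fld.p[:, tl] = 16.3e3
        fld.p[:, ~tl] = 16.0e3
        out = regional_summary(fld, grid, grid.geom, "systole", fluid)
        per_region, gap = pressure_difference(out)
        np.testing.assert_allclose(per_region.tl_minus_fl_kpa, 0.3)
        assert gap == pytest.approx(0.0, abs=1e-12)

    def test_identical_lumens_give_zero(self, fluid):
        grid = rasterize(df.make_case(5), 2.0)
        fld = _zero_field(grid)
        fld.p[:] = 12.0e3
        out = regional_summary(fld, grid, grid.geom, "systole", fluid)
        per_region, _ = pressure_difference(out)
        np.testing.assert_allclose(per_region.tl_minus_fl_kpa, 0.0)


class TestTearFlux:
    def test_stagnant_field_zero(self):
        grid = rasterize(df.make_case(5), 1.0)
        assert tear_flux(_zero_field(grid), grid, grid.geom, "entry") == 0.0

    def test_uniform_crossflow_equals_speed_times_width(self):
        # 0.1 m/s downward through the 6.4 mm entry tear -> 6.4e-4 m^2/s
        # FL->TL; 0.8 mm spacing makes the discrete tear width exactly 6.4 mm
        grid = rasterize(df.make_case(5), 0.8)
        fld = _zero_field(grid)
        fld.v[:] = -0.1
        assert tear_flux(fld, grid, grid.geom, "entry") == pytest.approx(
            6.4e-4, rel=1e-12)

    def test_sign_flips_with_velocity(self):
        grid = rasterize(df.make_case(5), 1.0)
        fld = _zero_field(grid)
        rng = np.random.default_rng(5)
        fld.v[:] = rng.standard_normal(fld.v.shape)
        a = tear_flux(fld, grid, grid.geom, "re_entry")
        fld.v *= -1
        assert tear_flux(fld, grid, grid.geom, "re_entry") == pytest.approx(
            -a, rel=1e-12)

    def test_absent_tear_raises(self):
        grid = rasterize(df.make_case(1), 1.0)
        with pytest.raises(AbsentTearError):
            tear_flux(_zero_field(grid), grid, grid.geom, "re_entry")

    def test_sealed_false_lumen_balances_tear_fluxes(self, case2_run):
        """Rigid sealed FL: entry flux must equal minus the re-entry flux."""
        for snap in case2_run.snapshots:
            e = tear_flux(snap, case2_run.grid, case2_run.geom, "entry")
            r = tear_flux(snap, case2_run.grid, case2_run.geom, "re_entry")
            assert e + r == pytest.approx(0.0, abs=1e-12)


class TestRecirculation:
    def test_uniform_forward_flow_gives_zero(self):
        grid = rasterize(df.make_case(5), 1.0)
        fld = _zero_field(grid)
        fld.u[:] = 0.5
        m = recirculation_extent(fld, grid, grid.geom)
        assert m.area_fraction_reversed == 0.0

    def test_uniformly_reversed_zone_gives_one(self):
        grid = rasterize(df.make_case(5), 1.0)
        fld = _zero_field(grid)
        fld.u[:] = -0.5
        m = recirculation_extent(fld, grid, grid.geom)
        assert m.area_fraction_reversed == 1.0
        assert m.reversed_area_mm2 == m.zone_area_mm2

    def test_vortex_fraction_matches_direct_count(self):
        """Solid-body vortex centered in the sub-tear zone: the metric must
        equal an explicit per-cell count."""
        geom = df.make_case(8)
        grid = rasterize(geom, 1.0)
        fld = _zero_field(grid)
        span = geom.re_entry_span
        x_edge = geom.dissection_start + span[1]
        xc = (x_edge + geom.dissection_end) / 2
        yc = geom.true_lumen_width + geom.septum_thickness \
            + geom.false_lumen_short_axis / 2
        X = grid.x_centers  # u-face x positions differ; use face coordinates
        for i in range(grid.nx + 1):
            for j in range(grid.ny):
                fld.u[i, j] = -0.02 * ((grid.y_centers[j] - yc))
        m = recirculation_extent(fld, grid, geom, threshold=0.01,
                                 reference_speed=1.0)
        uc = 0.5 * (fld.u[:-1] + fld.u[1:])
        count = 0
        total = 0
        for i in range(grid.nx):
            for j in range(grid.ny):
                if (grid.lumen_label[i, j] == 2
                        and grid.y_centers[j] >= geom.true_lumen_width
                        + geom.septum_thickness
                        and grid.x_centers[i] > x_edge):
                    total += 1
                    if uc[i, j] < -0.01:
                        count += 1
        assert m.area_fraction_reversed == pytest.approx(count / total)
        assert m.zone_area_mm2 == pytest.approx(total * grid.spacing**2)


class TestPeakVelocity:
    def test_single_nonzero_cell_is_found(self):
        geom = df.make_case(5)
        grid = rasterize(geom, 1.0)
        fld = _zero_field(grid)
        # one fast cell in the false lumen, third region
        x_target = geom.dissection_start + 100.0
        i = int(np.searchsorted(grid.x_centers, x_target))
        j = grid.ny - 3
        assert grid.lumen_label[i, j] == 2
        fld.u[i, j] = fld.u[i + 1, j] = 1.5
        speed, region, label = peak_velocity_location(fld, grid, geom)
        assert speed == pytest.approx(1.5)
        assert region == 3
        assert label == "false_lumen"

    def test_matches_brute_force_argmax(self, fluid, case2_run):
        snap = case2_run.snapshots[0]
        grid, geom = case2_run.grid, case2_run.geom
        speed, _, _ = peak_velocity_location(snap, grid, geom)
        speeds = cell_speeds(snap)
        best = max(speeds[i, j]
                   for i in range(grid.nx) for j in range(grid.ny)
                   if grid.fluid[i, j])
        assert speed == pytest.approx(best, rel=0, abs=0)

    def test_tie_breaks_to_lowest_region_true_lumen(self):
        geom = df.make_case(5)
        grid = rasterize(geom, 1.0)
        fld = _zero_field(grid)
        i_r5 = int(np.searchsorted(grid.x_centers,
                                   geom.dissection_start + 170.0))
        i_r2 = int(np.searchsorted(grid.x_centers,
                                   geom.dissection_start + 50.0))
        fld.u[i_r5, 5] = fld.u[i_r5 + 1, 5] = 2.0   # true lumen, region 5
        fld.u[i_r2, 5] = fld.u[i_r2 + 1, 5] = 2.0   # true lumen, region 2
        _, region, label = peak_velocity_location(fld, grid, geom)
        assert region == 2
        assert label == "true_lumen"
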