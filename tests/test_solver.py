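"""Solver unit tests: time-step arithmetic, Reynolds estimate, fixed
points, projection accuracy, no-slip and determinism."""

import numpy as np
import pytest

import dissectflow as df
from dissectflow.benchmarks import Constant
from dissectflow.grid import channel_grid, rasterize
from dissectflow.solver import (BoundaryConditions, FlowField,
                                FluidProperties, Numerics, StaggeredSolver,
                                cfl_timestep, max_reynolds)


def _zero_field(grid):
    return FlowField(0.0, np.zeros((grid.nx + 1, grid.ny)),
                     np.zeros((grid.nx, grid.ny + 1)),
                     np.zeros((grid.nx, grid.ny)))


class TestCflTimestep:
    def test_arithmetic(self):
        grid = channel_grid(60.0, 20.0, 1.0)
        fld = _zero_field(grid)
        fld.u[5, 5] = 1.0
        assert cfl_timestep(fld, grid, safety=0.5) == pytest.approx(5.0e-4)

    def test_zero_field_hits_cap(self):
        grid = channel_grid(60.0, 20.0, 1.0)
        assert cfl_timestep(_zero_field(grid), grid) == pytest.approx(1.0e-3)

    def test_spacing_linearity_below_cap(self):
        fine = channel_grid(60.0, 20.0, 0.25)
        coarse = channel_grid(60.0, 20.0, 0.5)
        f1, f2 = _zero_field(fine), _zero_field(coarse)
        f1.u[0, 0] = f2.u[0, 0] = 2.0
        assert cfl_timestep(f2, coarse) == pytest.approx(
            2 * cfl_timestep(f1, fine))

    def test_invalid_safety(self):
        grid = channel_grid(60.0, 20.0, 1.0)
        with pytest.raises(ValueError):
            cfl_timestep(_zero_field(grid), grid, safety=0.0)


class TestMaxReynolds:
    def test_channel_arithmetic(self):
        # rho U D_h / mu with D_h = 2 x 10 mm channel width
        geom = df.DissectionGeometry(true_lumen_width=10.0,
                                     entry_tear_width=6.0)
        grid = rasterize(geom, 1.0)
        fld = _zero_field(grid)
        fld.u[3, 3] = 0.5
        re = max_reynolds(fld, geom, FluidProperties())
        assert re == pytest.approx(1060 * 0.5 * 0.02 / 0.00371, rel=1e-12)

    def test_zero_field(self):
        geom = df.default_geometry()
        grid = rasterize(geom, 2.0)
        assert max_reynolds(_zero_field(grid), geom, FluidProperties()) == 0.0

    def test_linearity_in_speed(self):
        geom = df.default_geometry()
        grid = rasterize(geom, 2.0)
        f1, f2 = _zero_field(grid), _zero_field(grid)
        f1.u[3, 3], f2.u[3, 3] = 0.25, 0.5
        fl = FluidProperties()
        assert max_reynolds(f2, geom, fl) == pytest.approx(
            2 * max_reynolds(f1, geom, fl))


class TestRestState:
    def test_zero_inflow_keeps_rest_state(self):
        geom = df.make_case(1)
        bc = BoundaryConditions(outlet_pressure=Constant(1.0e4),
                                inlet_velocity=Constant(0.0))
        grid = rasterize(geom, 2.0)
        solver = StaggeredSolver(grid, df.BLOOD, bc)
        for _ in range(20):
            solver.advance(1e-3)
        assert np.all(solver.field.u == 0.0)
        assert np.all(solver.field.v == 0.0)

    def test_one_cycle_zero_inflow_simulate(self):
        geom = df.make_case(1)
        bc = BoundaryConditions(outlet_pressure=Constant(1.0e4),
                                inlet_velocity=Constant(0.0))
        res = df.simulate(geom, 2.0, bc, n_cycles=1, snapshot_phases=[0.5])
        assert res.snapshots[0].max_speed() == 0.0


class TestProjection:
    def test_divergence_small_after_single_step(self, bc, fluid):
        """Manufactured non-solenoidal start: one step must project it to a
        discrete divergence below 1e-8 1/s."""
        geom = df.make_case(2)
        grid = rasterize(geom, 1.0)
        solver = StaggeredSolver(grid, fluid, bc)
        rng = np.random.default_rng(11)
        fld = solver.field
        fld.u[solver.u_active] = 0.1 * rng.standard_normal(
            int(solver.u_active.sum()))
        fld.v[solver.v_active] = 0.1 * rng.standard_normal(
            int(solver.v_active.sum()))
        solver.advance(1e-4)
        assert solver.last_divergence <= 1e-8

    def test_no_slip_faces_exactly_zero(self, bc, fluid):
        geom = df.make_case(2)
        grid = rasterize(geom, 2.0)
        solver = StaggeredSolver(grid, fluid, bc)
        for _ in range(200):
            solver.advance(solver.stable_dt())
        u, v = solver.field.u, solver.field.v
        wall_u = solver.u_valid & ~solver.u_active
        wall_u[0, grid.inlet_j] = False
        wall_u[-1, grid.outlet_j] = False
        wall_v = solver.v_valid & ~solver.v_active
        for _, faces in grid.branch_faces:
            wall_v[faces, 0] = False
        assert np.all(u[wall_u] == 0.0)
        assert np.all(v[wall_v] == 0.0)
        assert np.all(u[~solver.u_valid] == 0.0)
        assert np.all(v[~solver.v_valid] == 0.0)

    def test_instability_reported_as_solver_error(self, bc, fluid):
        geom = df.make_case(1)
        grid = rasterize(geom, 2.0)
        solver = StaggeredSolver(grid, fluid, bc,
                                 Numerics(cfl_safety=1.0, dt_max=2.0e-2))
        with pytest.raises(df.SolverError):
            for _ in range(300):
                solver.advance(2.0e-2)


class TestDeterminism:
    def test_identical_configs_give_bit_identical_snapshots(self, bc, fluid,
                                                            numerics):
        geom = df.make_case(2)
        a = df.simulate(geom, 2.0, bc, fluid, n_cycles=1,
                        snapshot_phases=[0.25], numerics=numerics)
        b = df.simulate(geom, 2.0, bc, fluid, n_cycles=1,
                        snapshot_phases=[0.25], numerics=numerics)
        assert np.array_equal(a.snapshots[0].u, b.snapshots[0].u)
        assert np.array_equal(a.snapshots[0].v, b.snapshots[0].v)
        assert np.array_equal(a.snapshots[0].p, b.snapshots[0].p)


class TestSnapshotTiming:
    def test_default_phases_land_in_fourth_cycle(self, bc, fluid, numerics,
                                                 case2_run):
        assert [round(s.time, 10) for s in case2_run.snapshots] == [1.25, 1.47]

    def test_simulate_rejects_phase_outside_cycle(self, bc, fluid):
        with pytest.raises(ValueError):
            df.simulate(df.make_case(1), 2.0, bc, fluid, n_cycles=1,
                        snapshot_phases=[1.5])
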