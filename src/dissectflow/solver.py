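"""Unsteady incompressible Navier-Stokes on the masked staggered grid.

Continuity and momentum,

    div(v) = 0
    rho (dv/dt + v.grad v) = -grad p + div(tau),   tau = mu (grad v + grad v^T)

are discretized on a MAC (staggered) Cartesian grid with stair-step solid
masking: axial velocity u on x-faces, transverse velocity v on y-faces,
pressure p at cell centers.  Convection uses a second-order upwind scheme
falling back to first order where the upwind stencil crosses the mask;
viscous terms are central and explicit.  Pressure-velocity coupling is an
incremental fractional-step scheme with two pressure-correction sweeps per
step (a PISO predictor/multi-corrector structure); the pressure Poisson
system is pre-factorized with a sparse direct method, so the whole solver is
deterministic - there is no randomness anywhere in this module.

Boundary conditions: prescribed flat inlet velocity (or a pressure inlet for
benchmark channels), pressure outlet applied on the outlet plane, prescribed
outflow slots for the arch branches, and rigid no-slip walls where velocity
components are identically zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .geometry import DissectionGeometry
from .grid import MaskedGrid

__all__ = [
    "SolverError",
    "FluidProperties",
    "FlowField",
    "Diagnostics",
    "BoundaryConditions",
    "Numerics",
    "StaggeredSolver",
    "SimulationResult",
    "step",
    "simulate",
    "flow_split_audit",
    "cfl_timestep",
    "max_reynolds",
]

log = logging.getLogger(__name__)

MM = 1e-3  # mm -> m


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as a Newtonian incompressible fluid."""

    density: float = 1060.0            # kg/m^3
    dynamic_viscosity: float = 3.71e-3  # Pa.s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be > 0")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


BLOOD = FluidProperties()


@dataclass
class FlowField:
    """State at one instant: u on x-faces (nx+1, ny), v on y-faces
    (nx, ny+1), p at cell centers (nx, ny); SI units."""

    time: float
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray

    def copy(self) -> "FlowField":
        return FlowField(self.time, self.u.copy(), self.v.copy(), self.p.copy())

    def max_speed(self) -> float:
        return float(max(np.abs(self.u).max(), np.abs(self.v).max()))


@dataclass
class Diagnostics:
    re_max: float = 0.0
    re_critical: float = 2300.0
    cfl_max: float = 0.0
    divergence_max: float = 0.0          # 1/s, after the final corrector
    mass_imbalance_max: float = 0.0      # |net flux| / gross flux
    cycle_periodicity_error: float = math.nan
    n_steps: int = 0


@dataclass
class BoundaryConditions:
    """Boundary signals.  Exactly one of ``inlet_velocity`` (flat profile)
    or ``inlet_pressure`` must be given; ``outlet_pressure`` is applied on
    the outlet plane.  Branch slots carry their geometry-configured fraction
    of the instantaneous inlet flow (exact on the discrete slot widths)."""

    outlet_pressure: object                 # .evaluate(t) -> Pa
    inlet_velocity: Optional[object] = None  # .evaluate(t) -> m/s
    inlet_pressure: Optional[object] = None  # .evaluate(t) -> Pa
    period: float = 1.0

    def __post_init__(self) -> None:
        if (self.inlet_velocity is None) == (self.inlet_pressure is None):
            raise ValueError("give exactly one of inlet_velocity / inlet_pressure")


@dataclass
class Numerics:
    # forward Euler with second-order upwind convection is stable only up to
    # a Courant number of about 0.46 (amplification-factor analysis); 0.3
    # leaves margin for the viscous contribution
    cfl_safety: float = 0.3
    dt_max: float = 1.0e-3       # s
    n_correctors: int = 2
    divergence_tol: float = 1.0e-8   # 1/s
    re_critical: float = 2300.0

    def __post_init__(self) -> None:
        if not 0 < self.cfl_safety <= 1:
            raise ValueError("cfl_safety must be in (0, 1]")


def _shift(a: np.ndarray, di: int, dj: int) -> np.ndarray:
    """out[i, j] = a[i + di, j + dj], zero-filled outside."""
    out = np.zeros_like(a)
    ni, nj = a.shape
    si = slice(max(di, 0), ni + min(di, 0))
    sj = slice(max(dj, 0), nj + min(dj, 0))
    ti = slice(max(-di, 0), ni + min(-di, 0))
    tj = slice(max(-dj, 0), nj + min(-dj, 0))
    out[ti, tj] = a[si, sj]
    return out


class StaggeredSolver:
    """Pre-assembled solver for one (grid, fluid, bc, numerics) setup."""

    def __init__(self, grid: MaskedGrid, fluid: FluidProperties,
                 bc: BoundaryConditions, numerics: Optional[Numerics] = None):
        self.grid = grid
        self.fluid = fluid
        self.bc = bc
        self.num = numerics or Numerics()
        self.h = grid.spacing * MM
        self.nu = fluid.kinematic_viscosity
        nx, ny = grid.nx, grid.ny
        f = grid.fluid

        # adjacency of u-faces (nx+1, ny): cells (i-1, j) and (i, j)
        left = np.zeros((nx + 1, ny), bool)
        left[1:] = f
        right = np.zeros((nx + 1, ny), bool)
        right[:-1] = f
        self.u_valid = left | right
        self.u_active = left & right

        # adjacency of v-faces (nx, ny+1): cells (i, j-1) and (i, j)
        below = np.zeros((nx, ny + 1), bool)
        below[:, 1:] = f
        above = np.zeros((nx, ny + 1), bool)
        above[:, :-1] = f
        self.v_valid = below | above
        self.v_active = below & above

        # boundary openings
        self.pressure_inlet = bc.inlet_pressure is not None
        self.inlet_j = grid.inlet_j
        self.outlet_j = grid.outlet_j
        if self.outlet_j.size == 0:
            raise SolverError("grid has no outlet opening")
        self.branch_faces = grid.branch_faces
        n_inlet = self.inlet_j.size
        self.branch_scales = tuple(
            slot.outflow_fraction * n_inlet / idx.size
            for slot, idx in self.branch_faces
        )
        branch_cols = np.concatenate([idx for _, idx in self.branch_faces]) \
            if self.branch_faces else np.array([], dtype=int)
        self._branch_cols = branch_cols

        self._build_poisson()
        self.reset()

    # -- assembly -----------------------------------------------------------

    def _build_poisson(self) -> None:
        grid, h = self.grid, self.h
        nx, ny = grid.nx, grid.ny
        f = grid.fluid
        idx = -np.ones((nx, ny), dtype=np.int64)
        idx[f] = np.arange(grid.n_fluid)
        self.cell_index = idx

        rows, cols, vals = [], [], []
        diag = np.zeros(grid.n_fluid)

        def connect(ca, cb):
            a, b = idx[ca], idx[cb]
            rows.extend([a, b])
            cols.extend([b, a])
            vals.extend([np.ones(a.size), np.ones(b.size)])
            np.add.at(diag, a, -1.0)
            np.add.at(diag, b, -1.0)

        both_x = f[:-1] & f[1:]
        ii, jj = np.nonzero(both_x)
        connect((ii, jj), (ii + 1, jj))
        both_y = f[:, :-1] & f[:, 1:]
        ii, jj = np.nonzero(both_y)
        connect((ii, jj), (ii, jj + 1))

        # Dirichlet pressure applied on the boundary face (half-cell ghost)
        out_cells = idx[nx - 1, self.outlet_j]
        np.add.at(diag, out_cells, -2.0)
        self._outlet_cells = out_cells
        if self.pressure_inlet:
            in_cells = idx[0, self.inlet_j]
            np.add.at(diag, in_cells, -2.0)
            self._inlet_cells = in_cells
        else:
            self._inlet_cells = np.array([], dtype=int)

        n = grid.n_fluid
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = sparse.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsc() / h**2
        self._lu = splu(A)

    def reset(self, p0: Optional[float] = None) -> None:
        grid = self.grid
        if p0 is None:
            p0 = float(self.bc.outlet_pressure.evaluate(0.0))
        self.field = FlowField(
            0.0,
            np.zeros((grid.nx + 1, grid.ny)),
            np.zeros((grid.nx, grid.ny + 1)),
            np.full((grid.nx, grid.ny), p0),
        )
        self._apply_prescribed(self.field, 0.0)
        self.last_divergence = 0.0
        self.last_imbalance = 0.0

    # -- boundary handling --------------------------------------------------

    def _apply_prescribed(self, fld: FlowField, t: float) -> None:
        if not self.pressure_inlet:
            u_in = float(self.bc.inlet_velocity.evaluate(t))
            fld.u[0, self.inlet_j] = u_in
            for (slot, faces), scale in zip(self.branch_faces, self.branch_scales):
                fld.v[faces, 0] = -scale * u_in

    # -- spatial operators --------------------------------------------------

    def _upwind_derivative(self, q, adv, valid, axis, h):
        """Second-order upwind derivative of face field ``q`` advected by
        ``adv`` along ``axis``; first-order fallback where the second upwind
        node is outside the fluid.  Neighbors use antisymmetric wall ghosts
        in the tangential direction (prepared by the caller via ``valid``)."""
        d = (1, 0) if axis == 0 else (0, 1)

        def S(a, k):
            return _shift(a, k * d[0], k * d[1])

        vm1, vm2 = S(valid, -1), S(valid, -2)
        vp1, vp2 = S(valid, 1), S(valid, 2)
        qm1 = np.where(vm1, S(q, -1), -q)
        qm2 = S(q, -2)
        qp1 = np.where(vp1, S(q, 1), -q)
        qp2 = S(q, 2)
        sou_m = vm1 & vm2
        sou_p = vp1 & vp2
        d_minus = np.where(sou_m, (3 * q - 4 * qm1 + qm2) / (2 * h),
                           (q - qm1) / h)
        d_plus = np.where(sou_p, (-3 * q + 4 * qp1 - qp2) / (2 * h),
                          (qp1 - q) / h)
        return np.where(adv > 0, d_minus, d_plus)

    def _laplacian(self, q, valid, h):
        qxm = np.where(_shift(valid, -1, 0), _shift(q, -1, 0), -q)
        qxp = np.where(_shift(valid, 1, 0), _shift(q, 1, 0), -q)
        qym = np.where(_shift(valid, 0, -1), _shift(q, 0, -1), -q)
        qyp = np.where(_shift(valid, 0, 1), _shift(q, 0, 1), -q)
        return (qxm + qxp + qym + qyp - 4 * q) / h**2

    # -- time stepping ------------------------------------------------------

    def stable_dt(self) -> float:
        """Explicit stability estimate: harmonic combination of the
        advective (CFL) and diffusive limits, capped at dt_max."""
        fld = self.field
        h = self.h
        speed = max(fld.max_speed(), 1e-12)
        dt_adv = self.num.cfl_safety * h / speed
        dt_diff = 0.25 * h**2 / self.nu
        return min(self.num.dt_max, 1.0 / (1.0 / dt_adv + 1.0 / dt_diff))

    def advance(self, dt: float) -> None:
        fld = self.field
        h, nu, rho = self.h, self.nu, self.fluid.density
        u, v, p = fld.u, fld.v, fld.p
        t_old, t_new = fld.time, fld.time + dt
        nx, ny = self.grid.nx, self.grid.ny

        # cell-centred pressure padded with boundary-face ghosts
        p_out_old = float(self.bc.outlet_pressure.evaluate(t_old))

        # ---- predictor ----
        # advecting velocities averaged onto the staggered partner's faces:
        # u-face i sees v from cell columns i-1 and i; v-face j sees u from
        # cell rows j-1 and j
        vm = _shift(v, -1, 0)
        vbar_u = 0.25 * (v[:, :-1] + v[:, 1:] + vm[:, :-1] + vm[:, 1:])
        vbar_u = np.vstack([vbar_u, np.zeros((1, ny))])  # u-face i <- row i
        um = _shift(u, 0, -1)
        ubar_v = 0.25 * (u[:-1] + u[1:] + um[:-1] + um[1:])
        ubar_v = np.hstack([ubar_v, np.zeros((nx, 1))])  # v-face j <- col j

        conv_u = (u * self._upwind_derivative(u, u, self.u_valid, 0, h)
                  + vbar_u * self._upwind_derivative(u, vbar_u, self.u_valid, 1, h))
        conv_v = (ubar_v * self._upwind_derivative(v, ubar_v, self.v_valid, 0, h)
                  + v * self._upwind_derivative(v, v, self.v_valid, 1, h))
        lap_u = self._laplacian(u, self.u_valid, h)
        lap_v = self._laplacian(v, self.v_valid, h)

        gpx = np.zeros_like(u)
        gpx[1:-1] = (p[1:] - p[:-1]) / h
        gpy = np.zeros_like(v)
        gpy[:, 1:-1] = (p[:, 1:] - p[:, :-1]) / h

        us = u.copy()
        vs = v.copy()
        act_u, act_v = self.u_active, self.v_active
        us[act_u] = (u + dt * (-conv_u + nu * lap_u - gpx / rho))[act_u]
        vs[act_v] = (v + dt * (-conv_v + nu * lap_v - gpy / rho))[act_v]

        # outlet faces: convective outflow + viscous + old pressure gradient.
        # The generic laplacian used an antisymmetric ghost beyond the outlet
        # plane; replace it with a zero-gradient ghost (+2q/h^2 correction).
        jo = self.outlet_j
        uo = u[nx, jo]
        uc = np.maximum(uo, 0.0)
        dudx = (uo - u[nx - 1, jo]) / h
        gpx_o = (p_out_old - p[nx - 1, jo]) / (0.5 * h)
        lap_o = lap_u[nx, jo] + 2.0 * uo / h**2
        us[nx, jo] = uo + dt * (-uc * dudx + nu * lap_o - gpx_o / rho)
        if self.pressure_inlet:
            ji = self.inlet_j
            p_in_old = float(self.bc.inlet_pressure.evaluate(t_old))
            ui = u[0, ji]
            uc = np.minimum(ui, 0.0)
            dudx = (u[1, ji] - ui) / h
            gpx_i = (p[0, ji] - p_in_old) / (0.5 * h)
            lap_i = lap_u[0, ji] + 2.0 * ui / h**2
            us[0, ji] = ui + dt * (-uc * dudx + nu * lap_i - gpx_i / rho)

        # prescribed boundary values at the new time level
        tmp = FlowField(t_new, us, vs, p)
        self._apply_prescribed(tmp, t_new)

        # ---- pressure-correction sweeps (PISO structure) ----
        phi_out = float(self.bc.outlet_pressure.evaluate(t_new)) - p_out_old
        phi_in = 0.0
        if self.pressure_inlet:
            phi_in = float(self.bc.inlet_pressure.evaluate(t_new)) - p_in_old
        f = self.grid.fluid
        for sweep in range(self.num.n_correctors):
            div = (us[1:] - us[:-1] + vs[:, 1:] - vs[:, :-1]) / h
            rhs = (rho / dt) * div[f]
            if sweep == 0:
                rhs[self._outlet_cells] -= 2.0 * phi_out / h**2
                if self.pressure_inlet:
                    rhs[self._inlet_cells] -= 2.0 * phi_in / h**2
                bo, bi = phi_out, phi_in
            else:
                bo = bi = 0.0
            phi_flat = self._lu.solve(rhs)
            phi = np.zeros((nx, ny))
            phi[f] = phi_flat

            c = dt / rho
            dphix = (phi[1:] - phi[:-1]) / h
            us[1:-1][act_u[1:-1]] -= c * dphix[act_u[1:-1]]
            dphiy = (phi[:, 1:] - phi[:, :-1]) / h
            vs[:, 1:-1][act_v[:, 1:-1]] -= c * dphiy[act_v[:, 1:-1]]
            us[nx, jo] -= c * (bo - phi[nx - 1, jo]) / (0.5 * h)
            if self.pressure_inlet:
                us[0, self.inlet_j] -= c * (phi[0, self.inlet_j] - bi) / (0.5 * h)
            p[f] += phi_flat

        div = (us[1:] - us[:-1] + vs[:, 1:] - vs[:, :-1]) / h
        self.last_divergence = float(np.abs(div[f]).max())
        if not np.isfinite(us).all() or not np.isfinite(vs).all():
            raise SolverError(
                f"instability (NaN/Inf) at t={t_new:.4f}s; reduce the time step"
            )
        if self.last_divergence > self.num.divergence_tol:
            raise SolverError(
                f"divergence {self.last_divergence:.3e} 1/s above tolerance "
                f"{self.num.divergence_tol:.1e} after correction"
            )

        influx = float(us[0, self.inlet_j].sum() * h)
        outflux = float(us[nx, jo].sum() * h)
        branch_out = float(-vs[self._branch_cols, 0].sum() * h) \
            if self._branch_cols.size else 0.0
        gross = abs(influx) + abs(outflux) + abs(branch_out)
        net = influx - outflux - branch_out
        self.last_imbalance = abs(net) / gross if gross > 1e-12 else 0.0

        fld.u, fld.v = us, vs
        fld.time = t_new


def flow_split_audit(geom: DissectionGeometry, spacing: float,
                     bc: BoundaryConditions, fluid: FluidProperties = BLOOD,
                     n_cycles: int = 1,
                     numerics: Optional[Numerics] = None) -> dict:
    """Audit of the branch flow split over ``n_cycles``: integrates the
    normal velocity across each branch slot and across the inlet at every
    step and reports each branch's cycle-averaged flow as a percentage of
    inlet flow, plus the largest instantaneous deviation from the requested
    fraction."""
    from .grid import rasterize

    grid = rasterize(geom, spacing)
    solver = StaggeredSolver(grid, fluid, bc, numerics)
    h = solver.h
    nb = len(grid.branch_faces)
    inlet_int = 0.0
    branch_int = np.zeros(nb)
    inst_dev = np.zeros(nb)  # percentage points, at instants with inflow
    t_end = n_cycles * bc.period
    fld = solver.field
    while fld.time < t_end - 1e-12:
        dt = min(solver.stable_dt(), t_end - fld.time)
        solver.advance(dt)
        influx = float(fld.u[0, grid.inlet_j].sum() * h)
        inlet_int += influx * dt
        for k, (slot, faces) in enumerate(grid.branch_faces):
            q = float(-fld.v[faces, 0].sum() * h)
            branch_int[k] += q * dt
            if abs(influx) > 1e-8:
                inst_dev[k] = max(inst_dev[k],
                                  abs(100.0 * q / influx
                                      - 100.0 * slot.outflow_fraction))
    pct = 100.0 * branch_int / inlet_int
    return {
        "branch_percent_of_inlet": pct,
        "requested_percent": np.array(
            [100.0 * s.outflow_fraction for s, _ in grid.branch_faces]),
        "max_instantaneous_deviation_pp": inst_dev,
        "n_fluid_cells": grid.n_fluid,
    }


@dataclass
class SimulationResult:
    grid: MaskedGrid
    snapshots: list[FlowField]
    diagnostics: Diagnostics
    geom: Optional[DissectionGeometry] = None
    case_id: Optional[int] = None


def step(fld: FlowField, grid: MaskedGrid, fluid: FluidProperties,
         bc: BoundaryConditions, dt: float,
         numerics: Optional[Numerics] = None) -> FlowField:
    """Advance a field by one time step (convenience wrapper that assembles
    a solver; reuse :class:`StaggeredSolver` for long runs)."""
    solver = StaggeredSolver(grid, fluid, bc, numerics)
    solver.field = fld.copy()
    solver.advance(dt)
    return solver.field


def cfl_timestep(fld: FlowField, grid: MaskedGrid, safety: float = 0.5,
                 dt_max: float = 1.0e-3) -> float:
    """dt = safety * spacing / max speed, floored against zero fields and
    capped at ``dt_max``."""
    if not 0 < safety <= 1:
        raise ValueError("safety must be in (0, 1]")
    speed = max(fld.max_speed(), 1e-12)
    return min(dt_max, safety * grid.spacing * MM / speed)


def max_reynolds(fld: FlowField, geom: DissectionGeometry,
                 fluid: FluidProperties,
                 re_critical: float = 2300.0) -> float:
    """Re = rho U_max D_h / mu with D_h twice the proximal channel width
    (2D-channel hydraulic diameter); logs a warning above ``re_critical``."""
    d_h = 2.0 * geom.true_lumen_width * MM
    re = fluid.density * fld.max_speed() * d_h / fluid.dynamic_viscosity
    if re > re_critical:
        log.warning("Re_max %.0f exceeds critical Reynolds number %.0f "
                    "(laminar model retained)", re, re_critical)
    return re


def _run(solver: StaggeredSolver, t_end: float,
         targets: Sequence[float]) -> tuple[dict[float, FlowField], Diagnostics]:
    """March to ``t_end`` landing exactly on each target time; returns
    captured fields keyed by target time plus per-run diagnostics."""
    targets = sorted(set(targets))
    captured: dict[float, FlowField] = {}
    diag = Diagnostics(re_critical=solver.num.re_critical)
    h = solver.h
    next_i = 0
    fld = solver.field
    max_speed = 0.0
    while fld.time < t_end - 1e-12:
        dt = solver.stable_dt()
        while next_i < len(targets) and targets[next_i] <= fld.time + 1e-12:
            captured[targets[next_i]] = fld.copy()
            next_i += 1
        limit = targets[next_i] if next_i < len(targets) else t_end
        dt = min(dt, limit - fld.time, t_end - fld.time)
        solver.advance(dt)
        diag.n_steps += 1
        speed = fld.max_speed()
        max_speed = max(max_speed, speed)
        diag.cfl_max = max(diag.cfl_max, dt * speed / h)
        diag.divergence_max = max(diag.divergence_max, solver.last_divergence)
        diag.mass_imbalance_max = max(diag.mass_imbalance_max,
                                      solver.last_imbalance)
    for tt in targets[next_i:]:
        if tt <= fld.time + 1e-12:
            captured[tt] = fld.copy()
    return captured, diag, max_speed


def simulate(geom: DissectionGeometry, spacing: float,
             bc: BoundaryConditions, fluid: FluidProperties = BLOOD,
             n_cycles: int = 4,
             snapshot_phases: Sequence[float] = (0.25, 0.47),
             numerics: Optional[Numerics] = None,
             grid: Optional[MaskedGrid] = None,
             case_id: Optional[int] = None) -> SimulationResult:
    """Run ``n_cycles`` cardiac cycles from rest and return the fields at the
    requested phases of the final cycle (defaults mirror peak systole and
    early diastole) plus diagnostics, including the periodicity error between
    the last two cycles at the first snapshot phase."""
    from .grid import rasterize  # local import to keep module load light

    T = bc.period
    for ph in snapshot_phases:
        if not 0 <= ph < T:
            raise ValueError(f"snapshot phase {ph} outside [0, {T})")
    if grid is None:
        grid = rasterize(geom, spacing)
    solver = StaggeredSolver(grid, fluid, bc, numerics)

    t_end = n_cycles * T
    targets = [(n_cycles - 1) * T + ph for ph in snapshot_phases]
    prev_target = None
    if n_cycles >= 2 and snapshot_phases:
        prev_target = (n_cycles - 2) * T + snapshot_phases[0]
        targets.append(prev_target)
    captured, diag, max_speed = _run(solver, t_end, targets)

    snaps = [captured[(n_cycles - 1) * T + ph] for ph in snapshot_phases]
    d_h = 2.0 * geom.true_lumen_width * MM
    diag.re_max = fluid.density * max_speed * d_h / fluid.dynamic_viscosity
    if diag.re_max > diag.re_critical:
        log.warning("Re_max %.0f exceeds critical Reynolds number %.0f "
                    "(laminar model retained)", diag.re_max, diag.re_critical)
    if prev_target is not None:
        a, b = captured[prev_target], captured[targets[0]]
        num = math.sqrt(float(((b.u - a.u) ** 2).sum() + ((b.v - a.v) ** 2).sum()))
        den = math.sqrt(float((b.u ** 2).sum() + (b.v ** 2).sum()))
        diag.cycle_periodicity_error = num / den if den > 1e-14 else 0.0
        if not diag.cycle_periodicity_error < 0.02:
            log.warning("cycle-to-cycle periodicity error %.3f >= 2%%",
                        diag.cycle_periodicity_error)
    log.info("simulate: %d steps, Re_max %.0f, CFL %.2f, div %.2e 1/s, "
             "periodicity %.4f", diag.n_steps, diag.re_max, diag.cfl_max,
             diag.divergence_max, diag.cycle_periodicity_error)
    return SimulationResult(grid, snaps, diag, geom, case_id)
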