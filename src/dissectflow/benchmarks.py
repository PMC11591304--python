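"""Analytic channel-flow benchmarks for the solver.

Two classic closed forms validate the discretization: steady plane Poiseuille
flow, u(y) = (dp/dx / 2 mu) y (w - y), and oscillatory pressure-driven channel
flow (the planar Womersley problem).  Both are run as pressure-driven
channels: Dirichlet pressure on the inlet and outlet planes, no-slip walls.

The benchmark fluid is deliberately more viscous than blood so that the
start-up transient (time constant w^2 / (nu pi^2)) decays within a few
seconds of simulated time; the discretization error being measured is
independent of that choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import channel_grid
from .solver import (BoundaryConditions, FluidProperties,
                     StaggeredSolver, _run)

__all__ = [
    "Constant",
    "Harmonic",
    "poiseuille_profile",
    "oscillatory_profile",
    "poiseuille_benchmark",
    "womersley_benchmark",
    "convergence_order",
]

MM = 1e-3


@dataclass(frozen=True)
class Constant:
    value: float

    def evaluate(self, t):
        return self.value if np.isscalar(t) else np.full_like(np.asarray(t, float), self.value)


@dataclass(frozen=True)
class Harmonic:
    """offset + amplitude * cos(2 pi f t)"""

    offset: float
    amplitude: float
    frequency: float

    def evaluate(self, t):
        return self.offset + self.amplitude * np.cos(2 * math.pi * self.frequency * t)


def poiseuille_profile(y: np.ndarray, gradient: float, width: float,
                       viscosity: float) -> np.ndarray:
    """u(y) for dp/dx = -gradient (driving +x flow) across gap ``width`` (m)."""
    return gradient / (2.0 * viscosity) * y * (width - y)


def oscillatory_profile(y: np.ndarray, t: float, gradient_amplitude: float,
                        frequency: float, width: float, viscosity: float,
                        density: float) -> np.ndarray:
    """Planar Womersley solution for dp/dx = -G0 cos(omega t).

    u(y, t) = Re[ (-i G0 / (rho omega)) (1 - cosh(k y') / cosh(k w/2))
                  e^{i omega t} ],  k = sqrt(i omega / nu),  y' = y - w/2.

    In the low-frequency limit this tends to the quasi-steady Poiseuille
    profile (G0 cos(omega t) / 2 mu) y (w - y).
    """
    omega = 2 * math.pi * frequency
    nu = viscosity / density
    k = np.sqrt(1j * omega / nu)
    yp = np.asarray(y) - width / 2.0
    uhat = (-1j * gradient_amplitude / (density * omega)) * (
        1.0 - np.cosh(k * yp) / np.cosh(k * width / 2.0)
    )
    return np.real(uhat * np.exp(1j * omega * t))


def _centerline_u(u: np.ndarray, column: int) -> np.ndarray:
    return 0.5 * (u[column] + u[column + 1])


def poiseuille_benchmark(spacing: float = 0.5,
                         width: float = 20.0,
                         length: float = 60.0,
                         u_mean: float = 0.2,
                         viscosity: float = 0.0371,
                         density: float = 1060.0,
                         t_end: float = 7.0,
                         from_exact: bool = True) -> dict:
    """Steady pressure-driven channel vs the Poiseuille closed form.

    Returns max and L2 errors relative to the peak analytic velocity, plus
    the centerline-to-mean velocity ratio (analytically 1.5).
    """
    w = width * MM
    grad = 12.0 * viscosity * u_mean / w**2  # -dp/dx driving u_mean
    grid = channel_grid(length, width, spacing)
    fluid = FluidProperties(density=density, dynamic_viscosity=viscosity)
    p0 = 1.0e4
    bc = BoundaryConditions(
        outlet_pressure=Constant(p0),
        inlet_pressure=Constant(p0 + grad * length * MM),
    )
    solver = StaggeredSolver(grid, fluid, bc)
    y = grid.y_centers * MM
    exact = poiseuille_profile(y, grad, w, viscosity)
    if from_exact:
        solver.field.u[:] = exact[np.newaxis, :]
    _run(solver, t_end, [])
    u_num = _centerline_u(solver.field.u, grid.nx // 2)
    err = u_num - exact
    scale = exact.max()
    u_c = float(u_num.max())
    u_m = float(u_num.mean())
    return {
        "spacing_mm": spacing,
        "max_rel_error": float(np.abs(err).max() / scale),
        "l2_rel_error": float(np.linalg.norm(err) / np.linalg.norm(exact)),
        "centerline_over_mean": u_c / u_m,
        "u_numeric": u_num,
        "u_exact": exact,
        "y_m": y,
    }


def womersley_benchmark(spacing: float = 0.5,
                        frequency: float = 1.0,
                        width: float = 20.0,
                        length: float = 60.0,
                        womersley_number: float = 3.0,
                        u_scale: float = 0.3,
                        density: float = 1060.0,
                        n_cycles: int = 3,
                        n_phases: int = 16) -> dict:
    """Oscillatory channel flow vs the planar Womersley solution.

    The viscosity is chosen from the requested Womersley number
    alpha = (w/2) sqrt(omega / nu); the pressure-gradient amplitude from the
    requested velocity scale G0 ~ rho omega u_scale.  The final cycle is
    sampled at ``n_phases`` instants; errors are L2 over the profile,
    normalized by the cycle-peak analytic L2 norm.
    """
    w = width * MM
    omega = 2 * math.pi * frequency
    nu = omega * (w / 2.0) ** 2 / womersley_number**2
    viscosity = nu * density
    g0 = density * omega * u_scale
    grid = channel_grid(length, width, spacing)
    fluid = FluidProperties(density=density, dynamic_viscosity=viscosity)
    p0 = 1.0e4
    bc = BoundaryConditions(
        outlet_pressure=Constant(p0),
        inlet_pressure=Harmonic(p0, g0 * length * MM, frequency),
        period=1.0 / frequency,
    )
    solver = StaggeredSolver(grid, fluid, bc)
    T = 1.0 / frequency
    phases = np.arange(n_phases) / n_phases * T
    targets = [(n_cycles - 1) * T + ph for ph in phases]
    captured, _, _ = _run(solver, n_cycles * T, targets)

    y = grid.y_centers * MM
    col = grid.nx // 2
    norm_ref = max(
        np.linalg.norm(oscillatory_profile(y, t, g0, frequency, w, viscosity,
                                           density))
        for t in targets
    )
    errs = []
    for t in targets:
        u_num = _centerline_u(captured[t].u, col)
        u_ana = oscillatory_profile(y, t, g0, frequency, w, viscosity, density)
        errs.append(np.linalg.norm(u_num - u_ana) / norm_ref)
    return {
        "spacing_mm": spacing,
        "womersley_number": womersley_number,
        "cycle_avg_l2_error": float(np.mean(errs)),
        "phase_l2_errors": np.asarray(errs),
        "phases_s": phases,
    }


def convergence_order(spacings, errors) -> float:
    """Least-squares slope of log(error) vs log(spacing)."""
    s = np.log(np.asarray(spacings, float))
    e = np.log(np.asarray(errors, float))
    return float(np.polyfit(s, e, 1)[0])
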