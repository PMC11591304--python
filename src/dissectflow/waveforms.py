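"""Periodic boundary signals: pulsatile inlet velocity, outlet pressure and
branch outflow.

The published inlet/outlet curves for this problem are digitized figures with
no tabulated values, so this module ships documented parametric
approximations: a half-sine systolic velocity pulse and a two-phase arterial
pressure wave between configurable diastolic/systolic levels.  Control points
are interpolated with a monotone piecewise-cubic (PCHIP), which cannot
overshoot and therefore preserves positivity and the configured extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "WaveformError",
    "Waveform",
    "inlet_velocity_waveform",
    "outlet_pressure_waveform",
    "branch_outflow_waveform",
]


class WaveformError(ValueError):
    pass


@dataclass
class Waveform:
    """Periodic signal defined by control points ``(phase s, value)`` in
    ``[0, period)`` with periodic monotone-cubic interpolation.

    ``kind`` is ``"velocity"`` (m/s) or ``"pressure"`` (Pa); pressure
    waveforms must be strictly positive.
    """

    period: float
    kind: str
    control_points: tuple[tuple[float, float], ...]
    note: str = ""
    _interp: PchipInterpolator | None = field(default=None, repr=False,
                                              compare=False)

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise WaveformError(f"period must be > 0, got {self.period}")
        if self.kind not in ("velocity", "pressure"):
            raise WaveformError(f"unknown waveform kind {self.kind!r}")
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise WaveformError("need at least 2 control points")
        ph = pts[:, 0]
        if np.any(np.diff(ph) <= 0) or ph[0] < 0 or ph[-1] >= self.period:
            raise WaveformError("phases must be strictly increasing in [0, period)")
        if self.kind == "pressure" and np.any(pts[:, 1] <= 0):
            raise WaveformError("pressure control points must be > 0")
        # periodic extension: wrap three points on each side so the cubic is
        # smooth across the period seam
        k = min(3, len(ph))
        xs = np.concatenate([ph[-k:] - self.period, ph, ph[:k] + self.period])
        ys = np.concatenate([pts[-k:, 1], pts[:, 1], pts[:k, 1]])
        self._interp = PchipInterpolator(xs, ys)

    def evaluate(self, t):
        """Signal value at time(s) ``t`` (periodic in ``period``)."""
        phase = np.mod(t, self.period)
        out = self._interp(phase)
        return float(out) if np.isscalar(t) else out

    __call__ = evaluate

    def cycle_samples(self, n: int = 1000) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return t, self.evaluate(t)

    def cycle_mean(self, n: int = 2000) -> float:
        return float(self.cycle_samples(n)[1].mean())

    def cycle_max(self, n: int = 2000) -> float:
        return float(self.cycle_samples(n)[1].max())


def inlet_velocity_waveform(period: float = 1.0,
                            peak: float = 1.0,
                            systole_start: float = 0.05,
                            systole_end: float = 0.45,
                            baseline: float = 0.0) -> Waveform:
    """Pulsatile inlet velocity: half-sine systolic pulse over
    ``[systole_start, systole_end]`` peaking mid-interval (phase 0.25 s at the
    defaults), zero-flow diastolic baseline.

    The spatially flat profile is applied by the solver across the inlet.
    """
    if peak < baseline:
        raise WaveformError("peak velocity below diastolic baseline")
    if not 0 <= systole_start < systole_end < period:
        raise WaveformError("systolic interval must lie inside [0, period)")
    dur = systole_end - systole_start
    # symmetric sine samples => PCHIP max exactly at mid-systole
    phases = systole_start + dur * np.linspace(0.0, 1.0, 9)
    values = baseline + (peak - baseline) * np.sin(np.pi * (phases - systole_start) / dur)
    pts = [(0.0, baseline)] if systole_start > 0 else []
    pts += list(zip(phases, values))
    tail = systole_end + 0.5 * (period - systole_end)
    pts += [(tail, baseline)]
    return Waveform(period, "velocity", tuple(pts),
                    note="parametric half-sine systolic pulse")


def outlet_pressure_waveform(period: float = 1.0,
                             diastolic: float = 10.6e3,
                             systolic: float = 16.0e3,
                             peak_phase: float = 0.30) -> Waveform:
    """Pulsatile outlet pressure oscillating between the diastolic and
    systolic levels (defaults 10.6-16.0 kPa, i.e. ~80-120 mmHg), peaking at
    ``peak_phase``."""
    if systolic <= diastolic:
        raise WaveformError("systolic pressure must exceed diastolic")
    if not 0 < peak_phase < period:
        raise WaveformError("peak_phase must lie in (0, period)")
    d, s = diastolic, systolic
    amp = s - d
    rise0 = 0.05
    pts = (
        (0.0, d + 0.02 * amp),
        (rise0, d + 0.05 * amp),
        (0.5 * (rise0 + peak_phase), d + 0.60 * amp),
        (peak_phase, s),
        (peak_phase + 0.15, d + 0.45 * amp),
        (peak_phase + 0.30, d + 0.15 * amp),
        (min(peak_phase + 0.55, 0.999 * period), d),
    )
    return Waveform(period, "pressure", pts,
                    note="parametric two-phase arterial pressure wave")


def branch_outflow_waveform(inlet: Waveform, fraction: float,
                            inlet_width: float, branch_width: float) -> Waveform:
    """Branch-slot velocity waveform carrying ``fraction`` of the
    instantaneous inlet volumetric flow (2D flow per unit depth =
    velocity x width).

    PCHIP interpolation is positively homogeneous in the ordinates, so scaling
    the inlet control points by ``fraction * inlet_width / branch_width``
    preserves the flow split at every instant, not just at the nodes.
    """
    if not 0 < fraction < 1:
        raise WaveformError(f"fraction must be in (0, 1), got {fraction}")
    if inlet_width <= 0 or branch_width <= 0:
        raise WaveformError("widths must be > 0")
    scale = fraction * inlet_width / branch_width
    pts = tuple((ph, scale * v) for ph, v in inlet.control_points)
    return Waveform(inlet.period, "velocity", pts,
                    note=f"branch outflow, {fraction:.3f} of inlet flow")
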