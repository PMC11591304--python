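"""YAML configuration: defaults, loading, and assembly of the simulation
objects (geometry, boundary conditions, fluid, numerics)."""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import replace
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .geometry import (BranchSlot, DissectionGeometry, default_geometry,
                       make_case)
from .solver import BoundaryConditions, FluidProperties, Numerics
from .waveforms import inlet_velocity_waveform, outlet_pressure_waveform

__all__ = ["default_config", "load_config", "config_hash", "build_geometry",
           "build_case_geometry", "build_fluid", "build_numerics", "build_bc"]


def default_config() -> dict:
    text = resources.files("dissectflow").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[dict] = None) -> dict:
    """Default config, deep-merged with a YAML file and/or override dict."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            _deep_update(cfg, yaml.safe_load(fh) or {})
    if overrides:
        _deep_update(cfg, copy.deepcopy(overrides))
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def build_geometry(cfg: dict) -> DissectionGeometry:
    g = dict(cfg.get("geometry", {}))
    slots = g.pop("branch_slots", None)
    base = default_geometry()
    if not cfg.get("waveforms", {}).get("branches", True):
        slots = []
    if slots is not None:
        g["branch_slots"] = tuple(
            BranchSlot(s["axial_position"], s["width"], s["outflow_fraction"])
            for s in slots
        )
    return replace(base, **g) if g else base


def build_case_geometry(cfg: dict, case_id: int) -> DissectionGeometry:
    return make_case(case_id, build_geometry(cfg))


def build_fluid(cfg: dict) -> FluidProperties:
    f = cfg.get("fluid", {})
    return FluidProperties(
        density=f.get("density", 1060.0),
        dynamic_viscosity=f.get("dynamic_viscosity", 3.71e-3),
    )


def build_numerics(cfg: dict) -> Numerics:
    n = cfg.get("numerics", {})
    return Numerics(
        cfl_safety=n.get("cfl_safety", 0.3),
        dt_max=n.get("dt_max_ms", 1.0) * 1e-3,
        n_correctors=n.get("n_correctors", 2),
        divergence_tol=n.get("divergence_tol", 1e-8),
        re_critical=n.get("re_critical", 2300.0),
    )


def build_bc(cfg: dict) -> BoundaryConditions:
    w = cfg.get("waveforms", {})
    period = w.get("period", 1.0)
    inl = w.get("inlet", {})
    scale = 1.0
    if not w.get("branches", True):
        # branches off: divert their share by scaling the inlet instead
        geo = cfg.get("geometry", {})
        slots = geo.get("branch_slots")
        frac = (sum(s["outflow_fraction"] for s in slots) if slots
                else 3 * 0.05)
        scale = 1.0 - frac
    inlet = inlet_velocity_waveform(
        period=period,
        peak=inl.get("peak", 1.0) * scale,
        systole_start=inl.get("systole_start", 0.05),
        systole_end=inl.get("systole_end", 0.45),
        baseline=inl.get("baseline", 0.0) * scale,
    )
    outl = w.get("outlet", {})
    outlet = outlet_pressure_waveform(
        period=period,
        diastolic=outl.get("diastolic", 10.6e3),
        systolic=outl.get("systolic", 16.0e3),
        peak_phase=outl.get("peak_phase", 0.30),
    )
    return BoundaryConditions(outlet_pressure=outlet, inlet_velocity=inlet,
                              period=period)
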