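"""Hemodynamic post-processing of flow snapshots.

Computes the comparison quantities of the re-entry-location study: wall
shear stress along the lumen walls, per-region per-lumen pressure/WSS/speed
summaries at the sampled cardiac phases, signed tear fluxes, the reversed
(recirculating) flow area in the false lumen below the re-entry tear, and
the location of the peak velocity.  All metrics are pure functions of the
snapshot; recomputation is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import DissectionGeometry
from .grid import FALSE_LUMEN, LUMEN_NAMES, MaskedGrid, TRUE_LUMEN
from .solver import MM, FlowField, FluidProperties

__all__ = [
    "AbsentTearError",
    "RecirculationMetric",
    "wall_shear_stress",
    "regional_summary",
    "pressure_difference",
    "tear_flux",
    "recirculation_extent",
    "peak_velocity_location",
    "cell_speeds",
]


class AbsentTearError(ValueError):
    """Requested flux through a tear the geometry does not have."""


@dataclass(frozen=True)
class RecirculationMetric:
    """Recirculation in the false lumen below (distal to) the re-entry tear.

    Two readings of "reversed" are reported: ``area_fraction_reversed`` and
    ``reversed_area_mm2`` count cells whose axial velocity is below
    ``-threshold * reference_speed`` (a noise-robust measure of vigorous
    recirculation), while ``reversed_area_sign_mm2`` counts every cell with
    negative axial velocity — the plain reversed-flow area, which also
    captures the slow creeping recirculation of long dead-end columns.
    """

    phase: str
    area_fraction_reversed: float   # thresholded cells / zone cells, [0, 1]
    reversed_area_mm2: float        # thresholded
    reversed_area_sign_mm2: float   # any reversed axial flow
    zone_area_mm2: float
    zone: str
    case_id: Optional[int] = None


def _region_ids(grid: MaskedGrid, geom: DissectionGeometry) -> np.ndarray:
    """1-based region id per axial column; 0 outside the dissected segment."""
    x = grid.x_centers
    xl = x - geom.dissection_start
    ids = np.searchsorted(np.asarray(geom.region_bounds), xl, side="right")
    ids = np.clip(ids, 1, geom.n_regions)
    ids[(xl < 0) | (xl > geom.dissected_length)] = 0
    return ids


def cell_speeds(field: FlowField) -> np.ndarray:
    """Velocity magnitude interpolated to cell centers."""
    uc = 0.5 * (field.u[:-1] + field.u[1:])
    vc = 0.5 * (field.v[:, :-1] + field.v[:, 1:])
    return np.hypot(uc, vc)


def wall_shear_stress(field: FlowField, grid: MaskedGrid,
                      fluid: FluidProperties,
                      geom: Optional[DissectionGeometry] = None) -> pd.DataFrame:
    """WSS samples on every wall-adjacent face.

    WSS = mu * |dq/dn| at the wall from a one-sided quadratic fit through
    the wall (no-slip) and the two nearest cell-center tangential
    velocities: q'(0) = (9 q1 - q2) / (3 h).  Samples whose second interior
    cell is missing are flagged unreliable and excluded from summaries.
    """
    mu = fluid.dynamic_viscosity
    h = grid.spacing * MM
    f = grid.fluid
    nx, ny = grid.nx, grid.ny
    geom = geom if geom is not None else grid.geom

    uc = 0.5 * (field.u[:-1] + field.u[1:])   # (nx, ny) tangential for y-walls
    vc = 0.5 * (field.v[:, :-1] + field.v[:, 1:])  # tangential for x-walls

    open_bottom = np.zeros(nx, dtype=bool)
    for _, idx in grid.branch_faces:
        open_bottom[idx] = True

    rows = []

    def add(i, j, q1, q2, reliable, orientation, x_mm, y_mm):
        wss = mu * abs((9.0 * q1 - q2) / (3.0 * h)) if reliable else np.nan
        region = geom.region_of(x_mm) if geom is not None else 0
        rows.append((x_mm, y_mm, orientation,
                     LUMEN_NAMES.get(int(grid.lumen_label[i, j]), "solid"),
                     region, wss, reliable))

    xc, yc = grid.x_centers, grid.y_centers
    hmm = grid.spacing

    # horizontal walls (tangential velocity u)
    for i, j in zip(*np.nonzero(f)):
        # wall below
        if (j == 0 and not open_bottom[i]) or (j > 0 and not f[i, j - 1]):
            q2_ok = j + 1 < ny and f[i, j + 1]
            add(i, j, uc[i, j], uc[i, j + 1] if q2_ok else 0.0, q2_ok,
                "bottom", xc[i], yc[j] - hmm / 2)
        # wall above
        if j == ny - 1 or not f[i, j + 1]:
            q2_ok = j - 1 >= 0 and f[i, j - 1]
            add(i, j, uc[i, j], uc[i, j - 1] if q2_ok else 0.0, q2_ok,
                "top", xc[i], yc[j] + hmm / 2)
        # wall left (skip the inlet plane)
        if i > 0 and not f[i - 1, j]:
            q2_ok = i + 1 < nx and f[i + 1, j]
            add(i, j, vc[i, j], vc[i + 1, j] if q2_ok else 0.0, q2_ok,
                "left", xc[i] - hmm / 2, yc[j])
        # wall right (skip the outlet plane)
        if i < nx - 1 and not f[i + 1, j]:
            q2_ok = i - 1 >= 0 and f[i - 1, j]
            add(i, j, vc[i, j], vc[i - 1, j] if q2_ok else 0.0, q2_ok,
                "right", xc[i] + hmm / 2, yc[j])

    return pd.DataFrame(
        rows, columns=["x_mm", "y_mm", "orientation", "lumen", "region",
                       "wss_pa", "reliable"],
    )


def regional_summary(field: FlowField, grid: MaskedGrid,
                     geom: DissectionGeometry, phase: str,
                     fluid: FluidProperties,
                     wss: Optional[pd.DataFrame] = None,
                     case_id: Optional[int] = None) -> pd.DataFrame:
    """Per (region, lumen) summary at one phase: median pressure (kPa),
    median and max WSS (Pa) over reliable wall samples, and peak speed
    (m/s).  Always emits 6 regions x 2 lumens = 12 rows; empty
    region/lumen combinations carry NaN markers."""
    if wss is None:
        wss = wall_shear_stress(field, grid, fluid, geom)
    region = _region_ids(grid, geom)[:, np.newaxis] * np.ones(
        (1, grid.ny), dtype=int)
    speeds = cell_speeds(field)
    rows = []
    for r in range(1, geom.n_regions + 1):
        for code, lum in ((TRUE_LUMEN, "true"), (FALSE_LUMEN, "false")):
            cells = grid.fluid & (grid.lumen_label == code) & (region == r)
            name = LUMEN_NAMES[code]
            sel = wss[(wss.region == r) & (wss.lumen == name) & wss.reliable]
            rows.append({
                "case_id": case_id,
                "region": r,
                "lumen": lum,
                "phase": phase,
                "n_cells": int(cells.sum()),
                "pressure_median_kpa": (float(np.median(field.p[cells])) / 1e3
                                        if cells.any() else np.nan),
                "wss_median_pa": (float(sel.wss_pa.median())
                                  if len(sel) else np.nan),
                "wss_max_pa": float(sel.wss_pa.max()) if len(sel) else np.nan,
                "peak_speed_ms": (float(speeds[cells].max())
                                  if cells.any() else np.nan),
            })
    return pd.DataFrame(rows)


def pressure_difference(summary: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-region true-minus-false lumen median pressure gap (kPa), plus the
    true-lumen region-1 minus region-6 gap (the inlet-outlet drop along the
    dissected segment)."""
    piv = summary.pivot_table(index="region", columns="lumen",
                              values="pressure_median_kpa", dropna=False)
    for col in ("true", "false"):
        if col not in piv:
            piv[col] = np.nan
    out = pd.DataFrame({
        "region": piv.index,
        "tl_minus_fl_kpa": (piv["true"] - piv["false"]).to_numpy(),
    }).reset_index(drop=True)
    tl = piv["true"]
    last = summary.region.max()
    gap = float(tl.get(1, np.nan) - tl.get(last, np.nan))
    return out, gap


def _tear_columns(grid: MaskedGrid, geom: DissectionGeometry,
                  tear: str) -> np.ndarray:
    span = geom.entry_tear_span if tear == "entry" else geom.re_entry_span
    if span is None:
        raise AbsentTearError(f"geometry has no {tear} tear")
    lo, hi = (geom.dissection_start + span[0], geom.dissection_start + span[1])
    x = grid.x_centers
    return np.nonzero((x >= lo) & (x < hi))[0]


def tear_flux(field: FlowField, grid: MaskedGrid, geom: DissectionGeometry,
              tear: str = "entry") -> float:
    """Signed volumetric flux (m^2/s, per unit depth) through a septum tear,
    integrated across the tear gap at the true-lumen ceiling; positive means
    false-lumen -> true-lumen."""
    if tear not in ("entry", "re_entry"):
        raise ValueError(f"tear must be 'entry' or 're_entry', got {tear!r}")
    cols = _tear_columns(grid, geom, tear)
    h = grid.spacing * MM
    j_face = int(np.searchsorted(grid.y_centers, geom.true_lumen_width))
    # v > 0 flows upward (TL -> FL); FL -> TL is therefore -v
    return float(-field.v[cols, j_face].sum() * h)


def recirculation_extent(field: FlowField, grid: MaskedGrid,
                         geom: DissectionGeometry, phase: str = "",
                         threshold: float = 0.01,
                         reference_speed: float = 1.0,
                         case_id: Optional[int] = None) -> RecirculationMetric:
    """Fraction (and absolute area) of false-lumen cells distal to the
    re-entry tear whose axial velocity is reversed below
    ``-threshold * reference_speed`` (whole false lumen when there is no
    re-entry tear)."""
    y = grid.y_centers
    fl_body = (grid.lumen_label == FALSE_LUMEN) & (
        y[np.newaxis, :] >= geom.true_lumen_width + geom.septum_thickness)
    span = geom.re_entry_span
    if span is None:
        zone = fl_body
        desc = "entire false lumen (no re-entry tear)"
    else:
        x_edge = geom.dissection_start + span[1]
        zone = fl_body & (grid.x_centers[:, np.newaxis] > x_edge)
        desc = f"false lumen distal to x = {x_edge:.1f} mm"
    uc = 0.5 * (field.u[:-1] + field.u[1:])
    n_zone = int(zone.sum())
    reversed_cells = int((zone & (uc < -threshold * reference_speed)).sum())
    reversed_sign = int((zone & (uc < 0.0)).sum())
    frac = reversed_cells / n_zone if n_zone else 0.0
    cell_area = grid.spacing**2
    return RecirculationMetric(
        phase=phase,
        area_fraction_reversed=frac,
        reversed_area_mm2=reversed_cells * cell_area,
        reversed_area_sign_mm2=reversed_sign * cell_area,
        zone_area_mm2=n_zone * cell_area,
        zone=desc,
        case_id=case_id,
    )


def peak_velocity_location(field: FlowField, grid: MaskedGrid,
                           geom: DissectionGeometry) -> tuple[float, int, str]:
    """Maximum cell-center speed and its location as (speed, region id,
    label); cells inside a tear gap report the tear's own label.  Ties break
    to the lowest region id, then true lumen before false lumen."""
    speeds = cell_speeds(field)
    speeds = np.where(grid.fluid, speeds, -np.inf)
    smax = speeds.max()
    cand = np.argwhere(speeds == smax)
    region = _region_ids(grid, geom)
    sep_lo = geom.true_lumen_width
    sep_hi = sep_lo + geom.septum_thickness
    order = {TRUE_LUMEN: 0, FALSE_LUMEN: 1}

    def label_of(i, j):
        x, yv = grid.x_centers[i], grid.y_centers[j]
        if sep_lo <= yv < sep_hi:
            for name, span in (("entry_tear", geom.entry_tear_span),
                               ("re_entry_tear", geom.re_entry_span)):
                if span is not None and \
                        geom.dissection_start + span[0] <= x < geom.dissection_start + span[1]:
                    return name
        return LUMEN_NAMES[int(grid.lumen_label[i, j])]

    def key(ij):
        i, j = ij
        r = region[i]
        return (r if r > 0 else 99, order.get(int(grid.lumen_label[i, j]), 2),
                i, j)

    i, j = min(map(tuple, cand), key=key)
    return float(smax), int(region[i]), label_of(i, j)
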