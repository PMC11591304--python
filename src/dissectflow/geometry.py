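"""Parametric idealized geometry of a dissected descending aorta.

The patient anatomy is reduced to a 2D axial-plane idealization: a straight
true lumen (TL) running from inlet to outlet, and a parallel false lumen (FL)
alongside the dissected segment, separated by a septum (intimal flap).  The FL
is sealed at its distal floor and communicates with the TL only through an
entry tear and, in cases 2-11, a re-entry tear.  Aortic-arch branches are
represented as outflow slots on the proximal wall, not as resolved vessels.

Axial coordinate ``x`` (mm) increases distally from the inlet.  Transverse
coordinate ``y`` (mm) spans the TL ``[0, true_lumen_width)``, the septum, and
the FL above it.  Re-entry tear positions are measured from the FL distal
floor toward the proximal end, to the tear center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "BranchSlot",
    "ReEntryTear",
    "DissectionGeometry",
    "CaseSpec",
    "REENTRY_DISTANCES_MM",
    "N_CASES",
    "tear_width",
    "make_case",
    "partition_regions",
    "default_geometry",
    "case_table",
]

#: Re-entry tear center distances from the false-lumen distal floor (mm) for
#: cases 2-11, ordered by case id.  Case 1 has no re-entry tear.
REENTRY_DISTANCES_MM: tuple[float, ...] = (
    22.5, 33.7, 67.4, 89.9, 112.4, 134.9, 157.4, 168.6, 179.8, 202.3,
)

N_CASES = 1 + len(REENTRY_DISTANCES_MM)


class GeometryError(ValueError):
    """Raised when a geometry parameterization violates its invariants."""


@dataclass(frozen=True)
class BranchSlot:
    """An arch-branch outflow slot on the proximal wall.

    ``axial_position`` is the slot center (mm from the inlet); the slot carries
    ``outflow_fraction`` of the instantaneous inlet volumetric flow.
    """

    axial_position: float
    width: float
    outflow_fraction: float


@dataclass(frozen=True)
class ReEntryTear:
    """Re-entry tear: ``distance_from_floor`` locates the tear center,
    measured proximally from the false-lumen distal floor (mm)."""

    distance_from_floor: float
    width: float


@dataclass(frozen=True)
class DissectionGeometry:
    proximal_length: float = 60.0
    dissected_length: float = 225.0
    distal_length: float = 20.0
    true_lumen_width: float = 20.0
    false_lumen_short_axis: float = 12.8
    septum_thickness: float = 2.0
    entry_tear_width: float = 6.4
    entry_tear_offset: float = 5.0  # tear center, mm from dissection start
    re_entry: Optional[ReEntryTear] = None
    branch_slots: tuple[BranchSlot, ...] = (
        BranchSlot(15.0, 6.0, 0.05),
        BranchSlot(30.0, 6.0, 0.05),
        BranchSlot(45.0, 6.0, 0.05),
    )
    region_bounds: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        lengths = {
            "proximal_length": self.proximal_length,
            "dissected_length": self.dissected_length,
            "distal_length": self.distal_length,
            "true_lumen_width": self.true_lumen_width,
            "false_lumen_short_axis": self.false_lumen_short_axis,
            "septum_thickness": self.septum_thickness,
            "entry_tear_width": self.entry_tear_width,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise GeometryError(f"{name} must be > 0, got {value}")
        if self.entry_tear_width > self.false_lumen_short_axis:
            raise GeometryError("entry tear wider than false-lumen short axis")
        lo, hi = self.entry_tear_span
        if lo < 0 or hi > self.dissected_length:
            raise GeometryError("entry tear extends outside the dissected segment")
        if self.re_entry is not None:
            self._check_re_entry(self.re_entry)
        frac = sum(s.outflow_fraction for s in self.branch_slots)
        if not frac < 1.0:
            raise GeometryError(f"branch outflow fractions sum to {frac} >= 1")
        for slot in self.branch_slots:
            if not 0 < slot.outflow_fraction < 1:
                raise GeometryError("branch outflow fraction outside (0, 1)")
            if (slot.axial_position - slot.width / 2 < 0
                    or slot.axial_position + slot.width / 2 > self.proximal_length):
                raise GeometryError("branch slot outside the proximal segment")
        if not self.region_bounds:
            object.__setattr__(
                self, "region_bounds", tuple(partition_regions(self.dissected_length))
            )
        bounds = np.asarray(self.region_bounds, dtype=float)
        if bounds.ndim != 1 or bounds.size < 2 or np.any(np.diff(bounds) <= 0):
            raise GeometryError("region_bounds must be strictly increasing")
        if abs(bounds[0]) > 1e-9 or abs(bounds[-1] - self.dissected_length) > 1e-9:
            raise GeometryError("region_bounds must span [0, dissected_length]")

    def _check_re_entry(self, tear: ReEntryTear) -> None:
        if not tear.width > 0:
            raise GeometryError("re-entry tear width must be > 0")
        if tear.width > self.false_lumen_short_axis:
            raise GeometryError("re-entry tear wider than false-lumen short axis")
        lo, hi = self.re_entry_span  # type: ignore[misc]
        if not (0 < lo and hi < self.dissected_length):
            raise GeometryError(
                f"re-entry tear [{lo}, {hi}] mm not strictly inside the "
                f"dissected segment [0, {self.dissected_length}] mm"
            )
        e_lo, e_hi = self.entry_tear_span
        if lo < e_hi:
            raise GeometryError(
                "re-entry tear overlaps or lies proximal to the entry tear"
            )

    # -- derived positions (mm, in the dissected segment's local coordinate) --

    @property
    def entry_tear_span(self) -> tuple[float, float]:
        c = self.entry_tear_offset
        return c - self.entry_tear_width / 2, c + self.entry_tear_width / 2

    @property
    def re_entry_span(self) -> Optional[tuple[float, float]]:
        if self.re_entry is None:
            return None
        c = self.dissected_length - self.re_entry.distance_from_floor
        return c - self.re_entry.width / 2, c + self.re_entry.width / 2

    # -- global (inlet-origin) coordinates ------------------------------------

    @property
    def dissection_start(self) -> float:
        return self.proximal_length

    @property
    def dissection_end(self) -> float:
        return self.proximal_length + self.dissected_length

    @property
    def total_length(self) -> float:
        return self.proximal_length + self.dissected_length + self.distal_length

    @property
    def total_width(self) -> float:
        return (self.true_lumen_width + self.septum_thickness
                + self.false_lumen_short_axis)

    @property
    def n_regions(self) -> int:
        return len(self.region_bounds) - 1

    def region_of(self, x_global: float) -> int:
        """1-based region id of an axial position, or 0 outside the
        dissected segment."""
        xl = x_global - self.dissection_start
        if xl < 0 or xl > self.dissected_length:
            return 0
        idx = int(np.searchsorted(self.region_bounds, xl, side="right")) - 1
        return min(max(idx, 0), self.n_regions - 1) + 1


@dataclass(frozen=True)
class CaseSpec:
    """One scenario of the 11-case re-entry-location sweep."""

    case_id: int
    re_entry_distance: Optional[float]

    def __post_init__(self) -> None:
        if not 1 <= self.case_id <= N_CASES:
            raise GeometryError(f"case_id must be 1..{N_CASES}, got {self.case_id}")
        if self.case_id == 1:
            if self.re_entry_distance is not None:
                raise GeometryError("case 1 is the entry-only case")
        else:
            expected = REENTRY_DISTANCES_MM[self.case_id - 2]
            if self.re_entry_distance != expected:
                raise GeometryError(
                    f"case {self.case_id} re-entry distance must be {expected} mm"
                )


def tear_width(false_lumen_short_axis: float) -> float:
    """Tear diameter from the sizing rule: 50% of the false-lumen short axis.

    >>> tear_width(12.8)
    6.4
    """
    if not false_lumen_short_axis > 0:
        raise GeometryError(
            f"false-lumen short axis must be > 0, got {false_lumen_short_axis}"
        )
    return 0.5 * false_lumen_short_axis


def case_spec(case_id: int) -> CaseSpec:
    if not 1 <= case_id <= N_CASES:
        raise GeometryError(f"case_id must be 1..{N_CASES}, got {case_id}")
    dist = None if case_id == 1 else REENTRY_DISTANCES_MM[case_id - 2]
    return CaseSpec(case_id, dist)


def make_case(case_id: int, base: Optional[DissectionGeometry] = None) -> DissectionGeometry:
    """Geometry for scenario ``case_id``: case 1 has no re-entry tear; cases
    2-11 place a re-entry tear of width ``tear_width(false_lumen_short_axis)``
    at the case's distance from the false-lumen floor."""
    spec = case_spec(case_id)
    if base is None:
        base = default_geometry()
    if spec.re_entry_distance is None:
        return replace(base, re_entry=None)
    tear = ReEntryTear(
        distance_from_floor=spec.re_entry_distance,
        width=tear_width(base.false_lumen_short_axis),
    )
    return replace(base, re_entry=tear)


def partition_regions(dissected_length: float | DissectionGeometry,
                      n_regions: int = 6) -> np.ndarray:
    """Equal-length axial partition of the dissected segment into
    ``n_regions`` contiguous intervals; returns the n+1 bounds in mm."""
    if isinstance(dissected_length, DissectionGeometry):
        dissected_length = dissected_length.dissected_length
    if n_regions < 1:
        raise GeometryError(f"n_regions must be >= 1, got {n_regions}")
    return np.linspace(0.0, float(dissected_length), n_regions + 1)


def default_geometry() -> DissectionGeometry:
    return DissectionGeometry()


def case_table(base: Optional[DissectionGeometry] = None,
               case_ids: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Scenario table: case id, re-entry distance (NaN for case 1) and the
    tear width implied by the sizing rule."""
    if base is None:
        base = default_geometry()
    if case_ids is None:
        case_ids = range(1, N_CASES + 1)
    rows = []
    for cid in case_ids:
        spec = case_spec(cid)
        rows.append({
            "case_id": cid,
            "re_entry_distance_mm": (np.nan if spec.re_entry_distance is None
                                     else spec.re_entry_distance),
            "tear_width_mm": tear_width(base.false_lumen_short_axis),
        })
    return pd.DataFrame(rows)
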