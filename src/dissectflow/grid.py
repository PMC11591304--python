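"""Rasterization of the idealized dissection geometry onto a masked
Cartesian grid.

The grid is cell-centered and uniform; a cell is fluid when its center lies
inside the fluid region (stair-step masking).  The solver places unknowns on
a staggered (MAC) arrangement derived from this mask.  There is no randomness
anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .geometry import BranchSlot, DissectionGeometry, GeometryError

__all__ = ["ResolutionError", "MaskedGrid", "rasterize", "channel_grid"]

# lumen_label codes
SOLID, TRUE_LUMEN, FALSE_LUMEN, UNDISSECTED = 0, 1, 2, 3
LUMEN_NAMES = {TRUE_LUMEN: "true_lumen", FALSE_LUMEN: "false_lumen",
               UNDISSECTED: "undissected"}


class ResolutionError(GeometryError):
    """Raised when the grid spacing under-resolves a geometric feature."""


@dataclass
class MaskedGrid:
    """Masked uniform grid: ``fluid[i, j]`` over ``nx`` axial and ``ny``
    transverse cells, with lumen labels and tagged boundary openings.

    ``inlet_j`` / ``outlet_j`` are transverse indices of open cells on the
    first / last column; ``branch_faces`` maps each branch slot to the axial
    indices of its bottom-wall (y=0) faces.
    """

    spacing: float  # mm
    nx: int
    ny: int
    fluid: np.ndarray          # bool (nx, ny)
    lumen_label: np.ndarray    # uint8 (nx, ny), codes above
    inlet_j: np.ndarray
    outlet_j: np.ndarray
    branch_faces: tuple[tuple[BranchSlot, np.ndarray], ...]
    geom: Optional[DissectionGeometry] = None

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.spacing

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.spacing

    @property
    def n_fluid(self) -> int:
        return int(self.fluid.sum())

    def connected_to_inlet(self) -> bool:
        """Flood-fill check: every fluid cell reachable from the inlet."""
        labels, _ = ndimage.label(self.fluid)
        if self.inlet_j.size == 0:
            return False
        inlet_labels = set(labels[0, self.inlet_j]) - {0}
        reached = np.isin(labels, sorted(inlet_labels))
        return bool(np.array_equal(reached, self.fluid))

    def septum_rows(self) -> np.ndarray:
        """Transverse indices of cells whose centers lie in the septum band."""
        g = self.geom
        if g is None:
            return np.array([], dtype=int)
        y = self.y_centers
        lo = g.true_lumen_width
        hi = lo + g.septum_thickness
        return np.nonzero((y >= lo) & (y < hi))[0]

    def septum_openings(self) -> int:
        """Number of contiguous runs of open (fluid-through) septum columns."""
        rows = self.septum_rows()
        if rows.size == 0 or self.geom is None:
            return 0
        x = self.x_centers
        in_seg = (x >= self.geom.dissection_start) & (x < self.geom.dissection_end)
        open_col = in_seg & self.fluid[:, rows].all(axis=1)
        return int(np.count_nonzero(np.diff(open_col.astype(int)) == 1)
                   + (1 if open_col[0] else 0))


def _require_cells(n: int, name: str, minimum: int = 3) -> None:
    if n < minimum:
        raise ResolutionError(
            f"{name} spans only {n} cells (< {minimum}); refine the spacing"
        )


def rasterize(geom: DissectionGeometry, spacing: float) -> MaskedGrid:
    """Rasterize ``geom`` at uniform ``spacing`` (mm).

    The distal segment is extended by less than one cell so the outlet plane
    coincides with the last face of the uniform grid.  Raises
    :class:`ResolutionError` when a lumen or tear spans fewer than 3 cells or
    the septum vanishes from the mask.
    """
    if not spacing > 0:
        raise GeometryError(f"spacing must be > 0, got {spacing}")
    h = float(spacing)
    nx = int(np.ceil(geom.total_length / h - 1e-9))
    ny = int(np.ceil(geom.total_width / h - 1e-9))
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(x, y, indexing="ij")

    w_tl = geom.true_lumen_width
    sep_lo, sep_hi = w_tl, w_tl + geom.septum_thickness
    fl_hi = sep_hi + geom.false_lumen_short_axis
    xd0, xd1 = geom.dissection_start, geom.dissection_end
    in_seg = (X >= xd0) & (X < xd1)

    fluid = np.zeros((nx, ny), dtype=bool)
    fluid |= Y < w_tl                                   # TL runs inlet->outlet
    fluid |= in_seg & (Y >= sep_hi) & (Y < fl_hi)       # false lumen
    for span in (geom.entry_tear_span, geom.re_entry_span):
        if span is None:
            continue
        lo, hi = span
        fluid |= ((X >= xd0 + lo) & (X < xd0 + hi)
                  & (Y >= sep_lo) & (Y < sep_hi))

    lumen = np.zeros((nx, ny), dtype=np.uint8)
    lumen[fluid] = UNDISSECTED
    lumen[fluid & in_seg & (Y < w_tl)] = TRUE_LUMEN
    lumen[fluid & in_seg & (Y >= w_tl)] = FALSE_LUMEN

    # resolution preconditions: >= 3 cells across every lumen and tear
    _require_cells(int(np.count_nonzero(y < w_tl)), "true lumen")
    _require_cells(int(np.count_nonzero((y >= sep_hi) & (y < fl_hi))),
                   "false lumen")
    sep_rows = np.nonzero((y >= sep_lo) & (y < sep_hi))[0]
    _require_cells(sep_rows.size, "septum", minimum=1)
    lo, hi = geom.entry_tear_span
    _require_cells(int(np.count_nonzero((x >= xd0 + lo) & (x < xd0 + hi))),
                   "entry tear")
    if geom.re_entry_span is not None:
        lo, hi = geom.re_entry_span
        _require_cells(int(np.count_nonzero((x >= xd0 + lo) & (x < xd0 + hi))),
                       "re-entry tear")

    inlet_j = np.nonzero(fluid[0])[0]
    outlet_j = np.nonzero(fluid[-1])[0]
    branch_faces = []
    for slot in geom.branch_slots:
        lo, hi = slot.axial_position - slot.width / 2, slot.axial_position + slot.width / 2
        idx = np.nonzero((x >= lo) & (x < hi) & fluid[:, 0])[0]
        _require_cells(idx.size, f"branch slot at {slot.axial_position} mm",
                       minimum=1)
        branch_faces.append((slot, idx))

    grid = MaskedGrid(h, nx, ny, fluid, lumen, inlet_j, outlet_j,
                      tuple(branch_faces), geom)
    if not grid.connected_to_inlet():
        raise GeometryError("fluid region is not connected to the inlet")
    expected = 1 if geom.re_entry is None else 2
    n_open = grid.septum_openings()
    if n_open != expected:
        raise ResolutionError(
            f"septum has {n_open} openings, expected {expected}"
        )
    return grid


def channel_grid(length: float, width: float, spacing: float) -> MaskedGrid:
    """Plain rectangular channel (benchmark domain): fluid everywhere,
    pressure-driven end planes, no branch slots."""
    h = float(spacing)
    nx = int(np.ceil(length / h - 1e-9))
    ny = int(np.ceil(width / h - 1e-9))
    fluid = np.ones((nx, ny), dtype=bool)
    lumen = np.full((nx, ny), UNDISSECTED, dtype=np.uint8)
    j = np.arange(ny)
    return MaskedGrid(h, nx, ny, fluid, lumen, j, j, (), None)
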