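"""Variable-window local-maxima treetop detection on a smoothed CHM.

A cell is declared a treetop when it is at least ``min_height`` tall and no
valid cell within a height-dependent circular window is taller.  The window
radius grows linearly with the candidate's own (smoothed) height,
``radius = win_a * h + win_b`` — short trees are searched with a tight window,
tall trees with a wide one — which is the standard variable-window filter used
for individual tree detection in canopy height models.

Plateaus (equal-valued cells inside one window) are resolved deterministically:
only the first such cell in row-major order is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import Raster, TreeCandidate

__all__ = ["ItdParams", "window_radius", "detect_treetops"]


@dataclass
class ItdParams:
    """Parameters of the variable-window local-maxima filter.

    min_height: minimum candidate height in meters (cells below are never
        treetops).
    win_a, win_b: slope (unitless) and intercept (m) of the linear window
        function; the radius is evaluated at the candidate cell's own height.
    max_win_diameter: optional cap on the window diameter in meters.
    neighborhood: 'queen' (8-connected) or 'rook' (4-connected) minimum
        neighborhood; candidates must dominate at least this neighborhood even
        when the circular window is smaller than one cell.
    """

    min_height: float = 2.0
    win_a: float = 0.12
    win_b: float = 0.5
    max_win_diameter: Optional[float] = None
    neighborhood: str = "queen"

    def __post_init__(self) -> None:
        if self.min_height < 0:
            raise ValueError("min_height must be >= 0")
        if self.win_a * self.min_height + self.win_b <= 0:
            raise ValueError("window radius must be positive for h >= min_height")
        if self.neighborhood not in ("queen", "rook"):
            raise ValueError("neighborhood must be 'queen' or 'rook'")


def window_radius(h: float, params: ItdParams) -> float:
    """Search radius in meters for a candidate of height ``h``."""
    if h < 0:
        raise ValueError("height must be >= 0")
    r = params.win_a * h + params.win_b
    if params.max_win_diameter is not None:
        r = min(r, params.max_win_diameter / 2.0)
    return r


def _neighbor_offsets(neighborhood: str) -> list[tuple[int, int]]:
    if neighborhood == "queen":
        return [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    return [(-1, 0), (1, 0), (0, -1), (0, 1)]


def detect_treetops(chm: Raster, params: ItdParams | None = None) -> list[TreeCandidate]:
    """Find treetop cells of a (smoothed, building-clipped) CHM.

    Returns one candidate per treetop cell, positioned at the cell center and
    carrying the cell's CHM value as height; ids are ``t<k>`` in row-major
    order of the winning cells.  Nodata cells are ignored both as candidates
    and as competitors, so trees at clipped building edges remain detectable.
    An all-nodata raster yields an empty list.
    """
    params = params or ItdParams()
    z = chm.values
    valid = chm.valid_mask
    c = chm.cell_size
    n_rows, n_cols = z.shape

    cand = valid & (z >= params.min_height)
    if not cand.any():
        return []

    # Conservative prefilter: when every candidate's circular window covers
    # the full queen neighborhood (radius >= cell diagonal), a cell strictly
    # below a queen neighbor can never win; this prunes the slow check.
    min_radius = window_radius(params.min_height, params)
    if min_radius >= c * np.sqrt(2.0):
        neigh_max = ndimage.maximum_filter(
            np.where(valid, z, -np.inf), size=3, mode="constant", cval=-np.inf
        )
        cand &= z >= neigh_max

    offsets = _neighbor_offsets(params.neighborhood)
    out: list[TreeCandidate] = []
    k = 0
    for i, j in zip(*np.nonzero(cand)):
        h = z[i, j]
        r = window_radius(h, params)
        rc = max(int(np.floor(r / c)), 1)  # cells a radius can span (>= neighbors)
        i0, i1 = max(0, i - rc), min(n_rows, i + rc + 1)
        j0, j1 = max(0, j - rc), min(n_cols, j + rc + 1)
        block = z[i0:i1, j0:j1]
        bvalid = valid[i0:i1, j0:j1]
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        inwin = bvalid & (((ii - i) ** 2 + (jj - j) ** 2) * c**2 <= r**2 + 1e-12)
        # the window always includes at least the immediate neighborhood
        for di, dj in offsets:
            ni, nj = i + di, j + dj
            if 0 <= ni < n_rows and 0 <= nj < n_cols and valid[ni, nj]:
                inwin[ni - i0, nj - j0] = True
        if np.any(block[inwin] > h):
            continue
        # plateau rule: keep only the first equal-valued in-window cell
        eq = inwin & (block == h)
        if min(zip(ii[eq].tolist(), jj[eq].tolist())) != (i, j):
            continue
        x, y = chm.cell_center(i, j)
        out.append(
            TreeCandidate(id=f"t{k}", x=float(x), y=float(y), height=float(h), source="ALS")
        )
        k += 1
    return out
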