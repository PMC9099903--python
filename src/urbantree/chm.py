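"""Canopy height model construction from normalized point clouds.

Replicates the classic CHM workflow: grid the first returns at 0.25 m taking
the per-cell maximum height, smooth with a small mean filter to suppress
branch-level local maxima, and blank out cells under building footprints so
roofs cannot masquerade as canopy.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

from .core import PointCloud, Raster

__all__ = ["rasterize_chm", "smooth_chm", "clip_buildings"]


def rasterize_chm(
    cloud: PointCloud,
    cell_size: float = 0.25,
    extent: tuple[float, float, float, float] | None = None,
) -> Raster:
    """Grid a normalized cloud into a max-height raster.

    Parameters
    ----------
    cloud:
        Normalized point cloud (z = height above ground).
    cell_size:
        Cell edge in meters (default 0.25).
    extent:
        (xmin, ymin, xmax, ymax).  Defaults to the cloud's bounding box.
        Cells receiving no point are nodata, not zero: a no-return cell says
        nothing about the surface, and zero-filling would let street canyons
        manufacture spurious edges.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    xyz = cloud.xyz
    if extent is None:
        if len(cloud) == 0:
            raise ValueError("cannot infer extent from an empty cloud")
        xmin, ymin = xyz[:, 0].min(), xyz[:, 1].min()
        xmax, ymax = xyz[:, 0].max(), xyz[:, 1].max()
    else:
        xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent is degenerate")

    n_cols = int(np.ceil((xmax - xmin) / cell_size))
    n_rows = int(np.ceil((ymax - ymin) / cell_size))
    origin = (xmin, ymin + n_rows * cell_size)  # top-left corner (north-up)

    values = np.full((n_rows, n_cols), np.nan)
    if len(cloud):
        jj = np.floor((xyz[:, 0] - origin[0]) / cell_size).astype(int)
        ii = np.floor((origin[1] - xyz[:, 1]) / cell_size).astype(int)
        inside = (ii >= 0) & (ii < n_rows) & (jj >= 0) & (jj < n_cols)
        ii, jj, zz = ii[inside], jj[inside], xyz[inside, 2]
        flat = ii * n_cols + jj
        acc = np.full(n_rows * n_cols, -np.inf)
        np.maximum.at(acc, flat, zz)
        hit = np.isfinite(acc)
        values.ravel()[hit] = acc[hit]
    return Raster(origin, cell_size, values)


def smooth_chm(chm: Raster, window: int = 3) -> Raster:
    """Mean-filter a CHM, ignoring nodata and shrinking at the edges.

    Each valid cell becomes the mean of the valid cells in its
    ``window`` x ``window`` neighborhood (the neighborhood is clipped at the
    raster boundary); nodata cells stay nodata.  ``window`` must be odd so the
    kernel is centered; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    valid = chm.valid_mask
    filled = np.where(valid, chm.values, 0.0)
    # sum of valid values and count of valid cells per window, both with
    # zero-padding outside the raster so edge windows shrink naturally
    sums = ndimage.uniform_filter(filled, size=window, mode="constant") * window**2
    counts = ndimage.uniform_filter(valid.astype(float), size=window, mode="constant") * window**2
    counts = np.round(counts)
    out = np.full_like(chm.values, np.nan)
    ok = valid & (counts > 0)
    out[ok] = sums[ok] / counts[ok]
    return Raster(chm.origin, chm.cell_size, out, chm.nodata)


def clip_buildings(chm: Raster, buildings: Sequence[BaseGeometry]) -> Raster:
    """Set cells whose center lies inside (or on) a building footprint to nodata.

    Cell-center containment is used rather than any-overlap: it is
    deterministic, cheap, and the convention applied throughout the package.
    """
    out = chm.copy()
    if not buildings:
        return out
    for geom in buildings:
        if not geom.is_valid:
            raise ValueError("invalid building polygon geometry")
    X, Y = chm.center_grids()
    covered = np.zeros(chm.values.shape, dtype=bool)
    for geom in buildings:
        # covers = contains or touches the boundary
        covered |= shapely.intersects_xy(geom, X, Y)
    out.values[covered] = np.nan
    return out
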