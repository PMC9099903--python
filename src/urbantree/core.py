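"""Core domain types shared across the inventory pipeline.

Coordinates are planar (local easting/northing in meters); rasters follow the
north-up convention with row 0 at the top, and cell (i, j) covering the
half-open square [x0 + j*c, x0 + (j+1)*c) x (y0 - (i+1)*c, y0 - i*c], where
(x0, y0) is the top-left corner and c the cell size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Raster",
    "PointCloud",
    "TreeCandidate",
    "PanoStation",
    "Detection",
    "GeoObservation",
]


@dataclass
class Raster:
    """Single-band georeferenced grid (CHM or ortho band).

    ``values`` is row-major with row 0 at the north edge.  ``nodata`` cells are
    stored as NaN internally regardless of the declared sentinel, so validity
    is always ``np.isfinite(values)``.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not np.isnan(self.nodata):
            self.values = np.where(
                self.values == self.nodata, np.nan, self.values
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell (i, j) containing (x, y) under the half-open convention.

        x belongs to [left, right): closed on the west edge.  y belongs to
        (bottom, top]: closed on the north edge, so a point on a horizontal
        cell boundary is assigned to the cell below that edge's top.
        """
        x0, y0 = self.origin
        # floor realizes both half-open rules: a point on a vertical edge goes
        # to the cell whose west edge it is; a point on a horizontal edge has
        # integral dy = k and row k's closed top edge is exactly dy == k.
        j = int(np.floor((x - x0) / self.cell_size))
        i = int(np.floor((y0 - y) / self.cell_size))
        return i, j

    def contains_index(self, i: int, j: int) -> bool:
        return 0 <= i < self.n_rows and 0 <= j < self.n_cols

    def cell_center(self, i: np.ndarray | int, j: np.ndarray | int):
        x0, y0 = self.origin
        x = x0 + (np.asarray(j) + 0.5) * self.cell_size
        y = y0 - (np.asarray(i) + 0.5) * self.cell_size
        return x, y

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of every cell-center coordinate, shaped like values."""
        ii, jj = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_center(ii, jj)

    def copy(self) -> "Raster":
        return Raster(self.origin, self.cell_size, self.values.copy(), self.nodata)


@dataclass
class PointCloud:
    """Normalized point cloud: z is height above ground (>= 0)."""

    xyz: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if self.xyz.size and not np.all(np.isfinite(self.xyz)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.xyz.size and np.any(self.xyz[:, 2] < 0):
            raise ValueError("normalized heights must be >= 0")

    def __len__(self) -> int:
        return self.xyz.shape[0]


@dataclass
class TreeCandidate:
    """A putative tree point produced by any pipeline stage."""

    id: str
    x: float
    y: float
    height: Optional[float] = None
    source: str = "unknown"  # ALS | GSV | merged | filtered

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)

    def moved_to(self, x: float, y: float, source: Optional[str] = None) -> "TreeCandidate":
        return replace(self, x=x, y=y, source=source or self.source)


def candidate_array(candidates: Sequence[TreeCandidate]) -> np.ndarray:
    """(n, 2) array of candidate positions (empty-safe)."""
    if not candidates:
        return np.empty((0, 2))
    return np.array([[c.x, c.y] for c in candidates], dtype=float)


@dataclass
class PanoStation:
    """Panorama capture point with camera geometry.

    heading is degrees clockwise from north; pitch is the camera tilt
    (0 = level, positive up); hfov/vfov are the angular extents of the image.
    """

    id: str
    x: float
    y: float
    heading: float = 0.0
    pitch: float = 0.0
    hfov: float = 360.0
    vfov: float = 90.0
    img_width: int = 2048
    img_height: int = 1024
    camera_height: float = 2.5
    capture_date: str = ""

    def __post_init__(self) -> None:
        if self.img_width <= 0 or self.img_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.camera_height <= 0:
            raise ValueError("camera height must be positive")


@dataclass
class Detection:
    """Per-image detection of a tree stem base (or crown) in pixel space.

    u is the column from the left edge, v the row from the top.
    """

    station_id: str
    u: float
    v: float
    kind: str = "stem"  # stem | crown
    confidence: float = 1.0


@dataclass
class GeoObservation:
    """A detection converted to a bearing/distance/position observation."""

    station_id: str
    bearing: float  # degrees clockwise from north
    distance: float  # meters
    position: tuple[float, float]

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("observation distance must be positive")
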