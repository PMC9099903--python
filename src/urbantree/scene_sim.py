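"""Seeded synthetic urban scenes with known ground truth.

Emulates the data sources a city-scale tree inventory consumes — a normalized
ALS point cloud, a seven-band ortho stack, street-level panorama stations
with per-image tree detections, building footprints — over a configurable
layout of street and park trees, so every pipeline stage can be tested
end-to-end against exact truth.

Randomness: every artifact (tree layout, point cloud, ortho pixels, spectral
samples, detections) draws from its own child stream of the scene seed, so
artifacts can be regenerated independently and deterministically.

What the generator deliberately does NOT model: terrain relief (ground is
flat at z = 0), photorealistic imagery, tree-against-tree occlusion
(buildings do occlude; trees do not, unless enabled), and seasonal/spectral
variability beyond per-class Gaussian band values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Point, box
from shapely.geometry.base import BaseGeometry

from .core import Detection, GeoObservation, PanoStation, PointCloud, Raster, TreeCandidate
from .spectral import BAND_NAMES, NOT_TREE, TREE, OrthoStack
from . import street_geoloc

__all__ = [
    "SceneConfig",
    "Tree",
    "SyntheticScene",
    "generate_scene",
    "render_point_cloud",
    "render_ortho",
    "simulate_detections",
    "SceneDetector",
    "default_spectral_params",
    "demo_city_config",
]

# child-stream tags (spawn keys) per artifact
_STREAMS = {"layout": 1, "cloud": 2, "ortho": 3, "labels": 4, "detections": 5}


def default_spectral_params() -> dict[str, dict[str, list[float]]]:
    """Well-separated per-class band statistics (cleanly classifiable).

    Vegetation is green and NIR-bright; sealed surfaces are grey and
    NIR-dark.  Class means are many standard deviations apart on the NIR
    band, so a threshold classifier has essentially zero Bayes error.
    """
    return {
        TREE: {"mean": [60, 120, 60, 58, 122, 62, 180], "sd": [5, 5, 5, 5, 5, 5, 5]},
        NOT_TREE: {"mean": [120, 112, 105, 118, 114, 108, 60], "sd": [5, 5, 5, 5, 5, 5, 5]},
    }


@dataclass
class SceneConfig:
    """Scene layout, sensor, and noise parameters.

    Distances in meters; densities in stated units.  ``street_axes`` are
    polylines (lists of vertices); street trees sit at arc-length multiples of
    ``street_tree_spacing`` from the polyline start plus the final endpoint,
    offset laterally by ``street_tree_offset`` to the left of the direction of
    travel.  Stations run along the same axes every ``station_spacing``,
    starting half a spacing in.
    """

    area_width: float = 200.0
    area_height: float = 200.0
    street_axes: list[list[tuple[float, float]]] = field(default_factory=list)
    street_tree_spacing: float = 10.0
    street_tree_offset: float = 3.0
    park_tree_density: float = 0.0  # trees per hectare
    min_tree_spacing: float = 4.0
    height_range: tuple[float, float] = (6.0, 15.0)
    crown_radius_range: tuple[float, float] = (1.5, 3.0)
    building_rects: list[tuple[float, float, float, float]] = field(default_factory=list)
    building_height: float = 8.0
    pole_count: int = 0  # tall thin non-tree clutter (ALS false positives)
    pole_height: float = 8.0
    pole_radius: float = 0.5
    station_spacing: float = 15.0
    point_density: float = 14.0  # first returns per square meter
    cloud_noise_sd: float = 0.1  # additive, clipped to +-0.5 m
    bearing_noise_sd: float = 0.0  # degrees
    distance_noise_sd: float = 0.0  # meters
    detection_miss_rate: float = 0.0
    false_detection_rate: float = 0.0  # expected spurious detections per image
    max_detection_range: float = 40.0
    spectral_params: dict = field(default_factory=default_spectral_params)
    n_training_points: int = 2000
    camera_height: float = 2.5
    pixel_model: str = "equirect"
    img_width: int = 2048
    img_height: int = 1024
    hfov: float = 360.0
    vfov: float = 90.0
    cell_size: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_width <= 0 or self.area_height <= 0:
            raise ValueError("scene area must be positive")
        for lo, hi in (self.height_range, self.crown_radius_range):
            if lo > hi or lo <= 0:
                raise ValueError("ranges must satisfy 0 < min <= max")
        if not 0 <= self.detection_miss_rate <= 1:
            raise ValueError("detection_miss_rate must be in [0, 1]")
        if self.min_tree_spacing <= 0 or self.street_tree_spacing <= 0:
            raise ValueError("spacings must be positive")
        for cls in (TREE, NOT_TREE):
            if cls not in self.spectral_params:
                raise ValueError(f"spectral_params missing class {cls}")

    def rng(self, artifact: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[artifact]])


def demo_city_config(seed: int = 0) -> SceneConfig:
    """A 200 m x 200 m benchmark district: four streets, ~100 street trees.

    Zero detection noise, one expected spurious detection per two images
    worth of clutter (false_detection_rate = 2 per image across ~50 images),
    six pole-like non-tree objects and two building blocks set back from the
    streets.  Used by the examples and the reproduction script.
    """
    return SceneConfig(
        area_width=200.0,
        area_height=200.0,
        street_axes=[
            [(0.0, 25.0), (200.0, 25.0)],
            [(0.0, 75.0), (200.0, 75.0)],
            [(0.0, 125.0), (200.0, 125.0)],
            [(0.0, 175.0), (200.0, 175.0)],
        ],
        street_tree_spacing=7.5,
        building_rects=[(40.0, 40.0, 90.0, 60.0), (120.0, 140.0, 170.0, 160.0)],
        pole_count=6,
        false_detection_rate=2.0,
        seed=seed,
    )


@dataclass
class Tree:
    id: str
    x: float
    y: float
    height: float
    crown_radius: float
    zone: str  # street | park


@dataclass
class SyntheticScene:
    """Ground truth plus (optionally rendered) sensor artifacts."""

    config: SceneConfig
    trees: list[Tree]
    buildings: list[BaseGeometry]
    stations: list[PanoStation]
    poles: list[tuple[float, float]] = field(default_factory=list)
    point_cloud: Optional[PointCloud] = None
    ortho: Optional[OrthoStack] = None
    truth_labels: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.config.area_width, self.config.area_height)

    def truth_positions(self, zone: Optional[str] = None) -> np.ndarray:
        sel = [t for t in self.trees if zone is None or t.zone == zone]
        if not sel:
            return np.empty((0, 2))
        return np.array([[t.x, t.y] for t in sel])


def _polyline_walk(vertices: Sequence[tuple[float, float]], spacing: float, offset: float) -> list[tuple[float, float, float]]:
    """Points every ``spacing`` along a polyline starting at arc ``offset``.

    Returns (x, y, segment bearing degrees).  The final endpoint is always
    included when ``offset`` is 0 (both-endpoint convention for tree rows).
    """
    pts = np.asarray(vertices, dtype=float)
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    if total <= 0:
        return []
    targets = list(np.arange(offset, total + 1e-9, spacing))
    if offset == 0 and (not targets or total - targets[-1] > 1e-9):
        targets.append(total)
    out = []
    for s in targets:
        acc = 0.0
        for k in range(len(seg)):
            if s <= acc + seglen[k] + 1e-12:
                f = (s - acc) / seglen[k] if seglen[k] else 0.0
                x, y = pts[k] + f * seg[k]
                bearing = math.degrees(math.atan2(seg[k, 0], seg[k, 1])) % 360.0
                out.append((float(x), float(y), bearing))
                break
            acc += seglen[k]
    return out


def generate_scene(config: SceneConfig, render: bool = True) -> SyntheticScene:
    """Build a scene: trees, buildings, stations, labels (+ cloud/ortho).

    Street trees first (deterministic placement along each axis), then
    Poisson park trees thinned to ``min_tree_spacing``; any tree whose center
    falls inside a building rectangle is discarded.  With ``render=False``
    the point cloud and ortho stack are left unrendered (faster for tests
    that only need the layout); call :func:`render_point_cloud` /
    :func:`render_ortho` to fill them in later.
    """
    rng = config.rng("layout")
    buildings = [box(*rect) for rect in config.building_rects]

    trees: list[Tree] = []

    def admissible(x: float, y: float) -> bool:
        if not (0 <= x <= config.area_width and 0 <= y <= config.area_height):
            return False
        if any(b.covers(Point(x, y)) for b in buildings):
            return False
        return all(
            math.hypot(t.x - x, t.y - y) >= config.min_tree_spacing for t in trees
        )

    for axis in config.street_axes:
        for x, y, bearing in _polyline_walk(axis, config.street_tree_spacing, 0.0):
            # offset to the left of the direction of travel; snap the tiny
            # trigonometric residue so boundary trees stay inside the area
            b = math.radians(bearing)
            ox = round(x - config.street_tree_offset * math.cos(b), 9)
            oy = round(y + config.street_tree_offset * math.sin(b), 9)
            if admissible(ox, oy):
                h = rng.uniform(*config.height_range)
                r = rng.uniform(*config.crown_radius_range)
                trees.append(Tree(f"T{len(trees)}", ox, oy, h, r, "street"))

    if config.park_tree_density > 0:
        area_ha = config.area_width * config.area_height / 1e4
        n = rng.poisson(config.park_tree_density * area_ha)
        xs = rng.uniform(0, config.area_width, n)
        ys = rng.uniform(0, config.area_height, n)
        hs = rng.uniform(*config.height_range, n)
        rs = rng.uniform(*config.crown_radius_range, n)
        for x, y, h, r in zip(xs, ys, hs, rs):
            if admissible(x, y):
                trees.append(Tree(f"T{len(trees)}", float(x), float(y), float(h), float(r), "park"))

    poles: list[tuple[float, float]] = []
    attempts = 0
    while len(poles) < config.pole_count and attempts < 100 * max(config.pole_count, 1):
        attempts += 1
        x = float(rng.uniform(0, config.area_width))
        y = float(rng.uniform(0, config.area_height))
        # poles stand clear of crowns so they read as distinct ALS objects
        if any(math.hypot(t.x - x, t.y - y) < t.crown_radius + 2.0 for t in trees):
            continue
        if any(b.covers(Point(x, y)) for b in buildings):
            continue
        if any(math.hypot(px - x, py - y) < config.min_tree_spacing for px, py in poles):
            continue
        poles.append((x, y))

    stations: list[PanoStation] = []
    for axis in config.street_axes:
        for x, y, bearing in _polyline_walk(
            axis, config.station_spacing, config.station_spacing / 2.0
        ):
            stations.append(
                PanoStation(
                    id=f"S{len(stations)}",
                    x=x,
                    y=y,
                    heading=bearing,
                    pitch=0.0,
                    hfov=config.hfov,
                    vfov=config.vfov,
                    img_width=config.img_width,
                    img_height=config.img_height,
                    camera_height=config.camera_height,
                )
            )

    scene = SyntheticScene(config=config, trees=trees, buildings=buildings, stations=stations, poles=poles)
    scene.truth_labels = _sample_truth_labels(scene)
    if render:
        scene.point_cloud = render_point_cloud(scene)
        scene.ortho = render_ortho(scene)
    return scene


def _sample_truth_labels(scene: SyntheticScene) -> list[tuple[float, float, str]]:
    """Labelled spectral sample points, half on crowns, half off."""
    cfg = scene.config
    rng = cfg.rng("labels")
    n_each = cfg.n_training_points // 2
    labels: list[tuple[float, float, str]] = []
    if scene.trees:
        idx = rng.integers(0, len(scene.trees), n_each)
        for i in idx:
            t = scene.trees[i]
            r = t.crown_radius * 0.6 * math.sqrt(rng.uniform())
            a = rng.uniform(0, 2 * math.pi)
            x = min(max(t.x + r * math.cos(a), 0.0), cfg.area_width)
            y = min(max(t.y + r * math.sin(a), 0.0), cfg.area_height)
            labels.append((x, y, TREE))
    got = 0
    while got < n_each:
        x = float(rng.uniform(0, cfg.area_width))
        y = float(rng.uniform(0, cfg.area_height))
        if any(math.hypot(t.x - x, t.y - y) <= t.crown_radius + 1.0 for t in scene.trees):
            continue
        labels.append((x, y, NOT_TREE))
        got += 1
    return labels


def render_point_cloud(scene: SyntheticScene, density: Optional[float] = None) -> PointCloud:
    """Sample first returns over the scene at the requested density.

    Planimetric positions are uniform over the area; the return height is the
    synthetic surface under the point — a paraboloid crown
    z(r) = h (1 - (r/R)^2) for each tree (max over overlapping crowns), flat
    roofs over building rectangles, cylinders for poles, ground at 0
    elsewhere — with additive Gaussian noise (sd ``cloud_noise_sd``, clipped
    to +-0.5 m) on non-ground returns only, floored at 0.
    """
    cfg = scene.config
    density = cfg.point_density if density is None else density
    if density <= 0:
        raise ValueError("point density must be positive")
    rng = cfg.rng("cloud")
    n = int(round(density * cfg.area_width * cfg.area_height))
    xy = rng.uniform((0, 0), (cfg.area_width, cfg.area_height), (n, 2))
    z = np.zeros(n)

    if n:
        from scipy.spatial import cKDTree

        kd = cKDTree(xy)
        for t in scene.trees:
            idx = kd.query_ball_point([t.x, t.y], t.crown_radius)
            if not idx:
                continue
            idx = np.asarray(idx)
            rr = np.hypot(xy[idx, 0] - t.x, xy[idx, 1] - t.y)
            surf = t.height * (1.0 - (rr / t.crown_radius) ** 2)
            z[idx] = np.maximum(z[idx], surf)
        for px, py in scene.poles:
            idx = kd.query_ball_point([px, py], cfg.pole_radius)
            if idx:
                z[np.asarray(idx)] = np.maximum(z[np.asarray(idx)], cfg.pole_height)
        for b, rect in zip(scene.buildings, cfg.building_rects):
            xmin, ymin, xmax, ymax = rect
            inside = (
                (xy[:, 0] >= xmin) & (xy[:, 0] <= xmax)
                & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax)
            )
            z[inside] = np.maximum(z[inside], cfg.building_height)

        nonground = z > 0
        noise = np.clip(rng.normal(0, cfg.cloud_noise_sd, nonground.sum()), -0.5, 0.5)
        z[nonground] = np.maximum(z[nonground] + noise, 0.0)
    return PointCloud(np.column_stack([xy, z]))


def render_ortho(scene: SyntheticScene) -> OrthoStack:
    """Draw the seven-band ortho stack from the per-class spectra.

    Every pixel whose center lies under a tree crown disc draws from the TREE
    distribution; all other pixels (ground, roofs, poles) from NOT-TREE.
    """
    cfg = scene.config
    rng = cfg.rng("ortho")
    c = cfg.cell_size
    n_cols = int(math.ceil(cfg.area_width / c))
    n_rows = int(math.ceil(cfg.area_height / c))
    origin = (0.0, n_rows * c)

    jj = np.arange(n_cols)
    ii = np.arange(n_rows)
    cx = origin[0] + (jj + 0.5) * c
    cy = origin[1] - (ii + 0.5) * c

    tree_mask = np.zeros((n_rows, n_cols), dtype=bool)
    for t in scene.trees:
        j0 = max(0, int((t.x - t.crown_radius) / c) - 1)
        j1 = min(n_cols, int((t.x + t.crown_radius) / c) + 2)
        i0 = max(0, int((origin[1] - t.y - t.crown_radius) / c) - 1)
        i1 = min(n_rows, int((origin[1] - t.y + t.crown_radius) / c) + 2)
        if i0 >= i1 or j0 >= j1:
            continue
        dx = cx[j0:j1] - t.x
        dy = cy[i0:i1] - t.y
        tree_mask[i0:i1, j0:j1] |= (
            dy[:, None] ** 2 + dx[None, :] ** 2 <= t.crown_radius**2
        )

    bands: dict[str, Raster] = {}
    tree_p = scene.config.spectral_params[TREE]
    off_p = scene.config.spectral_params[NOT_TREE]
    for k, name in enumerate(BAND_NAMES):
        vals = rng.normal(off_p["mean"][k], off_p["sd"][k], (n_rows, n_cols))
        n_tree = int(tree_mask.sum())
        if n_tree:
            vals[tree_mask] = rng.normal(tree_p["mean"][k], tree_p["sd"][k], n_tree)
        bands[name] = Raster(origin, c, vals)
    return OrthoStack(bands)


def _visible(scene: SyntheticScene, station: PanoStation, x: float, y: float) -> bool:
    """Line of sight blocked iff the station-target segment crosses a building."""
    if not scene.buildings:
        return True
    seg = LineString([(station.x, station.y), (x, y)])
    return not any(seg.intersects(b) for b in scene.buildings)


def simulate_detections(scene: SyntheticScene) -> list[Detection]:
    """Per-image stem-base detections for all visible trees, plus clutter.

    For each station, every tree within ``max_detection_range`` and not
    occluded by a building yields a detection with probability
    (1 - detection_miss_rate); its pixels are the exact inverse of the
    pixel-to-bearing / pixel-to-distance model applied to the true bearing
    and distance plus the configured Gaussian noise, so locating the
    detections at zero noise reproduces the true positions.  Spurious
    detections (expected ``false_detection_rate`` per image, Poisson) are
    placed at random bearing/distance within the camera's reach.
    """
    cfg = scene.config
    rng = cfg.rng("detections")
    model = cfg.pixel_model
    out: list[Detection] = []
    for station in scene.stations:
        for t in scene.trees:
            d = math.hypot(t.x - station.x, t.y - station.y)
            if d <= 0 or d > cfg.max_detection_range:
                continue
            if not _visible(scene, station, t.x, t.y):
                continue
            if cfg.detection_miss_rate and rng.uniform() < cfg.detection_miss_rate:
                continue
            bearing = math.degrees(math.atan2(t.x - station.x, t.y - station.y)) % 360.0
            if cfg.bearing_noise_sd:
                bearing = (bearing + rng.normal(0, cfg.bearing_noise_sd)) % 360.0
            dist = d
            if cfg.distance_noise_sd:
                dist = max(d + rng.normal(0, cfg.distance_noise_sd), 0.5)
            try:
                u = street_geoloc.bearing_to_pixel(station, bearing, model)
                v = street_geoloc.distance_to_pixel(station, dist)
            except ValueError:
                continue  # out of the field of view or off-image
            out.append(Detection(station_id=station.id, u=u, v=v, kind="stem"))
        if cfg.false_detection_rate:
            for _ in range(int(rng.poisson(cfg.false_detection_rate))):
                bearing = station.heading + rng.uniform(-0.5, 0.5) * station.hfov
                dist = rng.uniform(3.0, cfg.max_detection_range)
                try:
                    u = street_geoloc.bearing_to_pixel(station, bearing % 360.0, model)
                    v = street_geoloc.distance_to_pixel(station, dist)
                except ValueError:
                    continue
                out.append(Detection(station_id=station.id, u=u, v=v, kind="stem"))
    return out


class SceneDetector:
    """Stage-2A detector contract backed by the synthetic detections.

    Precomputes every station's geolocated observations once; a query for
    (station, candidate) returns that station's observation nearest to the
    candidate if it lies within ``match_radius`` (default: the 4 m
    consistency distance), else None — i.e. "was anything detected near this
    position in this image?".
    """

    def __init__(
        self,
        scene: SyntheticScene,
        detections: Optional[Sequence[Detection]] = None,
        match_radius: float = 4.0,
    ) -> None:
        self.match_radius = match_radius
        dets = list(detections) if detections is not None else simulate_detections(scene)
        by_station = {s.id: s for s in scene.stations}
        self._obs: dict[str, list[GeoObservation]] = {s.id: [] for s in scene.stations}
        model = scene.config.pixel_model
        for det in dets:
            st = by_station[det.station_id]
            try:
                obs = street_geoloc.observe(st, det, model)
            except street_geoloc.HorizonError:
                continue
            self._obs[st.id].append(obs)

    def __call__(self, station: PanoStation, candidate: TreeCandidate) -> Optional[GeoObservation]:
        best, best_d = None, self.match_radius
        for obs in self._obs.get(station.id, []):
            d = math.hypot(obs.position[0] - candidate.x, obs.position[1] - candidate.y)
            if d < best_d:
                best, best_d = obs, d
        return best
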