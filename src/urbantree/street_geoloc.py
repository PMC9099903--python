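"""Tree geolocation from street-level imagery detections.

Stage 1A turns each per-image stem detection into a map position with plain
trigonometry: the pixel column gives the bearing (camera heading plus the
in-image angle), and the pixel row of the stem *base* gives the distance under
a flat-ground model — the base sits below the horizon by a depression angle
delta, and a camera of known height h sees it at distance h / tan(delta).

Stage 2A is the image-consistency false-positive check: a candidate survives
only if the detector finds it in each of the k (default 3) panoramas nearest
to it and the k estimated positions agree pairwise to within a consistency
distance (default 4 m); survivors are repositioned at the centroid of the k
positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .core import Detection, GeoObservation, PanoStation, TreeCandidate

__all__ = [
    "VerifyParams",
    "pixel_to_bearing",
    "bearing_to_pixel",
    "pixel_to_distance",
    "distance_to_pixel",
    "project_observation",
    "locate_trees",
    "verify_candidates",
    "HorizonError",
]

logger = logging.getLogger(__name__)

#: detector contract for stage 2A: given a station and a candidate, report the
#: observation of that candidate in the station's image, or None if the image
#: contains no matching detection.
DetectorFn = Callable[[PanoStation, TreeCandidate], Optional[GeoObservation]]


class HorizonError(ValueError):
    """Stem base at or above the horizon: no flat-ground distance exists."""


@dataclass
class VerifyParams:
    """Stage 2A image-consistency check parameters.

    k_images: number of nearest panoramas that must agree (default 3).
    consistency_distance: maximum pairwise distance in meters among the k
        estimated positions (default 4).
    require_all: if True (default) the candidate must be detected in all k
        images; if False, missing detections are tolerated as long as at
        least two positions remain to check.
    """

    k_images: int = 3
    consistency_distance: float = 4.0
    require_all: bool = True

    def __post_init__(self) -> None:
        if self.k_images < 2:
            raise ValueError("k_images must be >= 2")
        if self.consistency_distance <= 0:
            raise ValueError("consistency_distance must be positive")


def pixel_to_bearing(station: PanoStation, u: float, model: str = "perspective") -> float:
    """Bearing (degrees clockwise from north) of image column ``u``.

    perspective (rectilinear): bearing = heading + atan((2u/W - 1) tan(hfov/2))
    equirect (panoramic):      bearing = heading + (u/W - 1/2) hfov
    """
    if not 0 <= u < station.img_width:
        raise ValueError("pixel column outside the image")
    frac = u / station.img_width
    if model == "perspective":
        if station.hfov >= 180:
            raise ValueError("perspective model requires hfov < 180 degrees")
        off = math.degrees(math.atan((2 * frac - 1) * math.tan(math.radians(station.hfov / 2))))
    elif model == "equirect":
        off = (frac - 0.5) * station.hfov
    else:
        raise ValueError(f"unknown pixel model {model!r}")
    return (station.heading + off) % 360.0


def bearing_to_pixel(station: PanoStation, bearing: float, model: str = "perspective") -> float:
    """Inverse of :func:`pixel_to_bearing`; raises if outside the field of view."""
    off = (bearing - station.heading + 180.0) % 360.0 - 180.0
    if model == "perspective":
        if station.hfov >= 180:
            raise ValueError("perspective model requires hfov < 180 degrees")
        if abs(off) > station.hfov / 2:
            raise ValueError("bearing outside the field of view")
        frac = (math.tan(math.radians(off)) / math.tan(math.radians(station.hfov / 2)) + 1) / 2
    elif model == "equirect":
        if abs(off) > station.hfov / 2:
            raise ValueError("bearing outside the field of view")
        frac = off / station.hfov + 0.5
    else:
        raise ValueError(f"unknown pixel model {model!r}")
    return min(frac * station.img_width, station.img_width - 1e-9) % station.img_width


def pixel_to_distance(station: PanoStation, v: float) -> float:
    """Flat-ground distance to a stem base imaged at row ``v`` (from the top).

    The depression angle below the optical axis is
    delta = -pitch + atan((2v/H - 1) tan(vfov/2)); a base at or above the
    horizon (delta <= 0) has no flat-ground distance and raises
    :class:`HorizonError`.
    """
    if not 0 <= v < station.img_height:
        raise ValueError("pixel row outside the image")
    frac = v / station.img_height
    delta = -station.pitch + math.degrees(
        math.atan((2 * frac - 1) * math.tan(math.radians(station.vfov / 2)))
    )
    if delta <= 0:
        raise HorizonError("stem base at or above the horizon")
    return station.camera_height / math.tan(math.radians(delta))


def distance_to_pixel(station: PanoStation, distance: float) -> float:
    """Inverse of :func:`pixel_to_distance`; raises if the row falls off-image."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    delta = math.degrees(math.atan(station.camera_height / distance))
    t = math.tan(math.radians(delta + station.pitch)) / math.tan(math.radians(station.vfov / 2))
    v = (t + 1) / 2 * station.img_height
    if not 0 <= v <= station.img_height:
        raise ValueError("stem base row outside the image")
    return min(v, station.img_height - 1e-9)  # bottom edge maps to the last row


def project_observation(station: PanoStation, bearing: float, distance: float) -> tuple[float, float]:
    """Map position of an object at (bearing, distance) from the station."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    b = math.radians(bearing)
    return (station.x + distance * math.sin(b), station.y + distance * math.cos(b))


def observe(station: PanoStation, det: Detection, model: str = "perspective") -> GeoObservation:
    """Convert one detection into a bearing/distance/position observation."""
    bearing = pixel_to_bearing(station, det.u, model)
    distance = pixel_to_distance(station, det.v)
    return GeoObservation(
        station_id=station.id,
        bearing=bearing,
        distance=distance,
        position=project_observation(station, bearing, distance),
    )


def locate_trees(
    stations: Sequence[PanoStation],
    detections: Sequence[Detection],
    model: str = "perspective",
) -> list[TreeCandidate]:
    """Stage 1A: one candidate per usable stem detection.

    Detections whose stem base sits at or above the horizon cannot be ranged
    and are dropped (counted in the log).  Duplicates from the same tree seen
    in several images are NOT resolved here; that is the merging step's job.
    """
    by_id: Mapping[str, PanoStation] = {s.id: s for s in stations}
    out: list[TreeCandidate] = []
    dropped = 0
    k = 0
    for det in detections:
        if det.kind != "stem":
            continue
        try:
            station = by_id[det.station_id]
        except KeyError:
            raise KeyError(f"detection references unknown station {det.station_id!r}")
        try:
            obs = observe(station, det, model)
        except HorizonError:
            dropped += 1
            continue
        out.append(
            TreeCandidate(id=f"g{k}", x=obs.position[0], y=obs.position[1], source="GSV")
        )
        k += 1
    if dropped:
        logger.info("locate_trees: dropped %d detections at/above the horizon", dropped)
    return out


def verify_candidates(
    candidates: Sequence[TreeCandidate],
    stations: Sequence[PanoStation],
    detector: DetectorFn,
    params: VerifyParams | None = None,
) -> list[TreeCandidate]:
    """Stage 2A: keep candidates confirmed by their k nearest panoramas.

    For each candidate the k nearest stations (planar distance, ties broken by
    station id ascending) are queried through ``detector``.  The candidate is
    kept iff every queried image yields an observation (when ``require_all``)
    and all pairwise distances among the observed positions are below
    ``consistency_distance``; kept candidates are repositioned at the
    arithmetic centroid of the observed positions, with source "filtered".
    """
    params = params or VerifyParams()
    if len(stations) < params.k_images:
        raise ValueError(
            f"need at least {params.k_images} stations, have {len(stations)}"
        )
    out: list[TreeCandidate] = []
    for cand in candidates:
        ranked = sorted(
            stations, key=lambda s: (math.hypot(s.x - cand.x, s.y - cand.y), s.id)
        )
        nearest = ranked[: params.k_images]
        positions = []
        missing = 0
        for st in nearest:
            obs = detector(st, cand)
            if obs is None:
                missing += 1
            else:
                positions.append(obs.position)
        if params.require_all and missing:
            continue
        if len(positions) < 2:
            continue
        pts = np.asarray(positions)
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        if d.max() >= params.consistency_distance:
            continue
        cx, cy = pts.mean(axis=0)
        out.append(cand.moved_to(float(cx), float(cy), source="filtered"))
    return out
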