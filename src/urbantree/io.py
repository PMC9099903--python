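"""File formats: GeoJSON points/polygons, CSV tables, XYZ clouds, TIFF+TFW rasters.

Rasters are written as plain TIFF with an ESRI world file (.tfw) carrying the
georeferencing and the nodata value stored in the TIFF ImageDescription tag —
the same TIFF + TFW delivery convention used by national ortho programmes.
Coordinates are planar; no CRS metadata is attached.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .core import Detection, PanoStation, PointCloud, Raster, TreeCandidate

__all__ = [
    "write_raster",
    "read_raster",
    "write_xyz",
    "read_xyz",
    "write_candidates_geojson",
    "read_candidates_geojson",
    "write_candidates_csv",
    "write_polygons_geojson",
    "read_polygons_geojson",
    "write_stations_csv",
    "read_stations_csv",
    "write_detections_csv",
    "read_detections_csv",
    "write_yaml",
    "read_yaml",
]


# --- rasters -----------------------------------------------------------------

def write_raster(path: str | Path, raster: Raster, nodata: float = -9999.0) -> None:
    """TIFF + sidecar .tfw world file; nodata encoded in ImageDescription."""
    path = Path(path)
    vals = np.where(raster.valid_mask, raster.values, nodata).astype(np.float32)
    tifffile.imwrite(path, vals, description=json.dumps({"nodata": nodata}))
    c = raster.cell_size
    x0, y0 = raster.origin
    # world file lines: x-scale, rot, rot, y-scale, center-x, center-y of cell (0,0)
    tfw = [c, 0.0, 0.0, -c, x0 + c / 2.0, y0 - c / 2.0]
    path.with_suffix(".tfw").write_text("\n".join(f"{v:.10f}" for v in tfw) + "\n")


def read_raster(path: str | Path) -> Raster:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        vals = tf.asarray().astype(float)
        desc = tf.pages[0].tags.get("ImageDescription")
        nodata = -9999.0
        if desc is not None:
            try:
                nodata = float(json.loads(desc.value).get("nodata", nodata))
            except (ValueError, TypeError):
                pass
    lines = [float(s) for s in path.with_suffix(".tfw").read_text().split()]
    c = lines[0]
    origin = (lines[4] - c / 2.0, lines[5] + c / 2.0)
    vals = np.where(vals == nodata, np.nan, vals)
    return Raster(origin, c, vals)


# --- point clouds ------------------------------------------------------------

def write_xyz(path: str | Path, cloud: PointCloud) -> None:
    np.savetxt(path, cloud.xyz, fmt="%.3f")


def read_xyz(path: str | Path) -> PointCloud:
    data = np.loadtxt(path, ndmin=2)
    return PointCloud(data[:, :3]) if data.size else PointCloud(np.empty((0, 3)))


# --- candidates / trees ------------------------------------------------------

def write_candidates_geojson(path: str | Path, candidates: Sequence[TreeCandidate]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [c.x, c.y]},
            "properties": {"id": c.id, "height": c.height, "source": c.source},
        }
        for c in candidates
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_candidates_geojson(path: str | Path) -> list[TreeCandidate]:
    data = json.loads(Path(path).read_text())
    out = []
    for f in data["features"]:
        x, y = f["geometry"]["coordinates"][:2]
        p = f.get("properties", {})
        out.append(
            TreeCandidate(
                id=str(p.get("id", len(out))),
                x=float(x),
                y=float(y),
                height=p.get("height"),
                source=p.get("source", "unknown"),
            )
        )
    return out


def write_candidates_csv(path: str | Path, candidates: Sequence[TreeCandidate]) -> None:
    pd.DataFrame(
        [{"id": c.id, "x": c.x, "y": c.y, "height": c.height, "source": c.source} for c in candidates]
    ).to_csv(path, index=False)


# --- polygons (buildings) ----------------------------------------------------

def write_polygons_geojson(path: str | Path, polygons: Sequence[BaseGeometry]) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(p), "properties": {}} for p in polygons
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_polygons_geojson(path: str | Path) -> list[BaseGeometry]:
    data = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in data["features"]]


# --- stations & detections ---------------------------------------------------

_STATION_COLS = [
    "id", "x", "y", "heading", "pitch", "hfov", "vfov",
    "img_width", "img_height", "camera_height", "capture_date",
]


def write_stations_csv(path: str | Path, stations: Sequence[PanoStation]) -> None:
    pd.DataFrame([{c: getattr(s, c) for c in _STATION_COLS} for s in stations]).to_csv(
        path, index=False
    )


def read_stations_csv(path: str | Path) -> list[PanoStation]:
    df = pd.read_csv(path, dtype={"id": str, "capture_date": str}, keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        out.append(
            PanoStation(
                id=str(row["id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                heading=float(row.get("heading", 0.0)),
                pitch=float(row.get("pitch", 0.0)),
                hfov=float(row.get("hfov", 360.0)),
                vfov=float(row.get("vfov", 90.0)),
                img_width=int(row.get("img_width", 2048)),
                img_height=int(row.get("img_height", 1024)),
                camera_height=float(row.get("camera_height", 2.5)),
                capture_date=str(row.get("capture_date", "")),
            )
        )
    return out


def write_detections_csv(path: str | Path, detections: Sequence[Detection]) -> None:
    pd.DataFrame(
        [
            {"station_id": d.station_id, "u": d.u, "v": d.v, "kind": d.kind, "confidence": d.confidence}
            for d in detections
        ]
    ).to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path, dtype={"station_id": str})
    return [
        Detection(
            station_id=str(r["station_id"]),
            u=float(r["u"]),
            v=float(r["v"]),
            kind=str(r.get("kind", "stem")),
            confidence=float(r.get("confidence", 1.0)),
        )
        for r in df.to_dict("records")
    ]


# --- config ------------------------------------------------------------------

def write_yaml(path: str | Path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
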