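"""Reading and writing the pipeline's file formats.

Vector layers travel as GeoJSON FeatureCollections (attribute names
mapped in a small YAML/JSON layer config), rasters as ESRI ASCII grids,
sites and tables as CSV, models as JSON.  All inputs must already be in
one projected metric CRS; no reprojection happens here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .gis import (
    ClassedPolygonLayer,
    PredictorTable,
    RasterGrid,
    RoadLayer,
    RoadSegment,
    Site,
)

__all__ = [
    "read_sites_csv",
    "write_sites_csv",
    "read_polygon_geojson",
    "write_polygon_geojson",
    "read_roads_geojson",
    "write_roads_geojson",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_predictor_csv",
    "load_layer_config",
]


def read_sites_csv(path) -> list[Site]:
    df = pd.read_csv(path, dtype={"site_id": str})
    required = {"site_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sites CSV missing columns: {sorted(missing)}")
    return [
        Site(
            site_id=str(r.site_id),
            x=float(r.x),
            y=float(r.y),
            area=str(getattr(r, "area", "")),
            site_type=str(getattr(r, "site_type", "urban_background")),
            altitude_m=float(r.altitude_m)
            if "altitude_m" in df.columns and pd.notna(getattr(r, "altitude_m"))
            else None,
        )
        for r in df.itertuples()
    ]


def write_sites_csv(sites: Iterable[Site], path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "x": s.x,
                "y": s.y,
                "area": s.area,
                "site_type": s.site_type,
                "altitude_m": s.altitude_m,
            }
            for s in sites
        ]
    ).to_csv(path, index=False)


def read_polygon_geojson(
    path, class_attribute: str = "class", vocabulary: Iterable[str] | None = None
) -> ClassedPolygonLayer:
    with open(path) as fh:
        fc = json.load(fh)
    polys, classes = [], []
    for feat in fc["features"]:
        polys.append(shape(feat["geometry"]))
        classes.append(str(feat["properties"].get(class_attribute, "")))
    return ClassedPolygonLayer(polys, classes, vocabulary)


def write_polygon_geojson(layer: ClassedPolygonLayer, path, class_attribute: str = "class") -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(g),
            "properties": {class_attribute: str(c)},
        }
        for g, c in zip(layer.geometries, layer.classes)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_roads_geojson(
    path,
    intensity_attribute: str = "intensity",
    heavy_attribute: str = "heavy_share",
    class_attribute: str = "road_class",
    id_attribute: str = "segment_id",
) -> RoadLayer:
    with open(path) as fh:
        fc = json.load(fh)
    segments = []
    for i, feat in enumerate(fc["features"]):
        props = feat["properties"]
        segments.append(
            RoadSegment(
                segment_id=str(props.get(id_attribute, f"seg{i:05d}")),
                geometry=shape(feat["geometry"]),
                intensity=float(props[intensity_attribute]),
                heavy_share=float(props.get(heavy_attribute, 0.0)),
                road_class=str(props.get(class_attribute, "")),
            )
        )
    return RoadLayer(segments)


def write_roads_geojson(roads: RoadLayer, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(s.geometry),
            "properties": {
                "segment_id": s.segment_id,
                "intensity": s.intensity,
                "heavy_share": s.heavy_share,
                "road_class": s.road_class,
            },
        }
        for s in roads.segments
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_ascii_grid(path, role: str = "generic", units: str = "") -> RasterGrid:
    """ESRI ASCII grid: 6 header lines then rows north to south."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(lines[i:][: int(header["nrows"])], dtype=float, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {values.shape} disagrees with header")
    if "nodata_value" in header:
        values = np.where(values == header["nodata_value"], np.nan, values)
    return RasterGrid(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        values=values,
        role=role,
        units=units,
    )


def write_ascii_grid(grid: RasterGrid, path, nodata: float = -9999.0) -> None:
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
            f"xllcorner {grid.x0}\nyllcorner {grid.y0}\n"
            f"cellsize {grid.cell}\nNODATA_value {nodata}\n"
        )
        np.savetxt(fh, vals, fmt="%.6g")


def read_predictor_csv(path, specs=None, area_reference=None, areas=None) -> PredictorTable:
    frame = pd.read_csv(path, index_col="site_id")
    frame.index = frame.index.astype(str)
    return PredictorTable(frame, specs or {}, area_reference, areas)


def load_layer_config(path) -> dict:
    """YAML mapping of layer roles to file paths and attribute names."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("layer config must be a mapping")
    return cfg
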