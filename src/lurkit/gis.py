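"""GIS predictor engineering for land-use regression.

Computes circular-buffer, nearest-road and raster-overlay variables that
characterise a monitoring site: built-up area, land-use class areas,
population counts, road lengths, traffic loads, nearest-road traffic
metrics, altitude (with log/sqrt transforms) and dispersion-model
background concentrations.  All geometry is planar Euclidean in a
projected coordinate system with metre units; the study-area scale
(tens of km) makes geodesic corrections irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.validation import make_valid

__all__ = [
    "MAJOR_ROAD_INTENSITY",
    "VALID_BUFFER_RADII",
    "Site",
    "RoadSegment",
    "RoadLayer",
    "ClassedPolygonLayer",
    "RasterGrid",
    "PredictorSpec",
    "PredictorTable",
    "buffer_area",
    "buffer_line_length",
    "buffer_traffic_load",
    "nearest_road_metrics",
    "raster_at_point",
    "raster_buffer_sum",
    "build_predictor_table",
    "standard_predictor_specs",
    "NoQualifyingRoadError",
]

#: A road is "major" when its modelled traffic intensity is at least this
#: many vehicles per 24 h.
MAJOR_ROAD_INTENSITY = 5000.0

#: Buffer radii (m) used by the standard predictor inventory.
VALID_BUFFER_RADII = frozenset(
    {25, 50, 75, 100, 150, 200, 250, 300, 500, 1000, 2000, 5000}
)

# Segments per quarter circle when polygonising buffers; at 64 the area of
# the inscribed polygon is within ~1e-4 of the true disc, well inside the
# 0.5% tolerance the buffer statistics are validated to.
_BUFFER_QUAD_SEGS = 64


class NoQualifyingRoadError(ValueError):
    """No road satisfies the nearest-road query (e.g. no major road)."""


def _require_finite(x: float, y: float) -> None:
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"site coordinates must be finite, got ({x}, {y})")


@dataclass(frozen=True)
class Site:
    """A monitoring location in projected planar coordinates (metres)."""

    site_id: str
    x: float
    y: float
    area: str = ""
    site_type: str = "urban_background"  # regional_background | urban_background | traffic
    altitude_m: float | None = None

    def __post_init__(self) -> None:
        _require_finite(self.x, self.y)

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass(frozen=True)
class RoadSegment:
    """A road centreline with modelled daily traffic."""

    segment_id: str
    geometry: shapely.Geometry
    intensity: float  # vehicles/day
    heavy_share: float = 0.0  # fraction of heavy vehicles in [0, 1]
    road_class: str = ""

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"negative traffic intensity on {self.segment_id}")
        if not 0.0 <= self.heavy_share <= 1.0:
            raise ValueError(f"heavy_share outside [0,1] on {self.segment_id}")

    @property
    def is_major(self) -> bool:
        return self.intensity >= MAJOR_ROAD_INTENSITY


class RoadLayer:
    """A collection of road segments with vectorised geometry access."""

    def __init__(self, segments: Sequence[RoadSegment]):
        self.segments = list(segments)
        self.geometries = np.array([s.geometry for s in self.segments], dtype=object)
        self.intensity = np.array([s.intensity for s in self.segments], dtype=float)
        self.heavy_share = np.array([s.heavy_share for s in self.segments], dtype=float)
        self.segment_ids = np.array([s.segment_id for s in self.segments], dtype=object)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def major_mask(self) -> np.ndarray:
        return self.intensity >= MAJOR_ROAD_INTENSITY


class ClassedPolygonLayer:
    """Polygons carrying a land-use / feature class attribute.

    Invalid (self-intersecting) polygons are repaired on construction.
    ``vocabulary`` declares the admissible class labels; when given,
    unknown classes raise.
    """

    def __init__(
        self,
        polygons: Sequence[shapely.Geometry],
        classes: Sequence[str],
        vocabulary: Iterable[str] | None = None,
    ):
        if len(polygons) != len(classes):
            raise ValueError("polygons and classes must have equal length")
        repaired = [g if g.is_valid else make_valid(g) for g in polygons]
        self.geometries = np.array(repaired, dtype=object)
        self.classes = np.array(list(classes), dtype=object)
        if vocabulary is not None:
            vocab = set(vocabulary)
            unknown = set(self.classes) - vocab
            if unknown:
                raise ValueError(f"classes outside declared vocabulary: {sorted(unknown)}")
        self.vocabulary = set(vocabulary) if vocabulary is not None else None

    def __len__(self) -> int:
        return len(self.geometries)

    def class_mask(self, class_filter: Iterable[str] | None) -> np.ndarray:
        if class_filter is None:
            return np.ones(len(self), dtype=bool)
        wanted = set(class_filter)
        return np.array([c in wanted for c in self.classes], dtype=bool)


@dataclass
class RasterGrid:
    """A regular grid of values with lower-left origin and square cells.

    ``values`` follows raster file convention: row 0 is the northernmost
    row.  Point lookups are nearest-cell (no interpolation); a point on a
    cell boundary is assigned to the cell whose half-open interval
    [x0 + i*cell, x0 + (i+1)*cell) x [y0 + j*cell, y0 + (j+1)*cell)
    contains it.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray  # shape (nrows, ncols), row 0 = north
    role: str = "generic"  # population | altitude | dispersion_no2 | dispersion_pm25 | dispersion_pm10
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell,
            self.y0 + self.nrows * self.cell,
        )

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Array (row, col) of the cell containing (x, y); raises outside extent."""
        col = math.floor((x - self.x0) / self.cell)
        row_from_bottom = math.floor((y - self.y0) / self.cell)
        if not (0 <= col < self.ncols and 0 <= row_from_bottom < self.nrows):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.bounds}")
        return self.nrows - 1 - row_from_bottom, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of cell centres, matching ``values`` layout."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.nrows)[::-1] + 0.5) * self.cell
        return np.meshgrid(xs, ys)


@dataclass(frozen=True)
class PredictorSpec:
    """Definition of one predictor variable.

    ``statistic`` selects the extraction: area_sum / length_sum / load_sum
    operate inside a circular buffer; count_sum sums raster cells inside
    the buffer; point_value overlays the site on a raster; the nearest_*
    statistics use the closest (optionally major) road.  ``major_only``
    restricts roads to intensity >= 5000 veh/day, ``heavy`` weights
    intensity by the heavy-vehicle share.
    """

    name: str
    source: str  # key into the supplied layer mapping
    statistic: str
    buffer_m: float | None = None
    class_filter: frozenset[str] | None = None
    transform: str = "identity"  # identity | log | sqrt
    direction: str = "positive"  # positive | negative | either
    major_only: bool = False
    heavy: bool = False

    _STATISTICS = {
        "area_sum",
        "length_sum",
        "load_sum",
        "count_sum",
        "point_value",
        "nearest_intensity",
        "nearest_inverse_distance",
        "nearest_intensity_times_inverse_distance",
    }

    def __post_init__(self) -> None:
        if self.statistic not in self._STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r} for {self.name}")
        if self.transform not in {"identity", "log", "sqrt"}:
            raise ValueError(f"unknown transform {self.transform!r} for {self.name}")
        if self.direction not in {"positive", "negative", "either"}:
            raise ValueError(f"unknown direction {self.direction!r} for {self.name}")
        if self.buffer_m is not None and self.buffer_m not in VALID_BUFFER_RADII:
            raise ValueError(
                f"buffer radius {self.buffer_m} m not in the supported set for {self.name}"
            )


@dataclass
class PredictorTable:
    """Sites x predictors value matrix with per-column specifications.

    Missing features inside a buffer yield 0, never NaN.  Area-indicator
    columns are 0/1 dummies relative to a declared reference area.
    """

    frame: pd.DataFrame  # index: site_id, columns: predictor names
    specs: dict[str, PredictorSpec]
    area_reference: str | None = None
    areas: pd.Series | None = None  # site_id -> area label

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            bad = self.frame.columns[self.frame.isna().any()].tolist()
            raise ValueError(f"predictor table contains missing values in {bad}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.frame.columns)

    def direction_of(self, name: str) -> str:
        if name in self.specs:
            return self.specs[name].direction
        if name.startswith("Area_"):
            return "either"
        return "either"

    def is_area_dummy(self, name: str) -> bool:
        return name.startswith("Area_")

    def subset(self, site_ids: Sequence[str]) -> "PredictorTable":
        areas = self.areas.loc[list(site_ids)] if self.areas is not None else None
        return PredictorTable(
            self.frame.loc[list(site_ids)], self.specs, self.area_reference, areas
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="site_id")


def _buffer_polygon(site: Site, radius_m: float) -> shapely.Geometry:
    if radius_m <= 0:
        raise ValueError("buffer radius must be positive")
    return site.point.buffer(radius_m, quad_segs=_BUFFER_QUAD_SEGS)


def buffer_area(
    layer: ClassedPolygonLayer,
    site: Site,
    radius_m: float,
    class_filter: Iterable[str] | None = None,
) -> float:
    """Total area (m^2) of filtered polygons intersecting the circular buffer.

    Areas are summed per polygon; input layers are expected not to
    self-overlap within a class (true of building footprints and of
    mutually exclusive land-cover mosaics).
    """
    buf = _buffer_polygon(site, radius_m)
    mask = layer.class_mask(class_filter)
    if not mask.any():
        return 0.0
    geoms = layer.geometries[mask]
    # cheap bounding-box prefilter before exact intersection
    hits = shapely.intersects(geoms, buf)
    if not hits.any():
        return 0.0
    inter = shapely.intersection(geoms[hits], buf)
    return float(shapely.area(inter).sum())


def _clip_lengths(roads: RoadLayer, buf: shapely.Geometry, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(indices, clipped lengths) of masked segments intersecting ``buf``."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return idx, np.zeros(0)
    geoms = roads.geometries[idx]
    hits = shapely.intersects(geoms, buf)
    idx = idx[hits]
    if idx.size == 0:
        return idx, np.zeros(0)
    clipped = shapely.intersection(roads.geometries[idx], buf)
    return idx, shapely.length(clipped)


def buffer_line_length(
    roads: RoadLayer, site: Site, radius_m: float, major_only: bool = False
) -> float:
    """Summed clipped road length (m) inside the buffer."""
    buf = _buffer_polygon(site, radius_m)
    mask = roads.major_mask if major_only else np.ones(len(roads), dtype=bool)
    _, lengths = _clip_lengths(roads, buf, mask)
    return float(lengths.sum())


def buffer_traffic_load(
    roads: RoadLayer, site: Site, radius_m: float, variant: str = "all"
) -> float:
    """Traffic load (veh/day * m): sum of intensity x clipped length.

    variant "all" uses every road, "major" only roads with intensity
    >= 5000 veh/day, "heavy" weights intensity by the heavy-vehicle share.
    """
    if variant not in {"all", "major", "heavy"}:
        raise ValueError(f"unknown traffic-load variant {variant!r}")
    buf = _buffer_polygon(site, radius_m)
    mask = roads.major_mask if variant == "major" else np.ones(len(roads), dtype=bool)
    idx, lengths = _clip_lengths(roads, buf, mask)
    if idx.size == 0:
        return 0.0
    weights = roads.intensity[idx]
    if variant == "heavy":
        weights = weights * roads.heavy_share[idx]
    return float((weights * lengths).sum())


def nearest_road_metrics(
    roads: RoadLayer,
    site: Site,
    major_only: bool = False,
    heavy: bool = False,
    min_distance_m: float = 1.0,
) -> dict[str, float]:
    """Metrics of the nearest (optionally major) road.

    The Euclidean distance is clamped below at ``min_distance_m`` before
    inversion so that a site lying on a centreline keeps a finite inverse
    distance.  Equidistant ties resolve to the higher-intensity segment,
    then to the lexicographically smaller segment id.
    """
    mask = roads.major_mask if major_only else np.ones(len(roads), dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise NoQualifyingRoadError(
            "no qualifying road for nearest-road metrics"
            + (" (major_only)" if major_only else "")
        )
    dists = shapely.distance(roads.geometries[idx], site.point)
    dmin = dists.min()
    # exact-tie set; coordinates are constructed data, ties are exact
    tied = idx[np.isclose(dists, dmin, rtol=0.0, atol=1e-9)]
    order = sorted(
        tied, key=lambda i: (-roads.intensity[i], str(roads.segment_ids[i]))
    )
    chosen = order[0]
    intensity = roads.intensity[chosen]
    if heavy:
        intensity = intensity * roads.heavy_share[chosen]
    d = max(float(dmin), min_distance_m)
    return {
        "distance_m": d,
        "intensity": float(intensity),
        "inverse_distance": 1.0 / d,
        "intensity_times_inverse_distance": float(intensity) / d,
    }


def raster_at_point(grid: RasterGrid, site: Site) -> float:
    """Value of the raster cell containing the site (nearest-cell overlay)."""
    r, c = grid.cell_index(site.x, site.y)
    return float(grid.values[r, c])


def raster_buffer_sum(grid: RasterGrid, site: Site, radius_m: float) -> float:
    """Sum of raster cell values whose centres fall inside the buffer.

    Used for population counts: each cell carries a count, and a cell
    belongs to the buffer when its centre does.
    """
    if radius_m <= 0:
        raise ValueError("buffer radius must be positive")
    X, Y = grid.cell_centers()
    inside = (X - site.x) ** 2 + (Y - site.y) ** 2 <= radius_m**2
    return float(grid.values[inside].sum())


def _apply_transform(value: float, transform: str, name: str) -> float:
    if transform == "identity":
        return value
    if value <= 0:
        raise ValueError(
            f"{name}: {transform} transform requires a positive value, got {value}"
        )
    return math.log(value) if transform == "log" else math.sqrt(value)


def _extract_one(spec: PredictorSpec, site: Site, layers: Mapping[str, object]) -> float:
    if spec.source not in layers:
        raise KeyError(f"spec {spec.name}: source layer {spec.source!r} not supplied")
    layer = layers[spec.source]
    stat = spec.statistic
    if stat == "area_sum":
        value = buffer_area(layer, site, spec.buffer_m, spec.class_filter)
    elif stat == "length_sum":
        value = buffer_line_length(layer, site, spec.buffer_m, major_only=spec.major_only)
    elif stat == "load_sum":
        variant = "heavy" if spec.heavy else ("major" if spec.major_only else "all")
        value = buffer_traffic_load(layer, site, spec.buffer_m, variant=variant)
    elif stat == "count_sum":
        value = raster_buffer_sum(layer, site, spec.buffer_m)
    elif stat == "point_value":
        value = raster_at_point(layer, site)
    else:  # nearest-road family
        metrics = nearest_road_metrics(
            layer, site, major_only=spec.major_only, heavy=spec.heavy
        )
        key = {
            "nearest_intensity": "intensity",
            "nearest_inverse_distance": "inverse_distance",
            "nearest_intensity_times_inverse_distance": "intensity_times_inverse_distance",
        }[stat]
        value = metrics[key]
    return _apply_transform(value, spec.transform, spec.name)


def build_predictor_table(
    sites: Sequence[Site],
    layers: Mapping[str, object],
    specs: Sequence[PredictorSpec],
    area_reference: str | None = None,
) -> PredictorTable:
    """Evaluate every predictor spec at every site.

    Adds a 0/1 ``Area_<label>`` dummy for each area other than
    ``area_reference`` (when a reference is given and more than one area
    is present).  The result has no missing values by construction.
    """
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValueError("site_id values must be unique")
    data: dict[str, list[float]] = {}
    for spec in specs:
        data[spec.name] = [_extract_one(spec, site, layers) for site in sites]
    frame = pd.DataFrame(data, index=pd.Index(ids, name="site_id"))

    areas = pd.Series([s.area for s in sites], index=frame.index, name="area")
    if area_reference is not None:
        labels = sorted(set(areas))
        if area_reference not in labels:
            raise ValueError(f"reference area {area_reference!r} has no sites")
        for label in labels:
            if label == area_reference:
                continue
            frame[f"Area_{label}"] = (areas == label).astype(float)
    return PredictorTable(frame, {s.name: s for s in specs}, area_reference, areas)


# --- the standard variable inventory -------------------------------------

_LANDUSE_BUFFERS = (100, 150, 200, 250, 300, 500, 1000, 2000, 5000)
_ROAD_BUFFERS = (25, 50, 75, 100, 150, 200, 250, 300, 500, 1000, 2000, 5000)
_WATER_BUFFERS = (100, 150, 200, 250, 300, 500, 1000)

_LANDUSE_CLASSES = {
    "LDRES": ("positive", ("LDRES",)),
    "HDRES": ("positive", ("HDRES",)),
    "AIRPORT": ("positive", ("AIRPORT",)),
    "INDUSTRY": ("positive", ("INDUSTRY",)),
    "NATURAL": ("negative", ("NATURAL",)),
    "PORT": ("positive", ("PORT",)),
    "URBGREEN": ("negative", ("URBGREEN",)),
    "UGNL": ("negative", ("URBGREEN", "NATURAL")),
}


def standard_predictor_specs(
    dispersion: Sequence[str] = ("NO2_2010", "PM25_2010", "PM10_2010"),
) -> list[PredictorSpec]:
    """The full standard predictor inventory.

    Buffer families: building area (12 radii), population counts (9),
    eight land-use classes (9 each), water area (7), five road-network
    statistics (12 each); plus eight nearest-road metrics, altitude with
    log and sqrt transforms, and up to three dispersion-model overlays.
    Dispersion layers absent from ``dispersion`` are omitted.
    """
    specs: list[PredictorSpec] = []
    for r in _ROAD_BUFFERS:
        specs.append(
            PredictorSpec(f"BUILDINGS_{r}", "buildings", "area_sum", buffer_m=r)
        )
    for r in _LANDUSE_BUFFERS:
        specs.append(PredictorSpec(f"POP_{r}", "population", "count_sum", buffer_m=r))
    for cls, (direction, members) in _LANDUSE_CLASSES.items():
        for r in _LANDUSE_BUFFERS:
            specs.append(
                PredictorSpec(
                    f"{cls}_{r}",
                    "landuse",
                    "area_sum",
                    buffer_m=r,
                    class_filter=frozenset(members),
                    direction=direction,
                )
            )
    for r in _WATER_BUFFERS:
        specs.append(
            PredictorSpec(
                f"WATER_{r}",
                "landuse",
                "area_sum",
                buffer_m=r,
                class_filter=frozenset({"WATER"}),
                direction="either",
            )
        )
    for r in _ROAD_BUFFERS:
        specs.append(PredictorSpec(f"ROADLENGTH_{r}", "roads", "length_sum", buffer_m=r))
        specs.append(
            PredictorSpec(
                f"MAJROADLENGTH_{r}", "roads", "length_sum", buffer_m=r, major_only=True
            )
        )
        specs.append(PredictorSpec(f"TRAFLOAD_{r}", "roads", "load_sum", buffer_m=r))
        specs.append(
            PredictorSpec(
                f"TRAFMAJORLOAD_{r}", "roads", "load_sum", buffer_m=r, major_only=True
            )
        )
        specs.append(
            PredictorSpec(f"HEAVYTRAFLOAD_{r}", "roads", "load_sum", buffer_m=r, heavy=True)
        )
    specs += [
        PredictorSpec("TRAFNEAR", "roads", "nearest_intensity"),
        PredictorSpec("TRAFMAJOR", "roads", "nearest_intensity", major_only=True),
        PredictorSpec("HEAVYTRAFNEAR", "roads", "nearest_intensity", heavy=True),
        PredictorSpec(
            "INTINVDIST", "roads", "nearest_intensity_times_inverse_distance"
        ),
        PredictorSpec(
            "INTINVMAJDIST",
            "roads",
            "nearest_intensity_times_inverse_distance",
            major_only=True,
        ),
        PredictorSpec(
            "HEAVYINTINVDIST",
            "roads",
            "nearest_intensity_times_inverse_distance",
            heavy=True,
        ),
        PredictorSpec("INVDIST", "roads", "nearest_inverse_distance"),
        PredictorSpec(
            "MAJINVDIST", "roads", "nearest_inverse_distance", major_only=True
        ),
        PredictorSpec("ALT", "altitude", "point_value", direction="negative"),
        PredictorSpec(
            "LOG_ALT", "altitude", "point_value", transform="log", direction="negative"
        ),
        PredictorSpec(
            "SQRT_ALT", "altitude", "point_value", transform="sqrt", direction="negative"
        ),
    ]
    dispersion_sources = {
        "NO2_2010": "dispersion_no2",
        "PM25_2010": "dispersion_pm25",
        "PM10_2010": "dispersion_pm10",
    }
    for name in dispersion:
        specs.append(PredictorSpec(name, dispersion_sources[name], "point_value"))
    return specs
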