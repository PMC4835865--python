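"""Synthetic multi-area landscapes, predictor tables and campaigns.

Two generation paths serve different tests.  The geometric path builds
actual vector/raster layers (roads with lognormal traffic intensities,
building and land-use polygons, population/altitude/dispersion grids)
for several well-separated study areas, with about half the monitoring
sites placed next to high-traffic roads, mirroring the deliberate
over-representation of street sites in the measurement design.  The
direct path samples a predictor matrix with a prescribed correlation
structure, fast enough for many-replicate statistical tests.

The campaign generator produces three seasonal measurement periods per
site: value = (site long-term mean) * seasonal factor * exp(noise), with
a reference series per area sharing the seasonal factors exactly — the
regime in which reference-site temporal adjustment is unbiased.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Polygon, box

from .gis import (
    ClassedPolygonLayer,
    PredictorSpec,
    PredictorTable,
    RasterGrid,
    RoadLayer,
    RoadSegment,
    Site,
    MAJOR_ROAD_INTENSITY,
)
from .temporal import ReferenceSeries

__all__ = [
    "LandscapeConfig",
    "TruthModel",
    "Landscape",
    "generate_landscape",
    "generate_predictor_table",
    "generate_campaign",
]

DEFAULT_SEASONAL_FACTORS = (1.3, 1.0, 0.7)  # cold, intermediate, warm; mean 1


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of a synthetic multi-area study landscape.

    Defaults emulate the campaign design this pipeline targets: several
    distinct study areas with different background levels, 40 sites per
    area of which about half are traffic sites, areas far enough apart
    that no buffer crosses between them.
    """

    n_areas: int = 4
    sites_per_area: int = 40
    extent_km: float = 5.0
    area_spacing_km: float = 20.0
    traffic_site_fraction: float = 0.5
    roads_per_area: int = 60
    intensity_log_mean: float = math.log(1500.0)
    intensity_log_sd: float = 1.2
    buildings_per_area: int = 250
    area_backgrounds: tuple[float, ...] | None = None  # μg/m³ per area
    altitude_bases: tuple[float, ...] | None = None  # m per area

    def __post_init__(self) -> None:
        if self.n_areas < 1 or self.sites_per_area < 1:
            raise ValueError("counts must be >= 1")
        if self.extent_km <= 0 or self.area_spacing_km <= 0:
            raise ValueError("degenerate extents")

    def area_names(self) -> list[str]:
        return [f"area_{chr(ord('A') + i)}" for i in range(self.n_areas)]

    def area_origin(self, i: int) -> tuple[float, float]:
        """Lower-left corner (m) of area i on a square grid of areas."""
        per_row = max(1, math.ceil(math.sqrt(self.n_areas)))
        gx, gy = i % per_row, i // per_row
        s = self.area_spacing_km * 1000.0
        return gx * s, gy * s


@dataclass
class Landscape:
    sites: list[Site]
    layers: dict[str, object]
    config: LandscapeConfig


def _random_segment(rng: np.random.Generator, x0: float, y0: float, extent: float) -> LineString:
    sx, sy = x0 + rng.uniform(0, extent), y0 + rng.uniform(0, extent)
    angle = rng.uniform(0, 2 * math.pi)
    length = rng.uniform(300.0, 2000.0)
    ex = min(max(sx + length * math.cos(angle), x0), x0 + extent)
    ey = min(max(sy + length * math.sin(angle), y0), y0 + extent)
    if (ex, ey) == (sx, sy):  # degenerate clamp; nudge
        ex, ey = sx + 10.0, sy
    return LineString([(sx, sy), (ex, ey)])


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Gaussian-filtered white noise, standardised: a cheap stationary random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(config: LandscapeConfig, seed: int = 0) -> Landscape:
    """Build sites plus vector and raster layers for every study area.

    Traffic sites (a configurable fraction, default half) are placed
    5-30 m from a point on a major road; remaining sites are uniform over
    the area extent.  Road intensities are lognormal; at least one major
    road per area is guaranteed so nearest-major-road metrics are defined.
    """
    rng = np.random.default_rng(seed)
    extent = config.extent_km * 1000.0
    names = config.area_names()
    backgrounds = config.area_backgrounds or tuple(
        15.0 + 5.0 * i for i in range(config.n_areas)
    )
    alt_bases = config.altitude_bases or tuple(
        300.0 + 150.0 * i for i in range(config.n_areas)
    )

    sites: list[Site] = []
    segments: list[RoadSegment] = []
    buildings: list = []
    landuse_polys: list = []
    landuse_classes: list[str] = []

    for ai, aname in enumerate(names):
        x0, y0 = config.area_origin(ai)
        intensities = rng.lognormal(
            config.intensity_log_mean, config.intensity_log_sd, config.roads_per_area
        )
        if intensities.max() < MAJOR_ROAD_INTENSITY:
            intensities[int(np.argmax(intensities))] = MAJOR_ROAD_INTENSITY * 1.2
        area_segments = []
        for ri in range(config.roads_per_area):
            seg = RoadSegment(
                segment_id=f"{aname}_r{ri:03d}",
                geometry=_random_segment(rng, x0, y0, extent),
                intensity=float(intensities[ri]),
                heavy_share=float(rng.beta(2.0, 18.0)),
                road_class="street",
            )
            area_segments.append(seg)
        segments.extend(area_segments)
        majors = [s for s in area_segments if s.is_major]

        n_traffic = int(round(config.traffic_site_fraction * config.sites_per_area))
        for si in range(config.sites_per_area):
            sid = f"{aname}_s{si:03d}"
            if si < n_traffic:
                road = majors[rng.integers(len(majors))]
                pt = road.geometry.interpolate(rng.uniform(0, road.geometry.length))
                ang = rng.uniform(0, 2 * math.pi)
                off = rng.uniform(5.0, 30.0)
                sx = min(max(pt.x + off * math.cos(ang), x0 + 1), x0 + extent - 1)
                sy = min(max(pt.y + off * math.sin(ang), y0 + 1), y0 + extent - 1)
                stype = "traffic"
            else:
                sx, sy = x0 + rng.uniform(0, extent), y0 + rng.uniform(0, extent)
                stype = "urban_background" if rng.uniform() < 0.8 else "regional_background"
            sites.append(Site(sid, float(sx), float(sy), aname, stype))

        for bi in range(config.buildings_per_area):
            bx, by = x0 + rng.uniform(0, extent), y0 + rng.uniform(0, extent)
            w, h = rng.uniform(10, 40), rng.uniform(10, 40)
            buildings.append(box(bx, by, bx + w, by + h))

        # land-use mosaic: a few rectangles per class; PORT only in the first area
        for cls in ("HDRES", "LDRES", "INDUSTRY", "NATURAL", "URBGREEN", "WATER"):
            for _ in range(rng.integers(2, 6)):
                cx, cy = x0 + rng.uniform(0, extent), y0 + rng.uniform(0, extent)
                half = rng.uniform(100, 600)
                landuse_polys.append(box(cx - half, cy - half, cx + half, cy + half))
                landuse_classes.append(cls)
        if ai == 0:
            cx, cy = x0 + rng.uniform(0, extent), y0 + rng.uniform(0, extent)
            landuse_polys.append(box(cx - 300, cy - 300, cx + 300, cy + 300))
            landuse_classes.append("PORT")

    # rasters cover the bounding box of all areas plus the largest buffer
    pad = 5000.0
    xs = [config.area_origin(i)[0] for i in range(config.n_areas)]
    ys = [config.area_origin(i)[1] for i in range(config.n_areas)]
    minx, miny = min(xs) - pad, min(ys) - pad
    maxx, maxy = max(xs) + extent + pad, max(ys) + extent + pad

    def _grid(cell: float) -> tuple[int, int]:
        return math.ceil((maxy - miny) / cell), math.ceil((maxx - minx) / cell)

    pop_cell = 100.0
    pshape = _grid(pop_cell)
    pop = np.maximum(_smooth_field(rng, pshape, 5.0) * 20.0 + 25.0, 0.0)
    population = RasterGrid(minx, miny, pop_cell, pop, role="population", units="persons")

    env_cell = 200.0
    eshape = _grid(env_cell)
    alt = np.full(eshape, 400.0)
    X = minx + (np.arange(eshape[1]) + 0.5) * env_cell
    Y = miny + (np.arange(eshape[0])[::-1] + 0.5) * env_cell
    XX, YY = np.meshgrid(X, Y)
    for ai in range(config.n_areas):
        x0, y0 = config.area_origin(ai)
        inside = (
            (XX >= x0 - pad)
            & (XX < x0 + extent + pad / 2)
            & (YY >= y0 - pad)
            & (YY < y0 + extent + pad / 2)
        )
        alt[inside] = alt_bases[ai] + 0.004 * (XX[inside] - x0)
    alt = np.maximum(alt + 10.0 * _smooth_field(rng, eshape, 4.0), 1.0)
    altitude = RasterGrid(minx, miny, env_cell, alt, role="altitude", units="m")

    rasters: dict[str, RasterGrid] = {"population": population, "altitude": altitude}
    for role, scale in (
        ("dispersion_no2", 1.0),
        ("dispersion_pm25", 0.6),
        ("dispersion_pm10", 0.9),
    ):
        conc = np.full(eshape, 8.0)
        for ai in range(config.n_areas):
            x0, y0 = config.area_origin(ai)
            inside = (
                (XX >= x0 - pad)
                & (XX < x0 + extent + pad / 2)
                & (YY >= y0 - pad)
                & (YY < y0 + extent + pad / 2)
            )
            conc[inside] = backgrounds[ai] * scale
        conc = np.maximum(conc + 2.0 * _smooth_field(rng, eshape, 6.0), 0.5)
        rasters[role] = RasterGrid(minx, miny, env_cell, conc, role=role, units="ug/m3")

    layers: dict[str, object] = {
        "buildings": ClassedPolygonLayer(buildings, ["building"] * len(buildings)),
        "landuse": ClassedPolygonLayer(landuse_polys, landuse_classes),
        "roads": RoadLayer(segments),
        **rasters,
    }
    return Landscape(sites=sites, layers=layers, config=config)


def generate_predictor_table(
    names: Sequence[str],
    n_sites: int,
    correlation: np.ndarray | None = None,
    seed: int = 0,
    directions: Mapping[str, str] | None = None,
    nested_groups: Sequence[Sequence[str]] = (),
    areas: Sequence[str] | None = None,
    area_reference: str | None = None,
    scale: float = 1.0,
) -> PredictorTable:
    """Direct (non-geometric) sampling of a predictor matrix.

    Columns are standard-normal with the given correlation matrix (must
    be positive definite; identity when omitted).  Columns listed in a
    ``nested_groups`` sequence are instead built as cumulative sums of
    non-negative increments so nested-buffer monotonicity holds row-wise.
    """
    rng = np.random.default_rng(seed)
    names = list(names)
    k = len(names)
    nested_cols = {c for grp in nested_groups for c in grp}
    free = [n for n in names if n not in nested_cols]

    data: dict[str, np.ndarray] = {}
    if free:
        if correlation is None:
            corr = np.eye(len(free))
        else:
            corr = np.asarray(correlation, dtype=float)
            if corr.shape != (len(free), len(free)):
                raise ValueError("correlation shape does not match free columns")
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as err:
            raise ValueError("correlation matrix is not positive definite") from err
        z = rng.standard_normal((n_sites, len(free))) @ chol.T * scale
        for j, n in enumerate(free):
            data[n] = z[:, j]
    for grp in nested_groups:
        inc = np.abs(rng.standard_normal((n_sites, len(grp)))) * scale
        cum = np.cumsum(inc, axis=1)
        for j, n in enumerate(grp):
            data[n] = cum[:, j]

    ids = [f"s{i:04d}" for i in range(n_sites)]
    frame = pd.DataFrame({n: data[n] for n in names}, index=pd.Index(ids, name="site_id"))
    specs = {
        n: PredictorSpec(
            n,
            "synthetic",
            "point_value",
            direction=(directions or {}).get(n, "either"),
        )
        for n in names
    }
    area_series = None
    if areas is not None:
        area_series = pd.Series(list(areas), index=frame.index, name="area")
        if area_reference is not None:
            for label in sorted(set(areas)):
                if label != area_reference:
                    frame[f"Area_{label}"] = (area_series == label).astype(float)
    return PredictorTable(frame, specs, area_reference, area_series)


@dataclass(frozen=True)
class TruthModel:
    """The data-generating model behind a synthetic campaign."""

    pollutant: str
    intercept: float
    terms: dict[str, float]  # predictor name -> true coefficient
    area_offsets: dict[str, float] = field(default_factory=dict)
    site_noise_sd: float = 1.0
    seasonal_factors: tuple[float, ...] = DEFAULT_SEASONAL_FACTORS
    measurement_sd: float = 0.05  # lognormal sd of multiplicative period noise

    def site_means(self, table: PredictorTable) -> pd.Series:
        mu = pd.Series(self.intercept, index=table.frame.index, dtype=float)
        for name, coef in self.terms.items():
            mu = mu + coef * table.frame[name]
        if self.area_offsets:
            if table.areas is None:
                raise ValueError("area offsets given but table has no area labels")
            mu = mu + table.areas.map(self.area_offsets).astype(float)
        return mu


def generate_campaign(
    truth: TruthModel,
    table: PredictorTable,
    seed: int = 0,
    periods: int = 3,
    invalid_fraction: float = 0.0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ReferenceSeries], pd.Series]:
    """Simulate repeated seasonal measurements plus per-area references.

    Returns (measurements frame, reference series keyed by
    (area, pollutant), true site long-term means).  Site period values are
    mean * s_p * exp(nu) with nu ~ N(0, measurement_sd^2); the reference
    series shares the seasonal factors exactly, so temporal adjustment
    can recover the means.  ``invalid_fraction`` of site-periods are
    flagged invalid to exercise the minimum-season exclusion rule.
    """
    rng = np.random.default_rng(seed)
    s = np.asarray(truth.seasonal_factors[:periods], dtype=float)
    if len(s) < periods:
        raise ValueError("fewer seasonal factors than periods")
    base = truth.site_means(table)
    mu = base + rng.normal(0.0, truth.site_noise_sd, len(base))
    mu = mu.clip(lower=1e-6)

    areas = table.areas if table.areas is not None else pd.Series(
        "all", index=table.frame.index
    )
    rows = []
    for sid in table.frame.index:
        for p in range(periods):
            nu = rng.normal(0.0, truth.measurement_sd)
            rows.append(
                {
                    "site_id": sid,
                    "pollutant": truth.pollutant,
                    "period_id": f"P{p + 1}",
                    "value": float(mu[sid] * s[p] * math.exp(nu)),
                    "valid": bool(rng.uniform() >= invalid_fraction),
                }
            )
    measurements = pd.DataFrame(rows)

    references: dict[tuple[str, str], ReferenceSeries] = {}
    for label in sorted(set(areas)):
        ref_base = float(mu[areas == label].median())
        references[(label, truth.pollutant)] = ReferenceSeries(
            area=label,
            pollutant=truth.pollutant,
            period_means={f"P{p + 1}": ref_base * s[p] for p in range(periods)},
            biannual_mean=ref_base * float(s.mean()),
        )
    return measurements, references, mu
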