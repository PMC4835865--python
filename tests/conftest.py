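import numpy as np
import pytest
from shapely.geometry import LineString, box

from lurkit.gis import ClassedPolygonLayer, RoadLayer, RoadSegment, Site


@pytest.fixture
def origin_site() -> Site:
    return Site("s0", 0.0, 0.0, "A", "urban_background")


def random_polygon_layer(rng: np.random.Generator, n: int = 12, extent: float = 600.0,
                         cls: str = "building") -> ClassedPolygonLayer:
    """Non-overlapping axis-aligned rectangles on a jittered grid."""
    polys = []
    cells = int(np.ceil(np.sqrt(n)))
    pitch = 2 * extent / cells
    chosen = rng.choice(cells * cells, size=n, replace=False)
    for c in chosen:
        gx, gy = c % cells, c // cells
        x0 = -extent + gx * pitch + rng.uniform(0, pitch * 0.2)
        y0 = -extent + gy * pitch + rng.uniform(0, pitch * 0.2)
        w = rng.uniform(pitch * 0.2, pitch * 0.7)
        h = rng.uniform(pitch * 0.2, pitch * 0.7)
        polys.append(box(x0, y0, x0 + w, y0 + h))
    return ClassedPolygonLayer(polys, [cls] * n)


def random_road_layer(rng: np.random.Generator, n: int = 10, extent: float = 400.0) -> RoadLayer:
    segs = []
    for i in range(n):
        x0, y0 = rng.uniform(-extent, extent, 2)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(50, 500)
        seg = LineString(
            [(x0, y0), (x0 + length * np.cos(ang), y0 + length * np.sin(ang))]
        )
        segs.append(
            RoadSegment(
                f"r{i:03d}", seg,
                intensity=float(rng.lognormal(np.log(1500), 1.2)),
                heavy_share=float(rng.beta(2, 18)),
            )
        )
    return RoadLayer(segs)
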