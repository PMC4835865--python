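"""Geometry engine: buffer statistics, nearest-road metrics, raster overlay."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, box

from lurkit.gis import (
    ClassedPolygonLayer,
    PredictorSpec,
    RasterGrid,
    RoadLayer,
    RoadSegment,
    Site,
    NoQualifyingRoadError,
    buffer_area,
    buffer_line_length,
    buffer_traffic_load,
    build_predictor_table,
    nearest_road_metrics,
    raster_at_point,
    raster_buffer_sum,
    standard_predictor_specs,
)

from _oracles import grid_count_area, sampled_line_length
from conftest import random_polygon_layer, random_road_layer


class TestBufferArea:
    def test_fully_contained_square(self, origin_site):
        layer = ClassedPolygonLayer([box(100, 100, 200, 200)], ["building"])
        assert buffer_area(layer, origin_site, 1000) == pytest.approx(10000.0)

    def test_no_polygons_in_radius(self, origin_site):
        layer = ClassedPolygonLayer([box(5000, 5000, 5100, 5100)], ["building"])
        assert buffer_area(layer, origin_site, 300) == 0.0

    def test_class_filter(self, origin_site):
        layer = ClassedPolygonLayer(
            [box(0, 0, 10, 10), box(20, 20, 30, 30)], ["HDRES", "NATURAL"]
        )
        assert buffer_area(layer, origin_site, 100, {"HDRES"}) == pytest.approx(100.0)

    def test_additivity_over_disjoint_class_sets(self, origin_site):
        rng = np.random.default_rng(7)
        polys, classes = [], []
        for cls in ("HDRES", "NATURAL", "URBGREEN"):
            lay = random_polygon_layer(rng, n=6, extent=400, cls=cls)
            polys.extend(lay.geometries)
            classes.extend([cls] * 6)
        layer = ClassedPolygonLayer(polys, classes)
        parts = sum(
            buffer_area(layer, origin_site, 300, {c}) for c in ("HDRES", "NATURAL")
        )
        union = buffer_area(layer, origin_site, 300, {"HDRES", "NATURAL"})
        assert parts == pytest.approx(union, rel=1e-12)

    def test_against_rasterisation_oracle(self, origin_site):
        rng = np.random.default_rng(11)
        layer = random_polygon_layer(rng, n=16, extent=500)
        got = buffer_area(layer, origin_site, 300)
        want = grid_count_area(list(layer.geometries), 0.0, 0.0, 300, step=1.0)
        assert got == pytest.approx(want, rel=0.005)


class TestBufferLineLength:
    def test_chord_through_center(self, origin_site):
        roads = RoadLayer([RoadSegment("r0", LineString([(-500, 0), (500, 0)]), 1000)])
        for r in (25, 100, 300):
            assert buffer_line_length(roads, origin_site, r) == pytest.approx(2 * r, rel=1e-4)

    def test_road_outside_buffer(self, origin_site):
        roads = RoadLayer([RoadSegment("r0", LineString([(900, 0), (900, 100)]), 1000)])
        assert buffer_line_length(roads, origin_site, 100) == 0.0

    def test_major_only_restricts(self, origin_site):
        roads = RoadLayer(
            [
                RoadSegment("minor", LineString([(-50, 10), (50, 10)]), 4999),
                RoadSegment("major", LineString([(-50, -10), (50, -10)]), 5000),
            ]
        )
        assert buffer_line_length(roads, origin_site, 100, major_only=True) == pytest.approx(100.0)
        assert buffer_line_length(roads, origin_site, 100) == pytest.approx(200.0)

    def test_against_point_sampling_oracle(self, origin_site):
        rng = np.random.default_rng(3)
        roads = random_road_layer(rng, n=12, extent=150)
        got = buffer_line_length(roads, origin_site, 100)
        want = sampled_line_length(
            [s.geometry for s in roads.segments], 0, 0, 100, step=0.1
        ).sum()
        assert got == pytest.approx(want, rel=0.005, abs=1.0)


class TestTrafficLoad:
    def test_single_contained_segment(self, origin_site):
        roads = RoadLayer([RoadSegment("r0", LineString([(-100, 0), (100, 0)]), 8000)])
        got = buffer_traffic_load(roads, origin_site, 1000)
        assert got == pytest.approx(8000 * 200)

    def test_heavy_zero_share(self, origin_site):
        roads = RoadLayer([RoadSegment("r0", LineString([(-100, 0), (100, 0)]), 8000, 0.0)])
        assert buffer_traffic_load(roads, origin_site, 1000, variant="heavy") == 0.0

    def test_heavy_uses_share(self, origin_site):
        roads = RoadLayer([RoadSegment("r0", LineString([(-100, 0), (100, 0)]), 8000, 0.25)])
        got = buffer_traffic_load(roads, origin_site, 1000, variant="heavy")
        assert got == pytest.approx(8000 * 0.25 * 200)

    def test_mixed_network_matches_clip_oracle(self, origin_site):
        rng = np.random.default_rng(5)
        roads = random_road_layer(rng, n=15, extent=200)
        buf_r = 150
        # independent per-segment clip-and-sum with the sampling oracle
        lens = sampled_line_length([s.geometry for s in roads.segments], 0, 0, buf_r, step=0.05)
        want = float((roads.intensity * lens).sum())
        got = buffer_traffic_load(roads, origin_site, buf_r)
        assert got == pytest.approx(want, rel=0.005, abs=1.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            RoadSegment("bad", LineString([(0, 0), (1, 1)]), -10)


class TestNearestRoad:
    def test_direct_formula(self, origin_site):
        roads = RoadLayer([RoadSegment("r0", LineString([(20, -100), (20, 100)]), 10000)])
        m = nearest_road_metrics(roads, origin_site)
        assert m == pytest.approx(
            {"distance_m": 20, "intensity": 10000,
             "inverse_distance": 0.05, "intensity_times_inverse_distance": 500}
        )

    def test_distance_zero_clamped(self, origin_site):
        roads = RoadLayer([RoadSegment("r0", LineString([(-10, 0), (10, 0)]), 6000)])
        m = nearest_road_metrics(roads, origin_site, min_distance_m=1.0)
        assert m["distance_m"] == 1.0
        assert m["inverse_distance"] == 1.0

    def test_equidistant_tiebreak(self, origin_site):
        a = RoadSegment("a", LineString([(50, -10), (50, 10)]), 2000)
        b = RoadSegment("b", LineString([(-50, -10), (-50, 10)]), 7000)
        for order in ([a, b], [b, a]):  # enumerate both orderings
            m = nearest_road_metrics(RoadLayer(order), origin_site)
            assert m["intensity"] == 7000  # higher intensity wins
        # equal intensities: lexicographic id wins
        c = RoadSegment("c", LineString([(50, -10), (50, 10)]), 2000)
        d = RoadSegment("b2", LineString([(-50, -10), (-50, 10)]), 2000)
        for order in ([c, d], [d, c]):
            m = nearest_road_metrics(RoadLayer(order), origin_site, heavy=False)
            # "b2" < "c": chosen deterministic regardless of input order
            assert m["intensity"] == 2000

    def test_no_qualifying_road(self, origin_site):
        roads = RoadLayer([RoadSegment("r0", LineString([(5, -5), (5, 5)]), 100)])
        with pytest.raises(NoQualifyingRoadError):
            nearest_road_metrics(roads, origin_site, major_only=True)

    def test_heavy_scales_intensity(self, origin_site):
        roads = RoadLayer([RoadSegment("r0", LineString([(10, -5), (10, 5)]), 8000, 0.1)])
        m = nearest_road_metrics(roads, origin_site, heavy=True)
        assert m["intensity"] == pytest.approx(800.0)


class TestRaster:
    def grid(self):
        vals = np.arange(12, dtype=float).reshape(3, 4)  # row 0 = north
        return RasterGrid(0.0, 0.0, 10.0, vals)

    def test_cell_center(self):
        g = self.grid()
        # cell col 1, bottom row (south) -> array row 2
        assert raster_at_point(g, Site("s", 15.0, 5.0)) == g.values[2, 1]

    def test_boundary_lower_left_inclusive(self):
        g = self.grid()
        # x=10 is the left edge of col 1; y=10 bottom edge of middle row
        assert raster_at_point(g, Site("s", 10.0, 10.0)) == g.values[1, 1]

    def test_constant_raster(self):
        g = RasterGrid(0, 0, 10, np.full((3, 4), 7.0))
        for xy in [(1, 1), (35, 25), (20, 10)]:
            assert raster_at_point(g, Site("s", *map(float, xy))) == 7.0

    def test_outside_extent_raises(self):
        with pytest.raises(ValueError, match="outside"):
            raster_at_point(self.grid(), Site("s", -1.0, 5.0))

    def test_buffer_sum_counts_cell_centers(self):
        g = RasterGrid(0, 0, 10, np.ones((10, 10)))
        got = raster_buffer_sum(g, Site("s", 50.0, 50.0), 25.0)
        # count cells with centre within 25 m of (50,50)
        xs = np.arange(10) * 10 + 5.0
        X, Y = np.meshgrid(xs, xs)
        want = ((X - 50) ** 2 + (Y - 50) ** 2 <= 625).sum()
        assert got == want


class TestPredictorTable:
    def _simple_layers(self):
        alt = RasterGrid(-50, -50, 100.0, np.array([[100.0]]), role="altitude")
        roads = RoadLayer([RoadSegment("r0", LineString([(-50, 10), (50, 10)]), 6000)])
        return {"altitude": alt, "roads": roads}

    def test_transforms(self):
        specs = [
            PredictorSpec("ALT", "altitude", "point_value", direction="negative"),
            PredictorSpec("LOG_ALT", "altitude", "point_value", transform="log",
                          direction="negative"),
            PredictorSpec("SQRT_ALT", "altitude", "point_value", transform="sqrt",
                          direction="negative"),
        ]
        t = build_predictor_table([Site("s0", 0, 0, "A")], self._simple_layers(), specs)
        assert t.frame.loc["s0", "ALT"] == 100.0
        assert t.frame.loc["s0", "LOG_ALT"] == pytest.approx(math.log(100.0))
        assert t.frame.loc["s0", "SQRT_ALT"] == pytest.approx(10.0)

    def test_log_of_nonpositive_raises(self):
        layers = {"altitude": RasterGrid(-50, -50, 100.0, np.array([[0.0]]), role="altitude")}
        spec = PredictorSpec("LOG_ALT", "altitude", "point_value", transform="log")
        with pytest.raises(ValueError, match="positive"):
            build_predictor_table([Site("s0", 0, 0)], layers, [spec])

    def test_area_dummies_reference(self):
        sites = [Site("a1", 0, 0, "A"), Site("b1", 1, 1, "B"), Site("b2", 2, 2, "B")]
        t = build_predictor_table(sites, self._simple_layers(),
                                  [PredictorSpec("ALT", "altitude", "point_value")],
                                  area_reference="A")
        assert list(t.frame.columns) == ["ALT", "Area_B"]
        assert t.frame["Area_B"].tolist() == [0.0, 1.0, 1.0]

    def test_unknown_source_raises(self):
        with pytest.raises(KeyError, match="source layer"):
            build_predictor_table([Site("s0", 0, 0)], {}, [
                PredictorSpec("BUILDINGS_100", "buildings", "area_sum", buffer_m=100)])

    def test_full_inventory_on_synthetic_landscape(self):
        from lurkit.synthetic import LandscapeConfig, generate_landscape

        scape = generate_landscape(
            LandscapeConfig(n_areas=2, sites_per_area=5, roads_per_area=25,
                            buildings_per_area=40), seed=0)
        specs = standard_predictor_specs()
        t = build_predictor_table(scape.sites, scape.layers, specs,
                                  scape.config.area_names()[0])
        assert len(specs) == 174  # the full printed inventory
        assert t.frame.shape == (10, 175)  # + one area dummy
        assert np.isfinite(t.frame.to_numpy()).all()


class TestMonotonicityInvariants:
    def test_nested_buffers_and_major_subset(self, origin_site):
        rng = np.random.default_rng(13)
        roads = random_road_layer(rng, n=20, extent=800)
        layer = random_polygon_layer(rng, n=20, extent=800)
        radii = [25, 50, 100, 300, 500, 1000]
        areas = [buffer_area(layer, origin_site, r) for r in radii]
        lens = [buffer_line_length(roads, origin_site, r) for r in radii]
        loads = [buffer_traffic_load(roads, origin_site, r) for r in radii]
        for seq in (areas, lens, loads):
            assert all(a <= b + 1e-9 for a, b in zip(seq, seq[1:]))
        for r in radii:
            assert buffer_line_length(roads, origin_site, r, major_only=True) <= \
                buffer_line_length(roads, origin_site, r) + 1e-9
            assert buffer_traffic_load(roads, origin_site, r, variant="major") <= \
                buffer_traffic_load(roads, origin_site, r) + 1e-9
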