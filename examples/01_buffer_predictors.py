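"""Extract GIS buffer predictors for monitoring sites on a synthetic landscape.

Builds a two-area landscape (roads with traffic intensities, buildings,
land-use polygons, population/altitude/dispersion rasters), then evaluates
the full standard predictor inventory at every site.
"""

from lurkit import (
    LandscapeConfig,
    build_predictor_table,
    generate_landscape,
    standard_predictor_specs,
)

config = LandscapeConfig(n_areas=2, sites_per_area=10, roads_per_area=30,
                         buildings_per_area=80)
scape = generate_landscape(config, seed=42)
specs = standard_predictor_specs()
table = build_predictor_table(scape.sites, scape.layers, specs,
                              area_reference=config.area_names()[0])

print(f"{len(scape.sites)} sites x {table.frame.shape[1]} predictors")
cols = ["BUILDINGS_100", "ROADLENGTH_100", "TRAFLOAD_100", "TRAFNEAR", "ALT",
        "NO2_2010", "Area_area_B"]
print(table.frame[cols].head(6).round(1).to_string())
print()
print("Each row characterises one site: built-up area (m^2) and road length (m)")
print("within 100 m, traffic load (veh/day*m), traffic on the nearest road,")
print("altitude (m), the dispersion-model background (ug/m3), and the area dummy.")
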