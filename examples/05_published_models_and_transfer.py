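"""Evaluate the shipped published model equations and the transfer rules.

Loads the published campaign models, reproduces their worked-example
predictions, and demonstrates predictor truncation plus the
10 km / 20 km / 1000 m model-assignment rules.
"""

import math

import numpy as np

from lurkit import (
    LocalModel,
    ModelAssignmentRule,
    Site,
    assign_model,
    available_models,
    evaluate_model,
    load_published_model,
    truncate_predictors,
)

print("shipped model equations:", ", ".join(available_models()))
print()

alpine = load_published_model("no2_alpine")
print("alpine NO2 at a site with all predictors zero:",
      evaluate_model(alpine, {t.name: 0.0 for t in alpine.terms}), "ug/m3")

payerne = load_published_model("no2_payerne")
print("Payerne NO2 at a site with all predictors zero:",
      evaluate_model(payerne, {t.name: 0.0 for t in payerne.terms}), "ug/m3")

absorb = load_published_model("pm25_absorbance")
vals = {t.name: 0.0 for t in absorb.terms}
vals["LOG_ALT"] = math.log(1.0)
print("PM2.5 absorbance at 1 m altitude, all else zero:",
      evaluate_model(absorb, vals), "x1e-5/m")
print("(each equals the model intercept: every linear term vanishes)")
print()

# transfer: truncation to training ranges, dispersion exempt
payerne.training_ranges = {"BUILDINGS_50": (0.0, 6000.0),
                           "TRAFLOAD_50": (0.0, 8.0e5), "ALT": (430.0, 560.0)}
raw = {"BUILDINGS_50": 9000.0, "TRAFLOAD_50": 5.0e5, "ALT": 700.0}
print("raw predictors at a new site:", raw)
print("after truncation:            ", truncate_predictors(payerne, raw))

rule = ModelAssignmentRule(
    local_models=[LocalModel("payerne", payerne, np.array([[0.0, 0.0]]), 10.0)],
    alpine=alpine, non_alpine=load_published_model("no2_non_alpine"))
for x, alt in ((5_000.0, 450.0), (50_000.0, 1400.0), (50_000.0, 450.0)):
    name, _ = assign_model(Site("p", x, 0.0, altitude_m=alt), rule)
    print(f"station at {x/1000:.0f} km, {alt:.0f} m altitude -> {name} model")
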