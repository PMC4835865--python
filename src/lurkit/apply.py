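"""Applying fitted models at new locations.

Covers the rules used when transferring models beyond their training
sites: predictor truncation to training ranges (dispersion-derived
predictors exempt, since they represent regional background and may
legitimately exceed the training range), distance-based model
assignment (local models within their radius, then an altitude-split
fallback pair), and external-validation summaries against independently
observed long-term means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gis import Site
from .model import LURModel, evaluate_model

__all__ = [
    "LocalModel",
    "ModelAssignmentRule",
    "ExternalValidationSummary",
    "truncate_predictors",
    "assign_model",
    "external_validate",
]

ALTITUDE_THRESHOLD_M = 1000.0


@dataclass
class LocalModel:
    """A model applicable within ``radius_km`` of its training sites."""

    name: str
    model: LURModel
    training_xy: np.ndarray  # (n, 2) projected coordinates of training sites
    radius_km: float = 10.0

    def __post_init__(self) -> None:
        self.training_xy = np.asarray(self.training_xy, dtype=float)
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")

    def min_distance_km(self, x: float, y: float) -> float:
        d = np.hypot(self.training_xy[:, 0] - x, self.training_xy[:, 1] - y)
        return float(d.min()) / 1000.0


@dataclass
class ModelAssignmentRule:
    """Local models first, altitude-split fallback pair otherwise.

    A point is served by the local model with the nearest training site
    among those whose minimum distance is within their radius (default
    10 km for area-specific models, 20 km for area-indicator models; ties
    go to the lexicographically first name).  Otherwise the alpine model
    applies at or above the altitude threshold and the non-alpine model
    below it.
    """

    local_models: list[LocalModel] = field(default_factory=list)
    alpine: LURModel | None = None
    non_alpine: LURModel | None = None
    altitude_threshold_m: float = ALTITUDE_THRESHOLD_M


def truncate_predictors(
    model: LURModel, values: Mapping[str, float]
) -> dict[str, float]:
    """Clamp predictor values into the model's training ranges.

    Dispersion-derived predictors listed in ``model.truncation_exempt``
    pass through unchanged.  A non-exempt model predictor without a
    recorded training range is an error.
    """
    out: dict[str, float] = dict(values)
    for term in model.terms:
        name = term.name
        if name not in values:
            raise KeyError(f"predictor {name!r} missing from supplied values")
        if name in model.truncation_exempt:
            continue
        if name not in model.training_ranges:
            raise KeyError(f"no training range recorded for predictor {name!r}")
        lo, hi = model.training_ranges[name]
        out[name] = float(min(max(values[name], lo), hi))
    return out


def assign_model(point: Site, rule: ModelAssignmentRule) -> tuple[str, LURModel]:
    """(name, model) chosen for the point; deterministic and total given altitude."""
    in_range: list[tuple[float, str, LocalModel]] = []
    for lm in rule.local_models:
        d = lm.min_distance_km(point.x, point.y)
        if d <= lm.radius_km:
            in_range.append((d, lm.name, lm))
    if in_range:
        in_range.sort(key=lambda t: (t[0], t[1]))
        _, name, lm = in_range[0]
        return name, lm.model
    if point.altitude_m is None:
        raise ValueError(
            f"point {point.site_id!r} outside all local-model radii and has no altitude"
        )
    if point.altitude_m >= rule.altitude_threshold_m:
        if rule.alpine is None:
            raise ValueError("no alpine fallback model configured")
        return "alpine", rule.alpine
    if rule.non_alpine is None:
        raise ValueError("no non-alpine fallback model configured")
    return "non_alpine", rule.non_alpine


@dataclass
class ExternalValidationSummary:
    n: int
    mean_overprediction: float  # predicted - observed
    sd_overprediction: float
    r2: float
    predictions: pd.DataFrame
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (station, reason)


def external_validate(
    rule: ModelAssignmentRule,
    stations: Sequence[Site],
    observed: Mapping[str, float],
    predictor_values: Mapping[str, Mapping[str, float]],
) -> ExternalValidationSummary:
    """Assign, truncate and predict at external stations; summarise errors.

    ``observed`` maps station id to its measured long-term mean and
    ``predictor_values`` to that station's named predictor values.
    Stations that cannot be assigned (or lack predictors) are skipped
    with a reason.  Needs at least 2 successful predictions for an R^2.
    """
    rows = []
    skipped: list[tuple[str, str]] = []
    for st in stations:
        if st.site_id not in observed:
            skipped.append((st.site_id, "no observation"))
            continue
        try:
            name, model = assign_model(st, rule)
            vals = truncate_predictors(model, predictor_values[st.site_id])
            pred = evaluate_model(model, vals)
        except (ValueError, KeyError) as err:
            skipped.append((st.site_id, str(err)))
            continue
        rows.append(
            {
                "station": st.site_id,
                "model": name,
                "predicted": pred,
                "observed": float(observed[st.site_id]),
            }
        )
    if len(rows) < 2:
        raise ValueError(f"fewer than 2 assignable stations (skipped: {skipped})")
    frame = pd.DataFrame(rows).set_index("station")
    over = frame["predicted"] - frame["observed"]
    if frame["predicted"].std() == 0 or frame["observed"].std() == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(frame["predicted"], frame["observed"])[0, 1] ** 2)
    return ExternalValidationSummary(
        n=len(frame),
        mean_overprediction=float(over.mean()),
        sd_overprediction=float(over.std(ddof=1)),
        r2=r2,
        predictions=frame,
        skipped=skipped,
    )
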