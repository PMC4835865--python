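"""End-to-end orchestration of the modelling stages on a scenario config.

Stage order mirrors the modelling workflow: simulate (or load) the
landscape, extract predictors, temporally adjust measurements, screen
candidates, fit models phase by phase, validate, and write a manifest
with digests of every artifact so a rerun with the same seed is
verifiably identical.

The four modelling phases are encoded as presets:

* ``plain``            - one combined model over all sites, dispersion
                         predictors considered but not forced;
* ``forced_dispersion`` - the relevant dispersion surface is forced in
                         to carry between-area background differences;
* ``area_indicator``   - 0/1 area dummies are forced in instead,
                         restricting applicability to the training areas;
* ``per_area``         - one model per study area, fitted on that
                         area's sites only.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import geoio
from .gis import build_predictor_table, standard_predictor_specs, PredictorTable
from .model import LURModel, forward_select
from .screening import screen
from .synthetic import (
    LandscapeConfig,
    TruthModel,
    generate_campaign,
    generate_landscape,
)
from .temporal import adjust_measurements
from .validation import validate_model

__all__ = ["ScenarioConfig", "run_pipeline", "fit_phase"]

PHASES = ("plain", "forced_dispersion", "area_indicator", "per_area")

_DISPERSION_BY_POLLUTANT = {
    "NO2": "NO2_2010",
    "PM2.5": "PM25_2010",
    "PM2.5_abs": "NO2_2010",
    "PM10": "PM10_2010",
    "PMcoarse": "PM10_2010",
}

KNOWN_POLLUTANTS = {"NO2", "PM2.5", "PM2.5_abs", "PM10", "PMcoarse", "PNC", "LDSA"}


@dataclass
class ScenarioConfig:
    """Validated scenario settings for a synthetic end-to-end run."""

    pollutant: str = "NO2"
    seed: int = 0
    landscape: LandscapeConfig = None
    truth_terms: Mapping[str, float] = None
    truth_intercept: float = 12.0
    area_offsets: Mapping[str, float] | None = None
    site_noise_sd: float = 2.0
    measurement_sd: float = 0.05
    invalid_fraction: float = 0.03
    phases: Sequence[str] = PHASES

    def __post_init__(self) -> None:
        if self.pollutant not in KNOWN_POLLUTANTS:
            raise ValueError(
                f"unknown pollutant {self.pollutant!r}; known: {sorted(KNOWN_POLLUTANTS)}"
            )
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases {sorted(unknown)}; known: {PHASES}")
        if self.landscape is None:
            self.landscape = LandscapeConfig()
        if self.truth_terms is None:
            self.truth_terms = {"TRAFLOAD_100": 2e-6, "BUILDINGS_300": 5e-5}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "landscape" in d and isinstance(d["landscape"], Mapping):
            d["landscape"] = LandscapeConfig(**d["landscape"])
        return cls(**d)


def fit_phase(
    phase: str,
    y: pd.Series,
    table: PredictorTable,
    pollutant: str,
    dispersion_candidates: Sequence[str] = (),
) -> dict[str, LURModel]:
    """Fit the models of one phase; returns {model name: model}."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    dummies = [c for c in table.frame.columns if table.is_area_dummy(c)]
    non_dummy = [c for c in table.frame.columns if not table.is_area_dummy(c)]
    exempt_dispersion = set(dispersion_candidates)

    def _fit(sub_ids, forced, candidates, name) -> dict[str, LURModel]:
        sub = table.subset(list(sub_ids))
        sub_report = screen(sub, exempt=forced)
        # restrict eligibility to the phase's candidate pool
        pool = set(candidates) | set(forced)
        sub_report.screens = {
            k: v for k, v in sub_report.screens.items() if k in pool
        }
        model = forward_select(
            y.loc[list(sub_ids)].to_numpy(),
            sub,
            sub_report,
            forced=forced,
            pollutant=pollutant,
            truncation_exempt=exempt_dispersion,
        )
        return {name: model}

    all_ids = list(table.frame.index)
    if phase == "plain":
        return _fit(all_ids, [], non_dummy, "combined")
    if phase == "forced_dispersion":
        disp = _DISPERSION_BY_POLLUTANT.get(pollutant)
        forced = [disp] if disp and disp in table.frame.columns else []
        return _fit(all_ids, forced, non_dummy, "combined_forced_dispersion")
    if phase == "area_indicator":
        candidates = [c for c in non_dummy if c not in exempt_dispersion]
        return _fit(all_ids, dummies, candidates, "combined_area_indicator")
    # per_area
    out: dict[str, LURModel] = {}
    if table.areas is None:
        raise ValueError("per-area phase requires area labels")
    for label in sorted(set(table.areas)):
        ids = table.areas.index[table.areas == label]
        out.update(_fit(ids, [], non_dummy, f"area_{label}"))
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: ScenarioConfig, outdir) -> dict:
    """Execute all stages on a synthetic scenario; write artifacts + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.__dict__.copy(),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "digests": {},
    }
    manifest["config"]["landscape"] = config.landscape.__dict__.copy()
    manifest["config"]["truth_terms"] = dict(config.truth_terms)
    manifest["config"]["phases"] = list(config.phases)

    def _stage(name):
        manifest["stages"][name] = time.strftime("%Y-%m-%dT%H:%M:%S")

    try:
        _stage("simulate")
        scape = generate_landscape(config.landscape, seed=config.seed)
        geoio.write_sites_csv(scape.sites, outdir / "sites.csv")

        _stage("build_predictors")
        specs = standard_predictor_specs()
        ref_area = config.landscape.area_names()[0]
        table = build_predictor_table(scape.sites, scape.layers, specs, ref_area)
        table.to_csv(outdir / "predictors.csv")

        _stage("adjust")
        truth = TruthModel(
            pollutant=config.pollutant,
            intercept=config.truth_intercept,
            terms=dict(config.truth_terms),
            area_offsets=dict(config.area_offsets or {}),
            site_noise_sd=config.site_noise_sd,
            measurement_sd=config.measurement_sd,
        )
        measurements, references, _mu = generate_campaign(
            truth, table, seed=config.seed + 1, invalid_fraction=config.invalid_fraction
        )
        measurements.to_csv(outdir / "measurements.csv", index=False)
        site_areas = {s.site_id: s.area for s in scape.sites}
        adjusted = adjust_measurements(measurements, references, site_areas)
        adjusted.to_csv(outdir / "biannual.csv", index=False)

        kept = adjusted[~adjusted.excluded].set_index("site_id")
        y = kept["mean"]
        table_kept = table.subset(list(y.index))
        coords = np.array(
            [[s.x, s.y] for s in scape.sites if s.site_id in set(y.index)]
        )

        _stage("fit")
        disp = [n for n in ("NO2_2010", "PM25_2010", "PM10_2010") if n in table.frame.columns]
        models: dict[str, LURModel] = {}
        for phase in config.phases:
            models.update(
                fit_phase(phase, y, table_kept, config.pollutant, dispersion_candidates=disp)
            )
        for name, model in models.items():
            model.to_json(outdir / f"model_{name}.json")

        _stage("validate")
        reports = {}
        for name, model in models.items():
            if name.startswith("area_"):
                continue  # single-area models validated within their area only
            if not model.terms:
                continue
            rep = validate_model(
                model, y.to_numpy(), table_kept, coordinates=coords, seed=config.seed
            )
            reports[name] = rep.to_dict()
        with open(outdir / "validation.json", "w") as fh:
            json.dump(reports, fh, indent=1)
    except Exception as err:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "init"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["digests"][p.name] = _digest(p)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
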