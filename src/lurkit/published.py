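"""Loader for the published SAPALDIA-campaign model equations.

The package ships the final model equations reported for the Swiss
multi-area monitoring campaign (area-specific, alpine and non-alpine
NO2 models; multi-area models for PM2.5, PM2.5 absorbance, PM10,
PM_coarse, PNC and LDSA) as JSON fixtures.  Coefficients and fit
statistics are transcribed at their printed precision; training
predictor ranges were not published, so these models carry empty
ranges and are evaluated without truncation unless ranges are added.
"""

from __future__ import annotations

import json
from importlib import resources

from .model import LURModel

__all__ = ["available_models", "load_published_model"]

def _model_dir():
    return resources.files("lurkit") / "data" / "models"


def available_models() -> list[str]:
    """Keys of the shipped model equations (e.g. 'no2_alpine', 'pnc')."""
    return sorted(
        p.name[: -len(".json")]
        for p in _model_dir().iterdir()
        if p.name.endswith(".json")
    )


def load_published_model(key: str) -> LURModel:
    ref = _model_dir() / f"{key}.json"
    if not ref.is_file():
        raise KeyError(f"unknown model {key!r}; available: {available_models()}")
    return LURModel.from_dict(json.loads(ref.read_text()))
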