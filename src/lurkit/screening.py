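"""A-priori predictor eligibility screening.

Predictors whose values are driven by a handful of sites make unstable
coefficients with high Cook's distance, so before every model fit each
candidate is screened on the sites entering that fit:

rule 1 (mode count): ineligible when fewer than five sites take a value
other than the most common value (typically 0 for small port/industry
buffers).

rule 2/3 (outliers): ineligible when the maximum exceeds
P90 + 3*(P90-P10) or the minimum falls below P10 - 3*(P90-P10) — a
deliberately less restrictive variant of the usual quartile fences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .gis import PredictorTable

__all__ = ["PredictorScreen", "ScreeningReport", "rule_mode_count", "rule_outlier_bounds", "screen"]


@dataclass(frozen=True)
class PredictorScreen:
    name: str
    eligible: bool
    reasons: tuple[str, ...]
    p10: float
    p90: float
    lower: float
    upper: float
    exempt: bool = False


@dataclass
class ScreeningReport:
    screens: dict[str, PredictorScreen]
    n_sites: int

    @property
    def eligible(self) -> list[str]:
        return [n for n, s in self.screens.items() if s.eligible]

    def __getitem__(self, name: str) -> PredictorScreen:
        return self.screens[name]


def _mode(values: np.ndarray) -> float:
    # smallest modal value for a deterministic tie-break
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[counts == counts.max()].min())


def rule_mode_count(values: Sequence[float], min_other: int = 5) -> bool:
    """Pass iff at least ``min_other`` sites differ from the most common value."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    return int((v != _mode(v)).sum()) >= min_other


def rule_outlier_bounds(
    values: Sequence[float],
) -> tuple[float, float, bool]:
    """(lower, upper, pass) of the P10/P90 outlier fences.

    Percentiles use linear interpolation between order statistics.  When
    P10 == P90 (at least 80% identical values) the fences collapse onto
    that value and any other value fails — such columns are in practice
    also caught by the mode-count rule.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    p10, p90 = np.percentile(v, [10, 90], method="linear")
    spread = p90 - p10
    upper = p90 + 3.0 * spread
    lower = p10 - 3.0 * spread
    passed = bool(v.max() <= upper and v.min() >= lower)
    return float(lower), float(upper), passed


def screen(
    table: PredictorTable,
    site_subset: Sequence[str] | None = None,
    exempt: Iterable[str] = (),
    min_other: int = 5,
) -> ScreeningReport:
    """Evaluate both rules on the given site subset.

    Area-indicator dummies and any explicitly ``exempt`` predictors (e.g.
    forced dispersion terms) bypass the rules: they are introduced
    deliberately regardless of their distribution.  Screening is repeated
    before each model fit because eligibility depends on the site subset.
    """
    frame = table.frame if site_subset is None else table.frame.loc[list(site_subset)]
    if frame.shape[0] == 0:
        raise ValueError("site subset is empty")
    exempt_set = set(exempt)
    screens: dict[str, PredictorScreen] = {}
    for name in frame.columns:
        values = frame[name].to_numpy(dtype=float)
        if name in exempt_set or table.is_area_dummy(name):
            p10, p90 = np.percentile(values, [10, 90])
            screens[name] = PredictorScreen(
                name, True, (), float(p10), float(p90), float("-inf"), float("inf"),
                exempt=True,
            )
            continue
        reasons: list[str] = []
        if not rule_mode_count(values, min_other=min_other):
            reasons.append("too_few_distinct")
        lower, upper, ok = rule_outlier_bounds(values)
        if not ok:
            if values.max() > upper:
                reasons.append("high_outlier")
            if values.min() < lower:
                reasons.append("low_outlier")
        p10, p90 = np.percentile(values, [10, 90])
        screens[name] = PredictorScreen(
            name, not reasons, tuple(reasons), float(p10), float(p90), lower, upper
        )
    return ScreeningReport(screens, frame.shape[0])
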