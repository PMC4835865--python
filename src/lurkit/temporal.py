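"""Reference-site temporal adjustment of campaign measurements.

Short repeated campaigns (three 14-day periods spread over seasons) are
converted to biannual site averages by rescaling each period measurement
with the ratio of the reference site's biannual mean to its mean during
that period, under the assumption that the fixed reference monitor's
temporal variation reflects the whole area's seasonal pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MeasurementRecord",
    "ReferenceSeries",
    "SiteAverage",
    "correction_factor",
    "biannual_site_average",
    "adjust_measurements",
]


@dataclass(frozen=True)
class MeasurementRecord:
    site_id: str
    pollutant: str
    period_id: str
    value: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and self.value < 0:
            raise ValueError(
                f"negative concentration at {self.site_id}/{self.period_id}"
            )


@dataclass(frozen=True)
class ReferenceSeries:
    """Per-period reference-site means and the biannual mean, one area+pollutant."""

    area: str
    pollutant: str
    period_means: dict[str, float]
    biannual_mean: float

    def __post_init__(self) -> None:
        if self.biannual_mean <= 0:
            raise ValueError("biannual reference mean must be positive")


@dataclass(frozen=True)
class SiteAverage:
    site_id: str
    pollutant: str
    mean: float | None
    n_valid: int
    excluded: bool
    reason: str = ""


def correction_factor(ref: ReferenceSeries, period_id: str) -> float:
    """Biannual reference mean divided by the reference mean of the period."""
    if period_id not in ref.period_means:
        raise KeyError(f"period {period_id!r} missing from reference series")
    period_mean = ref.period_means[period_id]
    if period_mean <= 0:
        raise ValueError(f"non-positive reference period mean for {period_id!r}")
    return ref.biannual_mean / period_mean


def biannual_site_average(
    records: Sequence[MeasurementRecord],
    ref: ReferenceSeries,
    min_seasons: int = 2,
) -> SiteAverage:
    """Average the temporally corrected period values of one site.

    Each valid measurement is multiplied by its period's correction factor
    and the arithmetic mean is taken.  Sites with fewer than
    ``min_seasons`` valid periods are flagged excluded (mean None).
    """
    if not records:
        raise ValueError("no measurement records supplied")
    site_ids = {r.site_id for r in records}
    pollutants = {r.pollutant for r in records}
    if len(site_ids) != 1 or len(pollutants) != 1:
        raise ValueError("records must share one site and one pollutant")
    site_id, pollutant = site_ids.pop(), pollutants.pop()

    adjusted = [
        r.value * correction_factor(ref, r.period_id) for r in records if r.valid
    ]
    n_valid = len(adjusted)
    if n_valid == 0:
        return SiteAverage(site_id, pollutant, None, 0, True, "no valid measurements")
    if n_valid < min_seasons:
        return SiteAverage(
            site_id,
            pollutant,
            None,
            n_valid,
            True,
            f"valid measurements in only {n_valid} season(s)",
        )
    return SiteAverage(site_id, pollutant, sum(adjusted) / n_valid, n_valid, False)


def adjust_measurements(
    measurements: pd.DataFrame,
    references: dict[tuple[str, str], ReferenceSeries],
    site_areas: dict[str, str],
    min_seasons: int = 2,
) -> pd.DataFrame:
    """Tabular front-end: one adjusted biannual average per site and pollutant.

    ``measurements`` needs columns site_id, pollutant, period_id, value,
    valid; ``references`` maps (area, pollutant) to its series.  Returns a
    frame with columns site_id, pollutant, mean, n_valid, excluded, reason.
    """
    rows = []
    for (site_id, pollutant), group in measurements.groupby(
        ["site_id", "pollutant"], sort=True
    ):
        area = site_areas[site_id]
        ref = references[(area, pollutant)]
        records = [
            MeasurementRecord(
                site_id, pollutant, str(row.period_id), float(row.value), bool(row.valid)
            )
            for row in group.itertuples()
        ]
        avg = biannual_site_average(records, ref, min_seasons=min_seasons)
        rows.append(
            {
                "site_id": avg.site_id,
                "pollutant": avg.pollutant,
                "mean": avg.mean,
                "n_valid": avg.n_valid,
                "excluded": avg.excluded,
                "reason": avg.reason,
            }
        )
    return pd.DataFrame(rows)
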