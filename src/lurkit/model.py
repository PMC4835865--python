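"""Supervised forward selection of land-use-regression models.

The selection is "supervised" in the sense that a candidate predictor is
only admitted when its coefficient has the a-priori plausible sign
(traffic raises concentrations, green space lowers them), its two-sided
p-value is below 0.10, it improves the adjusted R-squared by at least
0.01 (from the second admission onward), and it does not flip the sign
of any previously admitted directional term.  Admission is greedy on the
adjusted-R-squared gain.  A finalisation pass then removes terms whose
p-value has drifted to 0.10 or above and enforces the collinearity
(VIF < 3) and influence (Cook's distance < 1) gates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gis import PredictorTable
from .screening import ScreeningReport

__all__ = [
    "FitResult",
    "LURModel",
    "ModelTerm",
    "RankDeficientError",
    "fit_ols",
    "vif",
    "cooks_distance",
    "forward_select",
    "finalize_model",
    "evaluate_model",
]

MAX_P = 0.10
MIN_GAIN = 0.01
VIF_LIMIT = 3.0
COOKS_LIMIT = 1.0


class RankDeficientError(ValueError):
    """The design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix rank deficient; collinear columns: {self.columns}")


@dataclass
class FitResult:
    """An ordinary-least-squares fit with the diagnostics the selection uses."""

    params: pd.Series  # includes "const"
    bse: pd.Series
    pvalues: pd.Series
    residuals: np.ndarray
    fitted: np.ndarray
    r2: float
    adj_r2: float
    rmse: float
    leverage: np.ndarray
    n: int
    k: int  # number of predictors (excluding intercept)

    @property
    def sigma2(self) -> float:
        """Unbiased residual variance s^2 = SSE / (n - k - 1)."""
        dof = self.n - self.k - 1
        return float(self.residuals @ self.residuals) / dof if dof > 0 else float("nan")


def _find_collinear(X: pd.DataFrame) -> list[str]:
    """Columns involved in a rank deficiency, via pivoted QR."""
    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    names = ["const"] + list(X.columns)
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return []
    # drop columns greedily: a column is redundant if removing it keeps rank
    redundant = []
    cols = list(range(design.shape[1]))
    for j in range(design.shape[1] - 1, 0, -1):
        keep = [c for c in cols if c != j]
        if np.linalg.matrix_rank(design[:, keep]) == rank:
            redundant.append(names[j])
            cols = keep
        if len(cols) == rank:
            break
    return sorted(redundant)


def fit_ols(y: Sequence[float], X: pd.DataFrame, rmse_ddof: int = 0) -> FitResult:
    """OLS with intercept.

    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1); RMSE uses the n
    denominator by default (``rmse_ddof`` switches to n - k - 1).
    Rank-deficient designs raise :class:`RankDeficientError` naming the
    collinear columns.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = X.shape[1]
    if np.isnan(y).any() or (k and X.isna().any().any()):
        raise ValueError("missing values in response or predictors")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    design = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise RankDeficientError(_find_collinear(X))
    res = sm.OLS(y, design).fit()
    resid = np.asarray(res.resid)
    sse = float(resid @ resid)
    denom = n - k - 1 if rmse_ddof else n
    rmse = math.sqrt(sse / denom)
    hat = res.get_influence().hat_matrix_diag if k >= 0 else None
    r2 = float(res.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return FitResult(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        residuals=resid,
        fitted=np.asarray(res.fittedvalues),
        r2=r2,
        adj_r2=adj,
        rmse=rmse,
        leverage=np.asarray(hat),
        n=n,
        k=k,
    )


def vif(X: pd.DataFrame, j: str) -> float:
    """Variance inflation factor of column ``j`` against the remaining columns.

    VIF_j = 1 / (1 - R^2_j); perfect collinearity returns +inf.
    """
    others = X.drop(columns=[j])
    if others.shape[1] == 0:
        return 1.0
    design = sm.add_constant(others.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        # the *other* columns are themselves collinear; regress on a basis
        design = design.loc[:, ~design.T.duplicated()]
    res = sm.OLS(np.asarray(X[j], dtype=float), design).fit()
    r2j = float(res.rsquared)
    if r2j >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2j)


def cooks_distance(fit: FitResult) -> np.ndarray:
    """Cook's distance per observation.

    D_i = e_i^2 h_i / (p s^2 (1 - h_i)^2) with p the number of estimated
    coefficients (intercept included) and s^2 the unbiased residual
    variance.
    """
    p = fit.k + 1
    h = fit.leverage
    e = fit.residuals
    s2 = fit.sigma2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = e**2 * h / (p * s2 * (1.0 - h) ** 2)
    return d


@dataclass(frozen=True)
class ModelTerm:
    name: str
    coef: float
    p_value: float | None = None
    direction: str = "either"


@dataclass
class LURModel:
    """A fitted land-use-regression model: intercept plus linear terms.

    Carries everything needed to apply it elsewhere: per-predictor
    training ranges for truncation, the set of truncation-exempt
    (dispersion-derived) predictors, and the geographic scope.
    """

    pollutant: str
    intercept: float
    terms: list[ModelTerm]
    stats: dict = field(default_factory=dict)  # r2, adj_r2, rmse
    scope: dict = field(default_factory=dict)  # areas, radius_km, altitude band
    training_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    truncation_exempt: set[str] = field(default_factory=set)
    forced: set[str] = field(default_factory=set)
    n_sites: int | None = None
    flags: list[str] = field(default_factory=list)
    admission_order: list[str] = field(default_factory=list)

    @property
    def predictor_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def predict(self, values: Mapping[str, float]) -> float:
        return evaluate_model(self, values)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pollutant": self.pollutant,
            "scope": self.scope,
            "intercept": self.intercept,
            "terms": [
                {"name": t.name, "coef": t.coef, "p": t.p_value, "direction": t.direction}
                for t in self.terms
            ],
            "stats": self.stats,
            "ranges": {k: [v[0], v[1]] for k, v in self.training_ranges.items()},
            "truncation_exempt": sorted(self.truncation_exempt),
            "forced": sorted(self.forced),
            "n_sites": self.n_sites,
            "flags": self.flags,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LURModel":
        return cls(
            pollutant=d["pollutant"],
            intercept=float(d["intercept"]),
            terms=[
                ModelTerm(
                    t["name"],
                    float(t["coef"]),
                    t.get("p"),
                    t.get("direction", "either"),
                )
                for t in d["terms"]
            ],
            stats=dict(d.get("stats", {})),
            scope=dict(d.get("scope", {})),
            training_ranges={
                k: (float(v[0]), float(v[1])) for k, v in d.get("ranges", {}).items()
            },
            truncation_exempt=set(d.get("truncation_exempt", [])),
            forced=set(d.get("forced", [])),
            n_sites=d.get("n_sites"),
            flags=list(d.get("flags", [])),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LURModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def evaluate_model(model: LURModel, values: Mapping[str, float]) -> float:
    """intercept + sum of coefficient * predictor value (no truncation)."""
    total = model.intercept
    for term in model.terms:
        if term.name not in values:
            raise KeyError(f"predictor {term.name!r} missing from supplied values")
        total += term.coef * float(values[term.name])
    return total


def _sign_ok(coef: float, direction: str) -> bool:
    if direction == "either":
        return True
    return coef > 0 if direction == "positive" else coef < 0


def _directions(table: PredictorTable, names: Iterable[str]) -> dict[str, str]:
    return {n: table.direction_of(n) for n in names}


def forward_select(
    y: Sequence[float],
    table: PredictorTable,
    report: ScreeningReport | None = None,
    forced: Iterable[str] = (),
    max_p: float = MAX_P,
    min_gain: float = MIN_GAIN,
    pollutant: str = "",
    truncation_exempt: Iterable[str] = (),
    finalize: bool = True,
) -> LURModel:
    """Greedy supervised forward selection.

    Starts from intercept + ``forced`` terms.  At each step every eligible
    remaining candidate is fitted alongside the current terms; candidates
    qualify when the coefficient sign matches the declared direction, the
    candidate p-value is below ``max_p``, the adjusted-R-squared gain is at
    least ``min_gain`` (second admission onward) and no previously admitted
    directional term flips sign.  The qualifying candidate with the
    largest gain is admitted (ties by name).  Forced terms are never
    removed but count toward the diagnostics.
    """
    y = np.asarray(y, dtype=float)
    forced = list(dict.fromkeys(forced))
    eligible = list(report.eligible) if report is not None else list(table.frame.columns)
    missing = [f for f in forced if f not in table.frame.columns]
    if missing:
        raise KeyError(f"forced predictors not in table: {missing}")
    candidates = [c for c in eligible if c not in forced]
    directions = _directions(table, list(table.frame.columns))

    current: list[str] = list(forced)
    flags: list[str] = []
    fit = fit_ols(y, table.frame[current])
    current_adj = fit.adj_r2
    n_admitted = 0

    while True:
        best: tuple[float, str] | None = None
        for cand in candidates:
            if cand in current:
                continue
            cols = current + [cand]
            try:
                trial = fit_ols(y, table.frame[cols])
            except (RankDeficientError, ValueError):
                continue
            if not _sign_ok(trial.params[cand], directions.get(cand, "either")):
                continue
            if trial.pvalues[cand] >= max_p:
                continue
            gain = trial.adj_r2 - current_adj
            if n_admitted >= 1 and gain < min_gain:
                continue
            flip = any(
                not _sign_ok(trial.params[prev], directions.get(prev, "either"))
                for prev in current
            )
            if flip:
                continue
            key = (gain, cand)
            if best is None or gain > best[0] or (gain == best[0] and cand < best[1]):
                best = key
        if best is None:
            break
        gain, chosen = best
        current.append(chosen)
        fit = fit_ols(y, table.frame[current])
        current_adj = fit.adj_r2
        n_admitted += 1

    if n_admitted == 0 and not forced:
        flags.append("no admissible first predictor; intercept-only model")

    model = _model_from_fit(
        pollutant, current, fit, table, set(forced), set(truncation_exempt), directions
    )
    model.flags.extend(flags)
    model.admission_order = list(current)
    if finalize:
        model = finalize_model(model, y, table)
    return model


def _model_from_fit(
    pollutant: str,
    names: list[str],
    fit: FitResult,
    table: PredictorTable,
    forced: set[str],
    truncation_exempt: set[str],
    directions: Mapping[str, str],
) -> LURModel:
    terms = [
        ModelTerm(n, float(fit.params[n]), float(fit.pvalues[n]), directions.get(n, "either"))
        for n in names
    ]
    ranges = {
        n: (float(table.frame[n].min()), float(table.frame[n].max())) for n in names
    }
    return LURModel(
        pollutant=pollutant,
        intercept=float(fit.params["const"]),
        terms=terms,
        stats={"r2": fit.r2, "adj_r2": fit.adj_r2, "rmse": fit.rmse},
        training_ranges=ranges,
        truncation_exempt=truncation_exempt & set(names),
        forced=forced,
        n_sites=fit.n,
        admission_order=list(names),
    )


def finalize_model(model: LURModel, y: Sequence[float], table: PredictorTable) -> LURModel:
    """Final p-value, collinearity and influence gates.

    Iteratively removes the non-forced term with the worst p-value >= 0.10
    and refits; then, while any VIF >= 3 or any Cook's distance >= 1,
    removes the most recently admitted non-forced offending term and
    refits.  Forced terms are exempt from removal but participate in the
    diagnostics.  Actions are recorded in ``model.flags``.
    """
    y = np.asarray(y, dtype=float)
    names = list(model.admission_order or model.predictor_names)
    forced = set(model.forced)
    flags = list(model.flags)
    directions = _directions(table, list(table.frame.columns))

    def _fit(cols: list[str]) -> FitResult:
        return fit_ols(y, table.frame[cols])

    # guard: a tie accident can admit perfectly collinear duplicates; drop
    # later-admitted columns until the design is full rank
    while True:
        try:
            fit = _fit(names)
            break
        except RankDeficientError as err:
            removable = [n for n in reversed(names) if n not in forced and n in err.columns]
            if not removable:
                raise
            names.remove(removable[0])
            flags.append(f"removed {removable[0]}: perfectly collinear")

    # 1) iterative worst-first removal of p >= 0.10 terms
    while True:
        droppable = [n for n in names if n not in forced and fit.pvalues[n] >= MAX_P]
        if not droppable:
            break
        worst = max(droppable, key=lambda n: fit.pvalues[n])
        names.remove(worst)
        flags.append(f"removed {worst}: p={fit.pvalues[worst]:.3f} >= {MAX_P}")
        fit = _fit(names)

    # 2) VIF and Cook's distance gates, latest-admitted offender removed
    while names:
        X = table.frame[names]
        vifs = {n: vif(X, n) for n in names} if len(names) > 1 else {names[0]: 1.0}
        offenders = [n for n in names if vifs[n] >= VIF_LIMIT and n not in forced]
        if offenders:
            victim = max(offenders, key=names.index)  # latest admitted
            names.remove(victim)
            flags.append(f"removed {victim}: VIF={vifs[victim]:.2f} >= {VIF_LIMIT}")
            fit = _fit(names)
            continue
        d = cooks_distance(fit)
        if np.nanmax(d, initial=0.0) >= COOKS_LIMIT:
            removable = [n for n in names if n not in forced]
            if not removable:
                flags.append(
                    f"Cook's D={np.nanmax(d):.2f} >= {COOKS_LIMIT} but only forced terms remain"
                )
                break
            victim = removable[-1]
            names.remove(victim)
            flags.append(
                f"removed {victim}: max Cook's D={np.nanmax(d):.2f} >= {COOKS_LIMIT}"
            )
            fit = _fit(names) if names else _fit([])
            continue
        break
    if not names:
        fit = _fit([])

    out = _model_from_fit(
        model.pollutant, names, fit, table, forced, set(model.truncation_exempt) | set(names) & model.truncation_exempt, directions
    )
    out.truncation_exempt = model.truncation_exempt & set(names)
    out.scope = dict(model.scope)
    out.flags = flags
    out.admission_order = names
    return out
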