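"""Cross-validation and residual diagnostics for fitted models.

The variable set is held fixed across folds (only coefficients are
refit), matching how land-use-regression models are conventionally
cross-validated: leave-one-site-out (LOOCV) for overall robustness and
leave-one-area-out (LOAOCV) for transferability between study areas.
Residual spatial structure is summarised by Moran's I with inverse
squared-distance weights, and residual dependence on study area by a
one-way ANOVA F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gis import PredictorTable
from .model import LURModel, RankDeficientError, fit_ols

__all__ = [
    "LoocvResult",
    "LoaocvAreaResult",
    "MoransIResult",
    "AreaTestResult",
    "ValidationReport",
    "loocv",
    "loaocv",
    "morans_i",
    "area_dependence_test",
    "validate_model",
]


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


@dataclass
class LoocvResult:
    r2: float
    rmse: float
    press_r2: float  # 1 - PRESS/SST, diverges from r2 under bias
    predictions: pd.Series
    excluded_folds: list[str]


@dataclass
class LoaocvAreaResult:
    area: str
    n: int
    mean_bias: float  # predicted - observed
    r2: float
    dropped_variables: list[str]


@dataclass
class MoransIResult:
    i: float
    expected: float
    p_value: float
    method: str


@dataclass
class AreaTestResult:
    f: float
    p_value: float
    excluded_areas: list[str]


@dataclass
class ValidationReport:
    loocv: LoocvResult | None = None
    loaocv: list[LoaocvAreaResult] | None = None
    morans_i: MoransIResult | None = None
    area_test: AreaTestResult | None = None

    def to_dict(self) -> dict:
        d: dict = {}
        if self.loocv:
            d["loocv"] = {
                "r2": self.loocv.r2,
                "rmse": self.loocv.rmse,
                "press_r2": self.loocv.press_r2,
            }
        if self.loaocv is not None:
            d["loaocv"] = [
                {"area": a.area, "n": a.n, "mean_bias": a.mean_bias, "r2": a.r2}
                for a in self.loaocv
            ]
        if self.morans_i:
            d["morans_i"] = {
                "I": self.morans_i.i,
                "expected": self.morans_i.expected,
                "p_value": self.morans_i.p_value,
                "method": self.morans_i.method,
            }
        if self.area_test:
            d["area_test"] = {"F": self.area_test.f, "p_value": self.area_test.p_value}
        return d


def loocv(variables: Sequence[str], y: Sequence[float], table: PredictorTable) -> LoocvResult:
    """Leave-one-out cross-validation with a fixed variable set.

    Each site is held out in turn, coefficients are refit on the n-1
    remaining sites, and the held-out site is predicted.  R^2 is the
    squared Pearson correlation of observed vs held-out predictions;
    RMSE is over held-out errors.  Folds whose refit is rank deficient
    are flagged and excluded from the summary.
    """
    y = np.asarray(y, dtype=float)
    X = table.frame[list(variables)]
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("need n > k + 2 sites for LOOCV")
    preds: dict[str, float] = {}
    excluded: list[str] = []
    ids = list(X.index)
    for i, sid in enumerate(ids):
        keep = np.arange(n) != i
        try:
            fit = fit_ols(y[keep], X.iloc[keep])
        except (RankDeficientError, ValueError):
            excluded.append(sid)
            continue
        row = X.iloc[i]
        preds[sid] = float(fit.params["const"] + sum(fit.params[v] * row[v] for v in variables))
    pred = pd.Series(preds)
    obs = pd.Series(y, index=ids).loc[pred.index]
    err = pred.to_numpy() - obs.to_numpy()
    sst = float(((obs - obs.mean()) ** 2).sum())
    press = float((err**2).sum())
    return LoocvResult(
        r2=_pearson_r2(obs.to_numpy(), pred.to_numpy()),
        rmse=float(np.sqrt(np.mean(err**2))),
        press_r2=1.0 - press / sst if sst > 0 else float("nan"),
        predictions=pred,
        excluded_folds=excluded,
    )


def loocv_closed_form(variables: Sequence[str], y: Sequence[float], table: PredictorTable) -> pd.Series:
    """Held-out residuals from the full fit via the hat-matrix identity e_i/(1-h_i)."""
    y = np.asarray(y, dtype=float)
    X = table.frame[list(variables)]
    fit = fit_ols(y, X)
    loo_resid = fit.residuals / (1.0 - fit.leverage)
    return pd.Series(y - loo_resid, index=X.index)


def loaocv(
    variables: Sequence[str],
    y: Sequence[float],
    table: PredictorTable,
    area_labels: Sequence[str] | None = None,
) -> list[LoaocvAreaResult]:
    """Leave-one-area-out cross-validation with a fixed variable set.

    For each area the model is refit on all other areas and applied to the
    held-out area.  A variable constant in the training complement but
    taking a different value in the held-out area encodes the area itself
    (an area-indicator dummy); predicting that area is then impossible and
    the operation refuses.  A variable constant everywhere in the
    training complement at the held-out area's own value is merely
    uninformative and is dropped from that fold with a flag.
    """
    y = np.asarray(y, dtype=float)
    if area_labels is None:
        if table.areas is None:
            raise ValueError("area labels required")
        area_labels = table.areas.to_numpy()
    areas = np.asarray(area_labels, dtype=object)
    labels = sorted(set(areas))
    if len(labels) < 2:
        raise ValueError("LOAOCV requires at least two areas")
    X = table.frame[list(variables)]
    results: list[LoaocvAreaResult] = []
    for label in labels:
        test = areas == label
        train = ~test
        Xtr, Xte = X.loc[train], X.loc[test]
        dropped = []
        use = list(variables)
        for v in variables:
            tr_vals = Xtr[v].to_numpy()
            if np.ptp(tr_vals) == 0.0:
                const = tr_vals[0]
                if np.any(Xte[v].to_numpy() != const):
                    raise ValueError(
                        f"variable {v!r} is constant in training but differs in area "
                        f"{label!r}: it encodes the held-out area and cannot be "
                        "cross-validated (area-indicator models apply only to their own areas)"
                    )
                use.remove(v)
                dropped.append(v)
        fit = fit_ols(y[train], Xtr[use])
        pred = fit.params["const"] + Xte[use].to_numpy() @ np.array(
            [fit.params[v] for v in use]
        )
        obs = y[test]
        results.append(
            LoaocvAreaResult(
                area=label,
                n=int(test.sum()),
                mean_bias=float(np.mean(pred - obs)),
                r2=_pearson_r2(obs, pred),
                dropped_variables=dropped,
            )
        )
    return results


def morans_i(
    residuals: Sequence[float],
    coordinates: np.ndarray,
    permutations: int = 999,
    seed: int | None = 0,
    method: str = "permutation",
) -> MoransIResult:
    """Moran's I of residuals with inverse squared-distance weights.

    I = (n/S0) * sum_ij w_ij (e_i - m)(e_j - m) / sum_i (e_i - m)^2 with
    w_ij = 1/d_ij^2, w_ii = 0.  The expectation under no autocorrelation
    is -1/(n-1).  Significance is two-sided, by seeded permutation of the
    residuals over locations (default) or by the normal approximation
    under the normality assumption.
    """
    e = np.asarray(residuals, dtype=float)
    xy = np.asarray(coordinates, dtype=float)
    n = len(e)
    if n < 5:
        raise ValueError("Moran's I needs at least 5 observations")
    if xy.shape != (n, 2):
        raise ValueError("coordinates must be an (n, 2) array")
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    off = ~np.eye(n, dtype=bool)
    if np.any(d2[off] == 0.0):
        raise ValueError("duplicate coordinates give infinite weights")
    w = np.zeros_like(d2)
    w[off] = 1.0 / d2[off]
    s0 = w.sum()
    expected = -1.0 / (n - 1)

    def _moran(vec: np.ndarray) -> float:
        z = vec - vec.mean()
        denom = float(z @ z)
        return float(n / s0 * (z @ w @ z) / denom)

    i_obs = _moran(e)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        dev = abs(i_obs - expected)
        count = 0
        for _ in range(permutations):
            i_p = _moran(rng.permutation(e))
            if abs(i_p - expected) >= dev - 1e-15:
                count += 1
        p = (count + 1) / (permutations + 1)
    elif method == "normal":
        s1 = 0.5 * ((w + w.T) ** 2).sum()
        s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
        var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - expected**2
        z = (i_obs - expected) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return MoransIResult(i=i_obs, expected=expected, p_value=p, method=method)


def area_dependence_test(
    residuals: Sequence[float], area_labels: Sequence[str]
) -> AreaTestResult:
    """One-way ANOVA F-test of residuals on the study-area factor.

    Areas with a single site cannot contribute a within-group variance
    and are flagged and excluded.
    """
    e = np.asarray(residuals, dtype=float)
    areas = np.asarray(area_labels, dtype=object)
    groups, excluded = [], []
    for label in sorted(set(areas)):
        vals = e[areas == label]
        if len(vals) < 2:
            excluded.append(label)
        else:
            groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least two areas with >= 2 sites each")
    f, p = stats.f_oneway(*groups)
    return AreaTestResult(f=float(f), p_value=float(p), excluded_areas=excluded)


def validate_model(
    model: LURModel,
    y: Sequence[float],
    table: PredictorTable,
    coordinates: np.ndarray | None = None,
    area_labels: Sequence[str] | None = None,
    seed: int = 0,
) -> ValidationReport:
    """Run the full validation battery applicable to the inputs supplied."""
    variables = model.predictor_names
    report = ValidationReport()
    report.loocv = loocv(variables, y, table)
    fit = fit_ols(np.asarray(y, dtype=float), table.frame[variables])
    if area_labels is None and table.areas is not None:
        area_labels = table.areas.to_numpy()
    if area_labels is not None and len(set(area_labels)) >= 2:
        has_dummy = any(table.is_area_dummy(v) for v in variables)
        if not has_dummy:
            try:
                report.loaocv = loaocv(variables, y, table, area_labels)
            except ValueError:
                report.loaocv = None
        try:
            report.area_test = area_dependence_test(fit.residuals, area_labels)
        except ValueError:
            report.area_test = None
    if coordinates is not None:
        report.morans_i = morans_i(fit.residuals, coordinates, seed=seed)
    return report
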