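"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written with different machinery than
the package (normal equations + scipy.stats instead of statsmodels,
grid counting instead of polygon clipping, double loops instead of
vectorisation) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_normal_equations(y: np.ndarray, X: np.ndarray):
    """OLS via the normal equations: (beta, p_values, r2, adj_r2).

    beta[0] is the intercept; p-values are two-sided t-tests.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)
    D = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    k = D.shape[1] - 1
    XtX = D.T @ D
    beta = np.linalg.solve(XtX, D.T @ y)
    resid = y - D @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    s2 = sse / (n - k - 1)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(XtX)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), n - k - 1)
    return beta, p, r2, adj


def forward_selection_path(
    y: np.ndarray,
    columns: dict[str, np.ndarray],
    directions: dict[str, str],
    forced: list[str] | None = None,
    max_p: float = 0.10,
    min_gain: float = 0.01,
) -> list[str]:
    """Step-by-step enumeration of the supervised greedy admission path.

    Mirrors the admission rules (direction, p < max_p, adjusted-R2 gain
    >= min_gain from the second admission, no sign flip of earlier
    directional terms, largest gain wins, name tie-break) but with the
    normal-equation fit above.
    """
    forced = list(forced or [])
    current = list(forced)
    names = sorted(columns)

    def fit(cols):
        X = np.column_stack([columns[c] for c in cols]) if cols else np.empty((len(y), 0))
        return ols_normal_equations(y, X)

    _, _, _, cur_adj = fit(current)
    n_admitted = 0
    while True:
        qualifying = []
        for cand in names:
            if cand in current:
                continue
            cols = current + [cand]
            try:
                beta, p, _, adj = fit(cols)
            except np.linalg.LinAlgError:
                continue
            coefs = dict(zip(["const"] + cols, beta))
            pvals = dict(zip(["const"] + cols, p))

            def ok(name):
                d = directions.get(name, "either")
                if d == "either":
                    return True
                return coefs[name] > 0 if d == "positive" else coefs[name] < 0

            if not ok(cand):
                continue
            if pvals[cand] >= max_p:
                continue
            gain = adj - cur_adj
            if n_admitted >= 1 and gain < min_gain:
                continue
            if any(not ok(prev) for prev in current):
                continue
            qualifying.append((gain, cand))
        if not qualifying:
            return current
        qualifying.sort(key=lambda t: (-t[0], t[1]))
        chosen = qualifying[0][1]
        current.append(chosen)
        _, _, _, cur_adj = fit(current)
        n_admitted += 1


def grid_count_area(polygons, cx: float, cy: float, radius: float, step: float = 1.0) -> float:
    """Monte-Carlo-free rasterisation: count step x step cells whose centre
    is inside the circle AND inside any polygon; area = count * step^2."""
    import shapely
    from shapely.geometry import Point

    xs = np.arange(cx - radius, cx + radius + step, step) + step / 2.0
    ys = np.arange(cy - radius, cy + radius + step, step) + step / 2.0
    X, Y = np.meshgrid(xs, ys)
    inside_circle = (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2
    pts = shapely.points(X[inside_circle], Y[inside_circle])
    total = 0
    for poly in polygons:
        total += int(shapely.contains(poly, pts).sum())
    return total * step * step


def sampled_line_length(lines, cx: float, cy: float, radius: float, step: float = 0.1):
    """Per-line clipped length by dense point sampling along the line."""
    out = []
    for line in lines:
        L = line.length
        n = max(int(np.ceil(L / step)), 1)
        coords = np.asarray(line.coords)
        if len(coords) == 2:  # straight segment: vectorised midpoints
            f = (np.arange(n) + 0.5) / n
            xs = coords[0, 0] + f * (coords[1, 0] - coords[0, 0])
            ys = coords[0, 1] + f * (coords[1, 1] - coords[0, 1])
        else:
            ts = (np.arange(n) + 0.5) * (L / n)
            pts = [line.interpolate(t) for t in ts]
            xs = np.array([p.x for p in pts])
            ys = np.array([p.y for p in pts])
        inside = int(((xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2).sum())
        out.append(inside * (L / n))
    return np.array(out)


def morans_i_double_loop(e: np.ndarray, xy: np.ndarray) -> float:
    e = np.asarray(e, float)
    n = len(e)
    z = e - e.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d2 = (xy[i, 0] - xy[j, 0]) ** 2 + (xy[i, 1] - xy[j, 1]) ** 2
            w = 1.0 / d2
            num += w * z[i] * z[j]
            s0 += w
    return n / s0 * num / float(z @ z)


def cooks_distance_refit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Cook's distance from explicit delete-one refits:
    D_i = (b - b_(i))' X'X (b - b_(i)) / (p s^2)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    p = D.shape[1]
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    resid = y - D @ beta
    s2 = float(resid @ resid) / (n - p)
    out = np.empty(n)
    XtX = D.T @ D
    for i in range(n):
        keep = np.arange(n) != i
        bi = np.linalg.solve(D[keep].T @ D[keep], D[keep].T @ y[keep])
        diff = beta - bi
        out[i] = float(diff @ XtX @ diff) / (p * s2)
    return out
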