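"""Supervised forward selection, diagnostics and model evaluation."""

import numpy as np
import pandas as pd
import pytest

from lurkit.gis import PredictorSpec, PredictorTable
from lurkit.model import (
    LURModel,
    ModelTerm,
    RankDeficientError,
    cooks_distance,
    evaluate_model,
    finalize_model,
    fit_ols,
    forward_select,
    vif,
)
from lurkit.published import available_models, load_published_model
from lurkit.screening import screen
from lurkit.synthetic import generate_predictor_table

from _oracles import cooks_distance_refit, forward_selection_path, ols_normal_equations


def table_from(frame: pd.DataFrame, directions=None) -> PredictorTable:
    specs = {
        c: PredictorSpec(c, "synthetic", "point_value",
                         direction=(directions or {}).get(c, "either"))
        for c in frame.columns
    }
    return PredictorTable(frame, specs)


def random_table(rng, n, names, directions=None):
    frame = pd.DataFrame(
        rng.standard_normal((n, len(names))), columns=names,
        index=pd.Index([f"s{i}" for i in range(n)], name="site_id"),
    )
    return table_from(frame, directions)


class TestFitOls:
    def test_exact_linear_r2_one(self):
        x = np.linspace(0, 10, 20)
        X = pd.DataFrame({"x": x})
        fit = fit_ols(3.0 + 2.0 * x, X)
        assert fit.r2 == pytest.approx(1.0)
        assert np.allclose(fit.residuals, 0, atol=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        y = 1.0 + 0.5 * X["a"] - 2.0 * X["b"] + rng.normal(0, 1, 30)
        fit = fit_ols(y, X)
        beta, p, r2, adj = ols_normal_equations(y.to_numpy(), X.to_numpy())
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)
        assert np.allclose(fit.pvalues.to_numpy(), p, atol=1e-8)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(adj, abs=1e-10)
        # RMSE default uses the n denominator
        assert fit.rmse == pytest.approx(np.sqrt((fit.residuals**2).mean()))

    def test_noise_against_constant_free_candidate(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(50):
            y = rng.normal(0, 1, 40)
            X = pd.DataFrame({"x": rng.standard_normal(40)})
            pvals.append(fit_ols(y, X).pvalues["x"])
        # most p-values far above 0.10 under the null; R2 near 0
        assert np.mean(np.array(pvals) > 0.10) > 0.7

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(20)})
        with pytest.raises(RankDeficientError) as exc:
            fit_ols(rng.normal(size=20), X)
        assert set(exc.value.columns) & {"a", "b"}

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0, 4.0, 5.0]})
        with pytest.raises(ValueError):
            fit_ols(np.ones(5), X)


class TestDiagnostics:
    def test_vif_orthogonal_columns(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        assert vif(X, "a") == pytest.approx(1.0)
        assert vif(X, "b") == pytest.approx(1.0)

    def test_vif_duplicate_infinite(self):
        x = np.random.default_rng(0).standard_normal(15)
        X = pd.DataFrame({"a": x, "b": x})
        assert vif(X, "a") == np.inf

    def test_cooks_matches_delete_one_refit(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((25, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(0, 1, 25)
        fit = fit_ols(y, X)
        want = cooks_distance_refit(y, X.to_numpy())
        assert np.allclose(cooks_distance(fit), want, atol=1e-8)


class TestForwardSelect:
    def test_recovers_single_true_predictor(self):
        hits, coefs = 0, []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            names = ["x1"] + [f"n{i}" for i in range(9)]
            t = random_table(rng, 40, names, directions={"x1": "positive"})
            y = 2.0 * t.frame["x1"].to_numpy() + rng.normal(0, 0.5, 40)
            m = forward_select(y, t, screen(t))
            if m.predictor_names == ["x1"]:
                hits += 1
                coefs.append(m.terms[0].coef)
        assert hits >= 45  # >= 90% exact support recovery
        assert np.mean(coefs) == pytest.approx(2.0, abs=0.1)

    def test_wrong_sign_never_admitted(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, 40, ["x1", "z"], directions={"x1": "positive"})
        y = -3.0 * t.frame["x1"].to_numpy() + rng.normal(0, 0.3, 40)
        m = forward_select(y, t, screen(t))
        assert "x1" not in m.predictor_names

    def test_small_gain_rejected(self):
        # construct x2 whose admission improves adj R2 by ~0.005
        rng = np.random.default_rng(11)
        n = 200
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        for scale in np.linspace(0.02, 0.4, 60):
            y = x1 + scale * x2 + rng.normal(0, 1.0, n)
            f1 = fit_ols(y, pd.DataFrame({"x1": x1}))
            f2 = fit_ols(y, pd.DataFrame({"x1": x1, "x2": x2}))
            gain = f2.adj_r2 - f1.adj_r2
            if 0.003 < gain < 0.008 and f2.pvalues["x2"] < 0.10:
                t = table_from(pd.DataFrame({"x1": x1, "x2": x2}),
                               {"x1": "positive", "x2": "positive"})
                m = forward_select(y, t, screen(t), finalize=False)
                assert m.predictor_names == ["x1"]
                return
        pytest.skip("no fixture with gain in (0.003, 0.008) found")  # pragma: no cover

    def test_intercept_only_when_nothing_admissible(self):
        rng = np.random.default_rng(13)
        t = random_table(rng, 30, ["a", "b"], directions={"a": "positive", "b": "positive"})
        y = rng.normal(10, 1, 30)  # pure noise
        m = forward_select(y, t, screen(t))
        if not m.terms:
            assert any("intercept-only" in f for f in m.flags) or m.terms == []

    def test_adj_r2_nondecreasing_along_path(self):
        rng = np.random.default_rng(17)
        names = [f"v{i}" for i in range(8)]
        t = random_table(rng, 45, names)
        y = (t.frame["v0"] + 0.8 * t.frame["v1"] + 0.6 * t.frame["v2"]).to_numpy() \
            + rng.normal(0, 1.0, 45)
        m = forward_select(y, t, screen(t), finalize=False)
        adj = []
        for i in range(1, len(m.admission_order) + 1):
            adj.append(fit_ols(y, t.frame[m.admission_order[:i]]).adj_r2)
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    @pytest.mark.parametrize("seed", range(20))
    def test_path_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(3, 9))
        n = int(rng.integers(25, 51))
        names = [f"c{i}" for i in range(k)]
        dirs = {nm: rng.choice(["positive", "negative", "either"]) for nm in names}
        t = random_table(rng, n, names, directions=dirs)
        true = rng.choice(names, size=min(3, k), replace=False)
        y = sum(
            (1.0 if dirs[nm] != "negative" else -1.0) * t.frame[nm].to_numpy()
            for nm in true
        ) + rng.normal(0, 1.0, n)
        m = forward_select(y, t, screen(t), finalize=False)
        want = forward_selection_path(
            y, {nm: t.frame[nm].to_numpy() for nm in names}, dirs
        )
        assert m.admission_order == want

    def test_forced_terms_kept_and_skip_gates(self):
        rng = np.random.default_rng(23)
        t = random_table(rng, 40, ["disp", "x"], directions={"x": "positive"})
        y = 1.5 * t.frame["x"].to_numpy() + rng.normal(0, 0.5, 40)
        m = forward_select(y, t, screen(t, exempt=["disp"]), forced=["disp"])
        assert "disp" in m.predictor_names  # irrelevant but forced -> retained
        assert "disp" in m.forced


class TestFinalize:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(31)
        x = rng.standard_normal(30)
        frame = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(30)},
                             index=pd.Index([f"s{i}" for i in range(30)], name="site_id"))
        t = table_from(frame)
        y = x + rng.normal(0, 0.5, 30)
        model = LURModel("NO2", 0.0, [ModelTerm("a", 1.0), ModelTerm("b", 1.0)],
                         admission_order=["a", "b"])
        out = finalize_model(model, y, t)
        assert out.predictor_names == ["a"]
        assert any("collinear" in f or "VIF" in f for f in out.flags)

    def test_high_p_terms_removed_iteratively(self):
        rng = np.random.default_rng(37)
        frame = pd.DataFrame(rng.standard_normal((40, 3)), columns=["x", "n1", "n2"],
                             index=pd.Index([f"s{i}" for i in range(40)], name="site_id"))
        t = table_from(frame)
        y = 2.0 * frame["x"].to_numpy() + rng.normal(0, 0.5, 40)
        model = LURModel("NO2", 0.0,
                         [ModelTerm("x", 2.0), ModelTerm("n1", 0.0), ModelTerm("n2", 0.0)],
                         admission_order=["x", "n1", "n2"])
        out = finalize_model(model, y, t)
        assert out.predictor_names == ["x"]

    def test_gross_outlier_triggers_cooks_removal(self):
        rng = np.random.default_rng(41)
        n = 30
        x1 = rng.standard_normal(n)
        x2 = np.zeros(n)
        x2[0] = 30.0  # single leverage point drives the x2 coefficient
        frame = pd.DataFrame({"x1": x1, "x2": x2},
                             index=pd.Index([f"s{i}" for i in range(n)], name="site_id"))
        t = table_from(frame)
        y = x1 + 0.5 * x2 + rng.normal(0, 0.3, n)
        fit = fit_ols(y, frame)
        assert cooks_distance(fit).max() >= 1.0  # fixture is as intended
        model = LURModel("NO2", 0.0, [ModelTerm("x1", 1.0), ModelTerm("x2", 0.5)],
                         admission_order=["x1", "x2"])
        out = finalize_model(model, y, t)
        assert "x2" not in out.predictor_names
        assert any("Cook" in f for f in out.flags)

    def test_clean_model_unchanged(self):
        rng = np.random.default_rng(43)
        frame = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"],
                             index=pd.Index([f"s{i}" for i in range(40)], name="site_id"))
        t = table_from(frame)
        y = (frame["a"] + frame["b"]).to_numpy() + rng.normal(0, 0.3, 40)
        model = LURModel("NO2", 0.0, [ModelTerm("a", 1.0), ModelTerm("b", 1.0)],
                         admission_order=["a", "b"])
        out = finalize_model(model, y, t)
        assert out.predictor_names == ["a", "b"]
        assert not [f for f in out.flags if "removed" in f]


class TestEvaluatePublishedModels:
    def test_alpine_intercept(self):
        m = load_published_model("no2_alpine")
        assert evaluate_model(m, {t.name: 0.0 for t in m.terms}) == pytest.approx(7.97)

    def test_payerne_intercept(self):
        m = load_published_model("no2_payerne")
        assert evaluate_model(m, {t.name: 0.0 for t in m.terms}) == pytest.approx(44.0)

    def test_absorbance_at_unit_altitude(self):
        m = load_published_model("pm25_absorbance")
        vals = {t.name: 0.0 for t in m.terms}
        vals["LOG_ALT"] = np.log(1.0)  # ALT = 1 m
        assert evaluate_model(m, vals) == pytest.approx(4.75)

    def test_linear_evaluation_and_missing_predictor(self):
        m = load_published_model("no2_non_alpine")
        vals = {"NO2_2010": 20.0, "MAJROADLENGTH_25": 10.0, "HDRES_250": 1000.0}
        want = -0.83 + 0.855 * 20 + 0.201 * 10 + 0.0000266 * 1000
        assert evaluate_model(m, vals) == pytest.approx(want)
        with pytest.raises(KeyError, match="NO2_2010"):
            evaluate_model(m, {"MAJROADLENGTH_25": 0.0, "HDRES_250": 0.0})

    def test_all_published_models_wellformed(self):
        for key in available_models():
            m = load_published_model(key)
            assert m.stats["adj_r2"] <= m.stats["r2"] + 1e-9
            for t in m.terms:
                if t.direction == "positive":
                    assert t.coef > 0, (key, t.name)
                elif t.direction == "negative":
                    assert t.coef < 0, (key, t.name)

    def test_json_roundtrip(self, tmp_path):
        m = load_published_model("pnc")
        p = tmp_path / "m.json"
        m.to_json(p)
        m2 = LURModel.from_json(p)
        assert m2.to_dict() == m.to_dict()
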