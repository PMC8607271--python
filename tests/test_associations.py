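"""Cohort association models, VIF diagnostics, dichotomised curve summaries."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor \
    as sm_vif
import statsmodels.api as sm

from bbbleak import (CohortSpec, dichotomised_curve_summary,
                     fit_association_model, generate_cohort,
                     variance_inflation_factors)
from bbbleak.simulate import PREDICTORS


def _minimal_table(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "age": rng.normal(66, 12, n),
        "stroke_subtype": rng.integers(0, 2, n),
        "map": rng.normal(140, 20, n),
        "hypertension": rng.integers(0, 2, n),
        "pulse_pressure": rng.normal(60, 18, n),
        "smoking": rng.integers(0, 2, n),
        "fazekas_total": rng.integers(0, 7, n),
        "wmh_icv_pct": rng.lognormal(0, 1, n),
    })


class TestFitAssociationModel:
    def test_exact_linear_outcome(self):
        df = _minimal_table()
        df["ps_wm"] = 2.0 + 1.0 * df["age"]
        m = fit_association_model(df, "ps_wm", "fazekas")
        assert m.coef("age") == pytest.approx(1.0, abs=1e-10)
        assert m.intercept == pytest.approx(2.0, abs=1e-8)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)
        for p in PREDICTORS:
            if p != "age":
                assert m.coef(p) == pytest.approx(0.0, abs=1e-10)

    def test_null_model_estimates_near_zero(self):
        rng = np.random.default_rng(77)
        df = _minimal_table(n=10_000, seed=2)
        df["vp_gm"] = rng.normal(0, 1, len(df))
        m = fit_association_model(df, "vp_gm", "fazekas")
        for p in PREDICTORS:
            lo, hi = m.ci(p)
            se = (hi - lo) / 2 / 1.96
            assert abs(m.coef(p)) < 3 * se + 1e-12

    def test_matches_normal_equations_small_design(self):
        df = _minimal_table(n=20, seed=4)
        rng = np.random.default_rng(4)
        df["ps_gm"] = rng.normal(3, 1, len(df))
        cols = list(PREDICTORS[:-1]) + ["fazekas_total"]
        x = np.column_stack([np.ones(len(df)),
                             df[cols].to_numpy(dtype=float)])
        beta = np.linalg.solve(x.T @ x, x.T @ df["ps_gm"].to_numpy())
        m = fit_association_model(df, "ps_gm", "fazekas")
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        for i, p in enumerate(cols):
            assert m.coef(p) == pytest.approx(beta[i + 1], abs=1e-10)

    def test_burden_metric_switches_predictor(self):
        df = _minimal_table()
        df["ps_wm"] = 1.0 + 0.5 * df["wmh_icv_pct"]
        m = fit_association_model(df, "ps_wm", "wmh_volume")
        assert "wmh_icv_pct" in m.table.index
        assert "fazekas_total" not in m.table.index
        assert m.coef("wmh_icv_pct") == pytest.approx(0.5, abs=1e-10)

    def test_missing_rows_dropped_with_count(self):
        df = _minimal_table()
        df["ps_wm"] = 1.0
        df.loc[:4, "ps_wm"] = np.nan
        df["ps_wm"] += 0.01 * df["age"]
        m = fit_association_model(df, "ps_wm", "fazekas")
        assert m.n_dropped == 5
        assert m.n_used == len(df) - 5

    def test_too_few_rows_and_collinearity_rejected(self):
        df = _minimal_table(n=10)
        df["ps_wm"] = 1.0 + df["age"]
        with pytest.raises(ValueError, match="15"):
            fit_association_model(df, "ps_wm", "fazekas")
        df2 = _minimal_table(n=50, seed=1)
        df2["map"] = df2["pulse_pressure"] * 2  # perfectly collinear pair
        df2["ps_wm"] = 1.0 + df2["age"]
        with pytest.raises(ValueError, match="collinear"):
            fit_association_model(df2, "ps_wm", "fazekas")

    def test_coefficient_recovery_from_generator(self):
        # one seeded cohort at study size: truth inside the fitted 95% CI
        spec = CohortSpec(seed=17)
        df = generate_cohort(spec)
        m = fit_association_model(df, "ps_wm", "fazekas")
        lo, hi = m.ci("age")
        assert lo <= spec.coefficients[("ps", "WM")]["age"] <= hi
        assert (m.table["vif"] < 2).all()


class TestVif:
    def test_orthogonal_design_gives_unit_vifs(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(40, 4)))
        # centre each column so the intercept-including auxiliaries see
        # exactly orthogonal regressors
        q -= q.mean(axis=0)
        q, _ = np.linalg.qr(q)
        vifs = variance_inflation_factors(q)
        assert np.allclose(vifs, 1.0, atol=1e-8)

    def test_duplicated_predictor_flagged_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 2))
        x = np.column_stack([x, x[:, 0]])
        vifs = variance_inflation_factors(x)
        assert np.isinf(vifs[0]) and np.isinf(vifs[2])

    def test_two_predictor_closed_form(self):
        rng = np.random.default_rng(5)
        n = 20_000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        c = rng.normal(size=n)
        x = np.column_stack([a, b, c])
        r = np.corrcoef(a, b)[0, 1]
        vifs = variance_inflation_factors(x)
        assert vifs[0] == pytest.approx(1 / (1 - r ** 2), rel=1e-3)
        assert vifs[1] == pytest.approx(1 / (1 - r ** 2), rel=1e-3)
        assert vifs[2] == pytest.approx(1.0, abs=0.01)

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(100, 5))
        x[:, 1] += 0.7 * x[:, 0]
        design = sm.add_constant(x)
        expected = [sm_vif(design, i + 1) for i in range(5)]
        assert np.allclose(variance_inflation_factors(x), expected,
                           rtol=1e-10)


class TestDichotomisedCurves:
    def _table(self, ages, fazekas):
        return pd.DataFrame({"age": ages, "fazekas_total": fazekas})

    def test_identical_curves_have_zero_spread(self):
        curves = np.tile(np.linspace(0, 1, 8), (4, 1))
        table = self._table([50, 55, 70, 80], [1, 2, 5, 6])
        out = dichotomised_curve_summary(curves, table, "median_fazekas")
        for grp in out.values():
            assert np.allclose(grp["sd"], 0)
            assert np.allclose(grp["sem"], 0)
            assert np.allclose(grp["mean"], np.linspace(0, 1, 8))

    def test_matches_two_pass_variance_oracle(self):
        rng = np.random.default_rng(3)
        curves = rng.random((9, 6))
        table = self._table(rng.normal(66, 10, 9), rng.integers(0, 7, 9))
        out = dichotomised_curve_summary(curves, table, "median_age")
        median = np.median(table["age"])
        sel = table["age"].to_numpy() > median
        for label, s in (("low", ~sel), ("high", sel)):
            grp = curves[s]
            n = s.sum()
            mean = grp.sum(axis=0) / n
            var = ((grp - mean) ** 2).sum(axis=0) / (n - 1)
            assert np.allclose(out[label]["mean"], mean)
            assert np.allclose(out[label]["sd"], np.sqrt(var))
            assert np.allclose(out[label]["sem"], np.sqrt(var / n))
            assert out[label]["n"] == n

    def test_fazekas_split_boundary(self):
        curves = np.ones((2, 4))
        table = self._table([60, 70], [3, 4])
        with pytest.raises(ValueError, match="< 2"):
            dichotomised_curve_summary(curves, table, "median_fazekas")

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            dichotomised_curve_summary(np.ones((4, 3)),
                                       self._table([1, 2, 3, 4], [0, 1, 5, 6]),
                                       "by_smoking")
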