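"""Cohort-level statistics: covariate-adjusted regression of PS and v_p.

Each kinetic outcome (tissue class x parameter) is regressed, with
intercept, on seven predictors: age, stroke subtype (cortical 0 / lacunar
1), mean arterial pressure, hypertension, pulse pressure, smoking, and one
white-matter burden metric — either the total Fazekas score (0-6) or WMH
volume normalised to intracranial volume. Collinearity is checked with
variance inflation factors; residuals are summarised with Shapiro-Wilk and
Breusch-Pagan statistics rather than visual plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "BASE_PREDICTORS",
    "BURDEN_COLUMNS",
    "ModelResult",
    "fit_association_model",
    "variance_inflation_factors",
    "dichotomised_curve_summary",
]

BASE_PREDICTORS = ("age", "stroke_subtype", "map", "hypertension",
                   "pulse_pressure", "smoking")
BURDEN_COLUMNS = {"fazekas": "fazekas_total", "wmh_volume": "wmh_icv_pct"}


@dataclass
class ModelResult:
    """One fitted association model (outcome x burden metric).

    ``table`` has one row per predictor: coefficient B, 95% CI bounds,
    p-value and VIF. Residual diagnostics: Shapiro-Wilk (normality) and
    Breusch-Pagan (heteroscedasticity) statistic/p pairs.
    """

    outcome: str
    burden_metric: str
    table: pd.DataFrame
    intercept: float
    n_used: int
    n_dropped: int
    r_squared: float
    shapiro: tuple[float, float]
    breusch_pagan: tuple[float, float]

    def coef(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "B"])

    def ci(self, predictor: str) -> tuple[float, float]:
        row = self.table.loc[predictor]
        return (float(row["ci_low"]), float(row["ci_high"]))


def variance_inflation_factors(design) -> np.ndarray:
    """VIF_j = 1 / (1 - R2_j) from regressing predictor j on the others.

    ``design`` is a 2D array or DataFrame of predictor columns (no
    constant); the auxiliary regressions include an intercept. Perfectly
    collinear predictors are flagged as ``inf``.
    """
    x = np.asarray(design, dtype=float)
    if x.ndim != 2:
        raise ValueError("design must be 2D (observations x predictors)")
    n, k = x.shape
    vifs = np.ones(k)
    if k == 1:
        return vifs
    for j in range(k):
        y = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError(f"constant predictor at column {j}")
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        vifs[j] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def fit_association_model(table: pd.DataFrame, outcome: str,
                          burden_metric: str = "fazekas",
                          alpha: float = 0.05) -> ModelResult:
    """OLS of one kinetic outcome on the seven study covariates.

    Missing rows are dropped (complete-case) with the count recorded.
    Requires >= 15 complete rows and a full-rank design; a rank-deficient
    design raises naming the collinear predictors.
    """
    if burden_metric not in BURDEN_COLUMNS:
        raise ValueError(f"burden_metric must be one of {set(BURDEN_COLUMNS)}")
    predictors = list(BASE_PREDICTORS) + [BURDEN_COLUMNS[burden_metric]]
    cols = predictors + [outcome]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"cohort table lacks columns {missing}")
    data = table[cols].dropna()
    n_dropped = len(table) - len(data)
    if len(data) < 15:
        raise ValueError(f"need >= 15 complete rows, got {len(data)}")
    x = data[predictors].to_numpy(dtype=float)
    if np.any(x.std(axis=0) == 0):
        const = [p for p, s in zip(predictors, x.std(axis=0)) if s == 0]
        raise ValueError(f"constant predictor(s): {const}")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        vifs = variance_inflation_factors(x)
        bad = [p for p, v in zip(predictors, vifs) if not np.isfinite(v)]
        raise ValueError(f"rank-deficient design; collinear set: {bad}")
    y = data[outcome].to_numpy(dtype=float)
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha)
    vifs = variance_inflation_factors(x)
    out = pd.DataFrame(
        {
            "B": res.params[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "p": res.pvalues[1:],
            "vif": vifs,
        },
        index=pd.Index(predictors, name="predictor"),
    )
    sw = sps.shapiro(res.resid)
    bp = het_breuschpagan(res.resid, design)
    return ModelResult(
        outcome=outcome,
        burden_metric=burden_metric,
        table=out,
        intercept=float(res.params[0]),
        n_used=len(data),
        n_dropped=n_dropped,
        r_squared=float(res.rsquared),
        shapiro=(float(sw.statistic), float(sw.pvalue)),
        breusch_pagan=(float(bp[0]), float(bp[1])),
    )


def dichotomised_curve_summary(curves: np.ndarray, table: pd.DataFrame,
                               grouping: str) -> dict[str, dict]:
    """Group-mean concentration curves with SD and SEM bands.

    ``curves`` is (n_patients, n_frames), row-aligned with ``table``.
    ``grouping`` is ``median_age`` (split at the realised cohort median,
    low = at or below) or ``median_fazekas`` (low = score <= 3, high >= 4).
    Returns {"low": {...}, "high": {...}} with per-frame ``mean``, ``sd``
    (ddof=1), ``sem`` = sd/sqrt(n) and ``n``. Each group needs >= 2
    patients.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] != len(table):
        raise ValueError("curves must be (n_patients, n_frames) aligned with table")
    if grouping == "median_age":
        split = float(table["age"].median())
        high = table["age"].to_numpy(dtype=float) > split
    elif grouping == "median_fazekas":
        high = table["fazekas_total"].to_numpy(dtype=float) >= 4
    else:
        raise ValueError("grouping must be 'median_age' or 'median_fazekas'")
    out = {}
    for label, sel in (("low", ~high), ("high", high)):
        n = int(sel.sum())
        if n < 2:
            raise ValueError(f"group '{label}' has {n} patients (< 2)")
        grp = curves[sel]
        sd = grp.std(axis=0, ddof=1)
        out[label] = {"mean": grp.mean(axis=0), "sd": sd,
                      "sem": sd / np.sqrt(n), "n": n}
    return out
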