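"""Patlak model: forward simulation and linear-regression estimation.

For low-leakage tissue at low temporal resolution the tissue concentration
follows

    C_t(t) = v_p * C_p(t) + PS * int_0^t C_p(tau) dtau

with fractional plasma volume v_p (dimensionless) and permeability-surface
area product PS (min^-1); under Patlak assumptions with early frames
excluded PS ~ Ktrans. Estimation is ordinary least squares of C_t on the
two regressors [C_p, int C_p] with no intercept. Reporting units follow the
field convention: PS in 1e-4 min^-1, v_p in 1e-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.integrate import cumulative_trapezoid

from .curves import ConcentrationCurve

__all__ = ["PatlakFit", "cumulative_integral", "patlak_forward", "patlak_fit"]

PS_REPORT_SCALE = 1e4   # min^-1  -> 1e-4 min^-1
VP_REPORT_SCALE = 1e2   # fraction -> 1e-2


@dataclass(frozen=True)
class PatlakFit:
    """Patlak estimates for one ROI, in natural and reporting units.

    Natural units are min^-1 (PS) and a plain fraction (v_p); the reporting
    properties apply the conventional 1e4 / 1e2 scalings. Confidence
    intervals are 95% Wald intervals from the OLS covariance. Negative
    estimates are reported as-is (flagged via the sign, not clamped) so that
    cohort statistics see the estimator's full distribution.
    """

    ps_per_min: float
    vp_frac: float
    ps_ci_per_min: tuple[float, float]
    vp_ci_frac: tuple[float, float]
    n_frames_used: int
    excluded_frames: tuple[int, ...]
    residual_rms_mM: float
    r_squared: float

    @property
    def ps_e4_per_min(self) -> float:
        return self.ps_per_min * PS_REPORT_SCALE

    @property
    def vp_e2(self) -> float:
        return self.vp_frac * VP_REPORT_SCALE

    @property
    def ps_ci_e4_per_min(self) -> tuple[float, float]:
        lo, hi = self.ps_ci_per_min
        return (lo * PS_REPORT_SCALE, hi * PS_REPORT_SCALE)

    @property
    def vp_ci_e2(self) -> tuple[float, float]:
        lo, hi = self.vp_ci_frac
        return (lo * VP_REPORT_SCALE, hi * VP_REPORT_SCALE)


def cumulative_integral(curve: ConcentrationCurve) -> np.ndarray:
    """Running trapezoidal integral int_0^t C dtau per frame, in mM*min.

    An implicit origin (t = 0, C = 0) is prepended when the first frame is
    post-injection: the true concentration is zero before the bolus, so the
    integral accumulates from injection time, not from the first sample.
    """
    if len(curve) < 2:
        raise ValueError("cumulative integral needs at least two frames")
    t_min = curve.times_s / 60.0
    c = curve.conc_mM
    if t_min[0] > 0:
        t_min = np.concatenate([[0.0], t_min])
        c = np.concatenate([[0.0], c])
        return cumulative_trapezoid(c, t_min)
    return cumulative_trapezoid(c, t_min, initial=0.0)


def patlak_forward(ps_per_min: float, vp_frac: float,
                   cp: ConcentrationCurve) -> ConcentrationCurve:
    """Tissue concentration implied by the Patlak model on the plasma grid.

    The running integral is the same trapezoidal quadrature the estimator
    uses, so fit-forward round trips are exact on noiseless data.
    """
    if cp.compartment != "plasma":
        raise ValueError("patlak_forward expects a plasma input curve")
    if not (0.0 <= vp_frac <= 1.0):
        raise ValueError("vp_frac must be a fraction in [0, 1]")
    ct = vp_frac * cp.conc_mM + ps_per_min * cumulative_integral(cp)
    return cp.with_conc(ct, "tissue", n_clamped=0)


def patlak_fit(ct: ConcentrationCurve, cp: ConcentrationCurve,
               exclude_n_early: int = 2, n_baseline: int = 1,
               alpha: float = 0.05) -> PatlakFit:
    """Estimate (PS, v_p) by no-intercept OLS of C_t on [C_p, int C_p].

    The pre-contrast baseline frame(s) and the first ``exclude_n_early``
    post-injection frames are excluded from the regression (bolus first-pass
    violates the Patlak mixing assumption); the running integral still uses
    the full history. Time is converted to minutes so PS is in min^-1.
    """
    if not np.array_equal(ct.times_s, cp.times_s):
        raise ValueError("tissue and plasma curves must share a time grid")
    n = len(ct)
    start = n_baseline + exclude_n_early
    if n - start < 3:
        raise ValueError(
            f"need >= 3 retained frames, got {n - start} "
            f"(n={n}, baseline={n_baseline}, excluded={exclude_n_early})"
        )
    design = np.column_stack([cp.conc_mM, cumulative_integral(cp)])
    keep = slice(start, None)
    x, y = design[keep], ct.conc_mM[keep]
    if np.linalg.matrix_rank(x) < 2:
        raise ValueError("rank-deficient Patlak design (degenerate C_p)")
    res = sm.OLS(y, x).fit()
    vp, ps = res.params
    ci = res.conf_int(alpha)
    return PatlakFit(
        ps_per_min=float(ps),
        vp_frac=float(vp),
        ps_ci_per_min=(float(ci[1, 0]), float(ci[1, 1])),
        vp_ci_frac=(float(ci[0, 0]), float(ci[0, 1])),
        n_frames_used=int(n - start),
        excluded_frames=tuple(range(start)),
        residual_rms_mM=float(np.sqrt(np.mean(res.resid ** 2))),
        r_squared=float(res.rsquared),
    )
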