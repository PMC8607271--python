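"""Patlak model: quadrature, forward model, and the linear estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import curve_fit

from bbbleak import (AIFParams, ConcentrationCurve, blood_to_plasma,
                     cumulative_integral, patlak_fit, patlak_forward,
                     population_aif, population_aif_integral)


def _plasma(conc, times):
    return ConcentrationCurve(np.asarray(times, float),
                              np.asarray(conc, float), "plasma")


def manual_patlak_forward(ps_per_min, vp, cp_conc, times_s):
    """Independent forward model: hand-rolled trapezoid with (0,0) origin."""
    t_min = np.asarray(times_s, float) / 60.0
    if t_min[0] > 0:
        t_min = np.concatenate([[0.0], t_min])
        c = np.concatenate([[0.0], cp_conc])
    else:
        c = np.asarray(cp_conc, float)
    integral = np.zeros(len(t_min))
    for i in range(1, len(t_min)):
        integral[i] = integral[i - 1] + 0.5 * (c[i] + c[i - 1]) * (
            t_min[i] - t_min[i - 1])
    if len(integral) > len(cp_conc):
        integral = integral[1:]
    return vp * np.asarray(cp_conc, float) + ps_per_min * integral


class TestCumulativeIntegral:
    def test_constant_concentration_rectangle(self):
        t = np.array([0.0, 60.0, 120.0, 180.0])
        out = cumulative_integral(_plasma([2.0] * 4, t))
        assert np.allclose(out, 2.0 * t / 60.0)

    def test_linear_ramp_exact(self):
        t = np.array([0.0, 30.0, 90.0, 240.0])
        a = 0.5  # mM per minute
        out = cumulative_integral(_plasma(a * t / 60.0, t))
        assert np.allclose(out, a * (t / 60.0) ** 2 / 2)

    def test_implicit_origin_when_first_frame_post_injection(self):
        out = cumulative_integral(_plasma([1.0, 1.0], [60.0, 120.0]))
        # triangle from (0,0) to (1 min, 1 mM), then rectangle
        assert np.allclose(out, [0.5, 1.5])

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            cumulative_integral(_plasma([1.0], [0.0]))

    def test_fine_grid_matches_closed_form(self, aif):
        t = np.linspace(0.0, 1440.0, 2000)
        cb = population_aif(aif, t)
        num = cumulative_integral(
            ConcentrationCurve(t, cb.conc_mM, "plasma")) * 60.0  # mM*s
        closed = population_aif_integral(aif, t)
        sel = closed > 0.01 * closed[-1]
        assert np.allclose(num[sel], closed[sel], rtol=1e-3)


class TestPatlakForward:
    def test_zero_ps_pure_intravascular(self, plasma_curve):
        out = patlak_forward(0.0, 0.02, plasma_curve)
        assert np.allclose(out.conc_mM, 0.02 * plasma_curve.conc_mM)
        assert out.compartment == "tissue"

    def test_zero_vp_constant_plasma_accumulates_linearly(self):
        t = np.arange(6) * 60.0
        cp = _plasma([3.0] * 6, t)
        out = patlak_forward(0.01, 0.0, cp)
        assert np.allclose(out.conc_mM, 0.01 * 3.0 * t / 60.0)

    def test_superposition(self, plasma_curve):
        a = patlak_forward(2e-4, 0.005, plasma_curve).conc_mM
        b = patlak_forward(3e-4, 0.010, plasma_curve).conc_mM
        ab = patlak_forward(5e-4, 0.015, plasma_curve).conc_mM
        assert np.allclose(ab, a + b, rtol=1e-12)


class TestPatlakFit:
    def test_recovers_study_deep_grey_matter_truth(self, plasma_curve):
        ct = patlak_forward(3.896e-4, 1.232e-2, plasma_curve)
        fit = patlak_fit(ct, plasma_curve, exclude_n_early=2)
        assert fit.ps_e4_per_min == pytest.approx(3.896, abs=1e-8)
        assert fit.vp_e2 == pytest.approx(1.232, abs=1e-8)
        assert fit.n_frames_used == 17
        assert fit.excluded_frames == (0, 1, 2)

    def test_pure_vp_tissue(self, plasma_curve):
        ct = plasma_curve.with_conc(0.01 * plasma_curve.conc_mM, "tissue")
        fit = patlak_fit(ct, plasma_curve)
        assert fit.vp_e2 == pytest.approx(1.0, abs=1e-9)
        assert fit.ps_e4_per_min == pytest.approx(0.0, abs=1e-8)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(ps=st.floats(0, 50e-4), vp=st.floats(0.001, 0.05),
           excl=st.integers(0, 16))
    def test_exact_recovery_any_early_exclusion(self, plasma_curve, ps, vp,
                                                excl):
        ct = patlak_forward(ps, vp, plasma_curve)
        fit = patlak_fit(ct, plasma_curve, exclude_n_early=excl)
        assert abs(fit.ps_per_min - ps) < 1e-8
        assert abs(fit.vp_frac - vp) < 1e-8

    def test_matches_nonlinear_least_squares_oracle(self, plasma_curve):
        rng = np.random.default_rng(42)
        t = plasma_curve.times_s
        cp = plasma_curve.conc_mM
        for _ in range(50):
            ps, vp = rng.uniform(0, 50e-4), rng.uniform(0.001, 0.05)
            ct_vals = manual_patlak_forward(ps, vp, cp, t)
            keep = slice(3, None)

            def model(_x, ps_, vp_):
                return manual_patlak_forward(ps_, vp_, cp, t)[keep]

            popt, _ = curve_fit(model, np.zeros(17), ct_vals[keep],
                                p0=[1e-4, 0.01])
            fit = patlak_fit(plasma_curve.with_conc(ct_vals, "tissue"),
                             plasma_curve)
            assert fit.ps_per_min == pytest.approx(popt[0], rel=1e-6)
            assert fit.vp_frac == pytest.approx(popt[1], rel=1e-6)

    def test_scale_equivariance_in_plasma(self, plasma_curve):
        ct = patlak_forward(4e-4, 0.012, plasma_curve)
        k = 2.5
        cp_scaled = plasma_curve.with_conc(k * plasma_curve.conc_mM)
        fit = patlak_fit(ct, cp_scaled)
        assert fit.ps_per_min == pytest.approx(4e-4 / k, rel=1e-9)
        assert fit.vp_frac == pytest.approx(0.012 / k, rel=1e-9)

    def test_unbiased_under_gaussian_noise(self, plasma_curve):
        rng = np.random.default_rng(7)
        ps, vp, sd = 4e-4, 0.01, 0.002
        clean = patlak_forward(ps, vp, plasma_curve).conc_mM
        est = np.empty((1000, 2))
        for i in range(1000):
            noisy = plasma_curve.with_conc(
                clean + rng.normal(0, sd, clean.size), "tissue")
            f = patlak_fit(noisy, plasma_curve)
            est[i] = f.ps_per_min, f.vp_frac
        for j, truth in enumerate((ps, vp)):
            se = est[:, j].std(ddof=1) / np.sqrt(len(est))
            assert abs(est[:, j].mean() - truth) < 3 * se

    def test_matches_normal_equations_closed_form(self):
        t = np.array([0.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0, 420.0])
        cp = _plasma([0.0, 2.0, 1.5, 1.2, 1.0, 0.9, 0.8, 0.7], t)
        rng = np.random.default_rng(3)
        ct_vals = patlak_forward(5e-4, 0.02, cp).conc_mM + rng.normal(
            0, 1e-3, 8)
        x = np.column_stack([cp.conc_mM, cumulative_integral(cp)])[3:]
        y = ct_vals[3:]
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        fit = patlak_fit(cp.with_conc(ct_vals, "tissue"), cp)
        assert fit.vp_frac == pytest.approx(beta[0], abs=1e-10)
        assert fit.ps_per_min == pytest.approx(beta[1], abs=1e-10)

    def test_ci_contains_point_estimate_and_negative_kept(self, plasma_curve):
        rng = np.random.default_rng(11)
        clean = patlak_forward(1e-5, 0.001, plasma_curve).conc_mM
        noisy = plasma_curve.with_conc(clean + rng.normal(0, 0.01, clean.size),
                                       "tissue")
        fit = patlak_fit(noisy, plasma_curve)
        assert fit.ps_ci_per_min[0] <= fit.ps_per_min <= fit.ps_ci_per_min[1]
        assert fit.vp_ci_frac[0] <= fit.vp_frac <= fit.vp_ci_frac[1]

    def test_degenerate_inputs_rejected(self, plasma_curve):
        zeros = plasma_curve.with_conc(np.zeros(len(plasma_curve)))
        ct = plasma_curve.with_conc(np.zeros(len(plasma_curve)), "tissue")
        with pytest.raises(ValueError, match="rank"):
            patlak_fit(ct, zeros)
        short = ConcentrationCurve([0.0, 60.0, 120.0, 180.0],
                                   [0, 1, 1, 1], "plasma")
        with pytest.raises(ValueError, match="retained"):
            patlak_fit(short.with_conc([0, 0.1, 0.1, 0.1], "tissue"), short)
        with pytest.raises(ValueError, match="grid"):
            patlak_fit(ConcentrationCurve([0.0, 30.0, 60.0, 90.0, 120.0],
                                          np.ones(5), "tissue"),
                       plasma_curve)
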