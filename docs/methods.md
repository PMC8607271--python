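# Methods

## Signal model and T1 estimation

All signal physics assumes the ideal steady-state spoiled gradient-echo
(SPGR) equation

    S = M0 · sin α · (1 − E1) / (1 − cos α · E1),   E1 = exp(−TR/T1),

with TE-dependent T2\* decay absorbed into the scale `M0` (TE is constant
across the series, so it cancels everywhere the model is used). B1
inhomogeneity and incomplete spoiling are not modelled. Angles are accepted
in degrees at every interface and converted once internally; relaxation
times are in milliseconds.

Pre-contrast T1 (`T10`) uses the closed-form two-point variable flip angle
solution of the linearised relation `S/sin α = E1·(S/tan α) + M0(1 − E1)`
through the low/high flip-angle pair (defaults 2°/12°, TR 8.24 ms). It
round-trips the forward model exactly on noiseless input. Noise can push the
implied `E1` outside (0, 1); such estimates are clamped to T1 ∈ [1 ms, 20 s]
and flagged rather than erroring, so QC can count them. Two inputs that
collapse to the same point on the linearised axis are a genuine degeneracy
and raise.

T1 estimation is performed at the analysis unit of the pipeline — the
ROI-median low/high-angle signals per tissue mask — rather than by averaging
a voxelwise map, matching the median-curve analysis; a voxelwise map
(`vfa_t1_map`) is available for map outputs and the `t1map` CLI command.

## Signal to concentration

Concentration conversion inverts the SPGR equation through the scanner-gain
free ratio `S_i/S_0` at the dynamic flip angle: given `T10`, the ratio
determines the post-contrast `E1(t)` algebraically,

    E1(t) = (1 − A) / (1 − A·cos α),   A = (S_i/S_0) · (1 − E10)/(1 − cos α·E10),

then `C_i = (1/r1)(1/T1(t) − 1/T10)` in mM. This ratio form avoids any
dependence on the fitted `M0` or scanner gain. The agent relaxivity `r1` is
not uniquely fixed by the acquisition description; the default is
4.5 s⁻¹mM⁻¹ (a standard value for a macrocyclic gadolinium agent at 1.5 T)
and is exposed in `AcquisitionParams`. Because the validation strategy is
built on forward/backward round trips, its exact value does not affect any
correctness property.

Frames whose inversion is non-physical (implied T1 ≤ 0 or T1 > T10, i.e.
negative concentration from noise) are clamped to 0 mM and counted in a
per-curve QC counter instead of being dropped, preserving the frame grid for
the regression. This choice trades a small positive bias at very low SNR for
robustness; at ROI-median SNR the clamp rarely fires.

## Input function

The measured route takes the median signal across vein-mask voxels per frame
(median chosen for consistency with the tissue ROIs and robustness to
partial-volume voxels), converts with the blood T1 estimated from the same
mask (a fixed literature blood T1 can be supplied instead), and applies the
haematocrit correction `C_p = C_b/(1 − Hct)`. Haematocrit defaults to 0.45
only when a patient record lacks a value. No partial-volume, inflow,
dispersion or delay corrections are applied.

For synthesis, the population input function is a gamma-variate bolus,
normalised so its maximum equals `peak_mM` at `τ = r·t_d`, plus two
exponential washout terms ramped in smoothly over ~1 min so the curve is
continuous and zero at bolus arrival:

    C_b(τ) = peak·(τ/(r·t_d))^r e^{r−τ/t_d} + (1 − e^{−τ/ramp}) Σ_j w_j e^{−k_j τ}.

Defaults (arrival 40 s, peak 2 mM whole blood, r = 3, t_d = 25 s, washout
0.4 mM at 1/600 s⁻¹ and 0.25 mM at 1/5000 s⁻¹) give a venous-scale curve
after a standard 0.1 mmol/kg dose: sharp first pass, ~0.2 mM whole-blood
tail at 24 min, unimodal. Every term has a closed-form antiderivative
(`population_aif_integral`, via the regularised lower incomplete gamma
function), which serves as the quadrature oracle in tests.

## Patlak estimation

The kinetic model is `C_t(t) = v_p·C_p(t) + PS·∫₀ᵗC_p dτ`, appropriate for
low-permeability tissue sampled at low temporal resolution. Estimation is
ordinary least squares of `C_t` on the two regressors `[C_p, ∫C_p]` with no
intercept (the model has none; baseline is removed in the concentration
step). Time is converted to minutes at the regression interface so PS is in
min⁻¹; the conventional reporting scalings (×10⁴ for PS, ×10² for v_p) are
applied only at the reporting boundary. 95% CIs come from the standard OLS
covariance (statsmodels). Negative estimates are reported, not clamped, so
cohort statistics see the estimator's true distribution.

The running integral is trapezoidal with an implicit (t = 0, C = 0) origin
prepended when the first sample is post-injection — the true curve is zero
before the bolus. The forward simulator uses the same quadrature, so
noiseless fit-forward round trips are exact to machine precision; this is
the standard digital-reference-object convention, where ground truth is
defined on the sampled grid.

How many early frames the original analysis excluded is not recorded;
the default here is `exclude_n_early = 2` post-baseline frames (~2.4 min at
73 s resolution), which covers the bolus first pass while retaining 17 of 20
frames. It is a parameter everywhere (library, CLI, config). Frames are
unweighted. The excluded frames still contribute to the running integral —
exclusion drops regression rows, not history.

The per-patient orchestration takes the median signal across each tissue
mask per frame (`S_0` = median over the pre-contrast baseline frames; the
default protocol has one), skips absent tissue classes (e.g. no WMH mask)
rather than failing, and also computes the semi-quantitative enhancement
slope — the OLS slope of `100·E_i` versus time in minutes over the retained
frames, in % min⁻¹ — for comparison with PS.

## Synthetic phantoms

`generate_phantom` lays out disjoint voxel blocks for the four tissue
classes and the vein on a small grid (default 16×16×4; geometry is not
anatomical by design). Tissue concentration courses come from the Patlak
forward model on the plasma input; vein voxels carry whole blood. Signals
follow the SPGR equation with `1/T1(t) = 1/T10 + r1·C(t)`; the two VFA
volumes are generated at the same `M0`/`T10`. Default kinetic truths are the
observed cohort means per tissue (PS 2.929/3.896/3.941/5.714 ×10⁻⁴ min⁻¹ and
v_p 0.600/1.232/0.825/0.815 ×10⁻² for WM/GM/WMH/RSL), so phantom round trips
double as anchored end-to-end checks; T10 defaults are standard 1.5 T values
(WM 650, deep GM 1100, WMH 900, RSL 1200, blood 1440 ms).

Noise is additive Gaussian on the signal. ROI-median curves at realistic
SNR sit far above the Rician floor, so the Gaussian approximation is
adequate at the analysis unit; voxelwise low-SNR magnitude statistics are
not emulated. All randomness flows from the spec seed. What phantom tests
do **not** show: robustness to motion, registration error, segmentation
error, B1 bias, water-exchange effects or spatially varying T10 — none of
these are simulated.

## Synthetic cohorts

`generate_cohort` draws covariates independently: age, mean arterial
pressure and pulse pressure as normals fitted to the printed median/IQR
summaries (IQR width = 1.349 σ); lacunar subtype, hypertension and smoking
as Bernoulli at the printed prevalences; the Fazekas total score (0–6) at
the printed frequencies. Only marginal summaries of the source cohort are
published, so the joint structure (independence) is a package choice; WMH
volume (% of intracranial volume) is the exception, generated log-linearly
in Fazekas (slope 0.5, residual SD 1.0 on the log scale, anchored at the
cohort median 0.91%) so the two burden metrics correlate as they do in
practice. Haematocrit is Normal(0.45, 0.03), clipped to [0.2, 0.65].

Each per-tissue outcome is the linear predictor from the published
coefficient sets plus Gaussian residual. The residual SD is derived by
variance decomposition: target total SD (the printed per-tissue SD) minus
the variance explained by the coefficients under the generator covariate
distributions, floored at 30% of the target SD. A single residual σ cannot
reproduce every printed CI half-width simultaneously; since OLS coefficient
estimates are unbiased regardless of σ, this calibration affects only the
spread, not the centre, of recovered coefficients. Intercepts are solved so
expected outcomes equal the printed per-tissue means. Stroke subtype is
coded 0 = cortical, 1 = lacunar.

## Association models

Each model is OLS with intercept of one outcome on the six clinical
covariates plus one burden metric (Fazekas score or normalised WMH volume —
separate models, never both, mirroring the study design). Complete-case
analysis with the dropped-row count recorded; fewer than 15 complete rows is
an error. Wald 95% CIs and two-sided p-values; no multiple-testing
correction across the 16 models (4 tissues × 2 parameters × 2 burden
metrics), matching the unadjusted reporting convention. Variance inflation
factors are computed from the auxiliary-regression definition
`VIF_j = 1/(1 − R²_j)`; perfect collinearity is flagged as infinite.
Residual checks are numeric statistics — Shapiro–Wilk for normality and
Breusch–Pagan for heteroscedasticity — rather than visual plot inspection,
for testability.

Dichotomised curve summaries split by Fazekas (low ≤ 3, high ≥ 4) or by the
realised cohort median age (the study's 66.72 y applies to its cohort only)
and report per-frame mean, SD (ddof = 1) and SEM = SD/√n per group; groups
of fewer than two patients are an error since SEM is undefined.

## Numerical choices and edge cases

- Trapezoidal quadrature is exact for piecewise-linear integrands; against
  the closed-form input-function integral on a fine grid the relative error
  is < 0.1% wherever the integral exceeds 1% of its final value (the kink at
  bolus arrival makes relative error meaningless on near-zero values).
- Rank checks precede every regression; all-zero plasma input or duplicated
  predictors raise with the collinear set named.
- Even-count medians use the numpy mean-of-middle convention.
- Masks and series must share the voxel grid exactly; no resampling is
  performed (registration is an upstream concern).
- Reporting-unit scalings are exactly ×10⁴ (PS) and ×10² (v_p) and are
  applied only at the reporting boundary.

## Problem sizes

Default simulations are deliberately small: phantoms of 1,024 voxels × 20
frames, cohort replicates of n = 201, and 200-replicate Monte-Carlo loops
for coefficient recovery — each chosen as the smallest size at which the
corresponding property (exact recovery, CI coverage, unbiasedness) is
informative. The complete test suite and the acceptance script each run in
seconds on a single CPU.

## Known limitations

- PS and v_p are estimated from ROI-median curves; voxelwise PS maps are out
  of scope.
- The Patlak model ignores backflux and water exchange; extended Tofts or
  two-compartment exchange models are deliberately not implemented.
- The phantom geometry is a layout of labelled blocks, not a brain; it
  validates the estimator chain, not spatial processing.
- The population input function is a synthesis device; real analyses should
  use the measured venous curve.
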