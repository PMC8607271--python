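"""Per-patient orchestration: ROI curves, enhancement slopes, end-to-end fits.

The analysis unit is the ROI-median signal curve for each of four tissue
classes — normal-appearing white matter (WM), deep grey matter (GM), white
matter hyperintensities (WMH) and recent stroke lesions (RSL) — plus the
venous input mask. Each tissue curve is taken through VFA T1 estimation,
concentration conversion and the Patlak fit against the patient's plasma
input function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .aif import DEFAULT_HCT, blood_to_plasma, extract_blood_curve
from .curves import SignalCurve
from .dataio import DynamicSeries
from .patlak import PatlakFit, patlak_fit
from .spgr import (AcquisitionParams, T1Estimate, concentration_from_signal,
                   enhancement, fit_vfa_t1)

__all__ = [
    "TISSUE_CLASSES",
    "TissueROI",
    "PatientResult",
    "roi_median_curve",
    "enhancement_slope",
    "run_patient",
]

log = logging.getLogger("bbbleak")

TISSUE_CLASSES = ("WM", "GM", "WMH", "RSL")


@dataclass(frozen=True)
class TissueROI:
    """A tissue-class mask on the acquisition grid."""

    tissue_class: str
    mask: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"empty mask for tissue class {self.tissue_class}")
        object.__setattr__(self, "mask", mask)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class PatientResult:
    """Per-tissue Patlak fits and enhancement slopes for one patient.

    ``slopes_pct_per_min`` are semi-quantitative enhancement slopes
    (% min^-1). ``t10_ms`` records the ROI T1 estimates used. ``qc`` holds
    skip reasons, clamped-frame counters and flagged T1 fits.
    """

    patient_id: str
    fits: dict[str, PatlakFit] = field(default_factory=dict)
    slopes_pct_per_min: dict[str, float] = field(default_factory=dict)
    t10_ms: dict[str, float] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)


def roi_median_curve(series: DynamicSeries, roi: TissueROI) -> SignalCurve:
    """Median signal across mask voxels per frame.

    S_0 is the median over the pre-contrast baseline frame(s) of the median
    curve. The even-count median is the mean of the two middle values
    (numpy convention).
    """
    if roi.mask.shape != series.data.shape[:3]:
        raise ValueError(
            f"mask grid {roi.mask.shape} does not match series "
            f"{series.data.shape[:3]} for {roi.tissue_class}"
        )
    sig = np.median(series.data[roi.mask], axis=0)
    s0 = float(np.median(sig[: series.n_baseline]))
    return SignalCurve(series.times_s, sig, s0)


def enhancement_slope(curve: SignalCurve, exclude_n_early: int = 2,
                      n_baseline: int = 1) -> float:
    """Semi-quantitative leakage surrogate: OLS slope of 100*E_i vs minutes.

    Uses the same retained-frame rule as the Patlak fit (baseline and early
    bolus frames dropped). Units: % min^-1.
    """
    start = n_baseline + exclude_n_early
    if len(curve) - start < 3:
        raise ValueError("need >= 3 retained frames for the enhancement slope")
    t_min = curve.times_s[start:] / 60.0
    e_pct = 100.0 * enhancement(curve)[start:]
    slope, _ = np.polyfit(t_min, e_pct, 1)
    return float(slope)


def _roi_vfa_t1(vfa_low: np.ndarray, vfa_high: np.ndarray, mask: np.ndarray,
                params: AcquisitionParams) -> T1Estimate:
    """Two-point T1 from the ROI-median low/high flip-angle signals."""
    return fit_vfa_t1(float(np.median(vfa_low[mask])),
                      float(np.median(vfa_high[mask])), params)


def run_patient(series: DynamicSeries, vfa_low: np.ndarray,
                vfa_high: np.ndarray, tissue_masks: dict[str, np.ndarray],
                vein_mask: np.ndarray, hct: float | None,
                params: AcquisitionParams, *, patient_id: str = "patient",
                exclude_n_early: int = 2,
                blood_t10_ms: float | None = None) -> PatientResult:
    """Full signal-to-Patlak analysis for one patient.

    Composes: ROI-median VFA T1 estimation, signal-to-concentration
    conversion, venous input extraction with haematocrit correction, and the
    Patlak regression plus enhancement slope per available tissue class.
    Deterministic given its inputs. Tissue classes with a missing or empty
    mask are skipped and logged, not errors (e.g. patients without WMH).
    """
    result = PatientResult(patient_id=patient_id)
    result.qc["skipped"] = []
    result.qc["clamped_frames"] = {}
    result.qc["flagged_t1"] = []

    if hct is None:
        hct = DEFAULT_HCT
        result.qc["hct_defaulted"] = True

    vein = np.asarray(vein_mask, dtype=bool)
    if blood_t10_ms is None:
        t10_blood = _roi_vfa_t1(vfa_low, vfa_high, vein, params)
    else:
        t10_blood = T1Estimate(blood_t10_ms,
                               float(np.median(vfa_high[vein])))
    cb = extract_blood_curve(series, vein, t10_blood, params)
    cp = blood_to_plasma(cb, hct)
    result.qc["clamped_frames"]["blood"] = cb.n_clamped
    result.t10_ms["blood"] = t10_blood.t10_ms

    for tissue, mask in tissue_masks.items():
        if mask is None or not np.asarray(mask, dtype=bool).any():
            log.info("%s: tissue class %s absent, skipping", patient_id, tissue)
            result.qc["skipped"].append(tissue)
            continue
        roi = TissueROI(tissue, mask)
        t10 = _roi_vfa_t1(vfa_low, vfa_high, roi.mask, params)
        if t10.flagged:
            result.qc["flagged_t1"].append(tissue)
        result.t10_ms[tissue] = t10.t10_ms
        curve = roi_median_curve(series, roi)
        ct = concentration_from_signal(curve, t10, params)
        result.qc["clamped_frames"][tissue] = ct.n_clamped
        result.fits[tissue] = patlak_fit(
            ct, cp, exclude_n_early=exclude_n_early,
            n_baseline=series.n_baseline,
        )
        result.slopes_pct_per_min[tissue] = enhancement_slope(
            curve, exclude_n_early=exclude_n_early,
            n_baseline=series.n_baseline,
        )
        log.info("%s/%s: PS=%.3f e-4/min vP=%.3f e-2 (%d voxels)",
                 patient_id, tissue, result.fits[tissue].ps_e4_per_min,
                 result.fits[tissue].vp_e2, roi.voxel_count)
    return result
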