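"""Synthetic data: digital reference phantoms and covariate-driven cohorts.

Two generators:

* :func:`generate_phantom` builds a 4D dynamic SPGR acquisition (plus the
  two pre-contrast variable-flip-angle volumes and tissue/vein masks) whose
  tissue curves obey the Patlak forward model exactly, with known
  ground-truth PS and v_p per tissue class. It is the test bed for the
  whole signal-to-kinetics chain.

* :func:`generate_cohort` draws a patient table whose per-tissue PS and v_p
  outcomes are linear in the clinical covariates (age, stroke subtype, mean
  arterial pressure, hypertension, pulse pressure, smoking, Fazekas score)
  with configurable coefficients, the test bed for the association stage.

Default ground-truth values reproduce the observed cohort summaries of a
201-patient small-vessel-disease study: per-tissue PS/v_p means, covariate
prevalences and the fitted association coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aif import AIFParams, blood_to_plasma, population_aif
from .dataio import DynamicSeries
from .patlak import PS_REPORT_SCALE, VP_REPORT_SCALE, patlak_forward
from .pipeline import TISSUE_CLASSES
from .spgr import AcquisitionParams, spgr_signal

__all__ = [
    "TissueTruth",
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "CohortSpec",
    "generate_cohort",
    "PREDICTORS",
    "DEFAULT_PS_COEFFICIENTS",
    "DEFAULT_VP_COEFFICIENTS",
    "DEFAULT_PS_MEAN_SD",
    "DEFAULT_VP_MEAN_SD",
]

# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

#: Observed per-tissue cohort means (SD) in reporting units: PS 1e-4 min^-1.
DEFAULT_PS_MEAN_SD = {
    "WM": (2.929, 1.672),
    "GM": (3.896, 1.588),
    "WMH": (3.941, 1.775),
    "RSL": (5.714, 4.700),
}
#: Observed per-tissue cohort means (SD) in reporting units: v_p 1e-2.
DEFAULT_VP_MEAN_SD = {
    "WM": (0.600, 0.370),
    "GM": (1.232, 0.406),
    "WMH": (0.825, 0.560),
    "RSL": (0.815, 0.584),
}

#: Approximate 1.5 T pre-contrast T1 values per tissue class, ms.
DEFAULT_T10_MS = {"WM": 650.0, "GM": 1100.0, "WMH": 900.0, "RSL": 1200.0,
                  "vein": 1440.0}


@dataclass(frozen=True)
class TissueTruth:
    """Ground truth for one phantom tissue class (natural units)."""

    t10_ms: float
    ps_per_min: float
    vp_frac: float
    n_voxels: int = 60

    def __post_init__(self):
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if not self.t10_ms > 0:
            raise ValueError("t10_ms must be positive")
        if not (0.0 <= self.vp_frac <= 1.0):
            raise ValueError("vp_frac must be in [0, 1]")


def _default_tissues() -> dict[str, TissueTruth]:
    return {
        t: TissueTruth(
            t10_ms=DEFAULT_T10_MS[t],
            ps_per_min=DEFAULT_PS_MEAN_SD[t][0] / PS_REPORT_SCALE,
            vp_frac=DEFAULT_VP_MEAN_SD[t][0] / VP_REPORT_SCALE,
        )
        for t in TISSUE_CLASSES
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic dynamic acquisition.

    ``noise_sd`` is additive Gaussian noise on the signal (scanner units;
    0 = noiseless). ``m0`` sets the equilibrium signal scale. All randomness
    derives from ``seed``.
    """

    shape: tuple[int, int, int] = (16, 16, 4)
    tissues: dict[str, TissueTruth] = field(default_factory=_default_tissues)
    vein_t10_ms: float = DEFAULT_T10_MS["vein"]
    vein_n_voxels: int = 20
    aif: AIFParams = field(default_factory=AIFParams)
    hct: float = 0.45
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    m0: float = 1000.0
    noise_sd: float = 0.0
    n_baseline: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.hct < 1.0):
            raise ValueError("hct must be in [0, 1)")
        total = sum(t.n_voxels for t in self.tissues.values()) + self.vein_n_voxels
        if total > int(np.prod(self.shape)):
            raise ValueError(
                f"grid {self.shape} too small for {total} requested voxels"
            )

    def with_truth(self, tissue: str, ps_per_min: float,
                   vp_frac: float) -> "PhantomSpec":
        """Copy of the spec with one tissue's kinetic truth replaced."""
        tissues = dict(self.tissues)
        tissues[tissue] = replace(tissues[tissue], ps_per_min=ps_per_min,
                                  vp_frac=vp_frac)
        return replace(self, tissues=tissues)


@dataclass
class Phantom:
    """A generated phantom: images, masks and the ground-truth record."""

    series: DynamicSeries
    vfa_low: np.ndarray
    vfa_high: np.ndarray
    masks: dict[str, np.ndarray]      # tissue class -> bool volume
    vein_mask: np.ndarray
    truth: dict
    spec: PhantomSpec


def _signal_timecourse(m0: float, t10_ms: float, conc_mM: np.ndarray,
                       acq: AcquisitionParams, flip_deg: float) -> np.ndarray:
    """SPGR signal over time for a voxel with known concentration course."""
    r1_t = 1.0 / (t10_ms / 1000.0) + acq.r1_per_s_mM * conc_mM  # s^-1
    t1_ms = 1000.0 / r1_t
    return spgr_signal(m0, t1_ms, flip_deg, acq.tr_ms)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the 4D dynamic series, VFA volumes and masks from a spec.

    Tissue concentration courses come from the Patlak forward model driven
    by the haematocrit-corrected population input function; vein voxels
    carry the whole-blood curve. Signals follow the SPGR steady-state
    equation; Gaussian noise of ``spec.noise_sd`` is added to every volume.
    Masks are disjoint. Deterministic given ``spec.seed``.
    """
    acq = spec.acquisition
    times = acq.frame_times_s
    rng = np.random.default_rng(spec.seed)

    cb = population_aif(spec.aif, times)
    cp = blood_to_plasma(cb, spec.hct)

    # Region signal timecourses (noiseless) and pre-contrast VFA values.
    regions: list[tuple[str, int, np.ndarray, float]] = []
    for name, tt in spec.tissues.items():
        ct = patlak_forward(tt.ps_per_min, tt.vp_frac, cp)
        sig = _signal_timecourse(spec.m0, tt.t10_ms, ct.conc_mM, acq,
                                 acq.flip_high_deg)
        regions.append((name, tt.n_voxels, sig, tt.t10_ms))
    vein_sig = _signal_timecourse(spec.m0, spec.vein_t10_ms, cb.conc_mM, acq,
                                  acq.flip_high_deg)
    regions.append(("vein", spec.vein_n_voxels, vein_sig, spec.vein_t10_ms))

    n_vox = int(np.prod(spec.shape))
    data = np.zeros((n_vox, len(times)))
    low = np.zeros(n_vox)
    high = np.zeros(n_vox)
    masks_flat: dict[str, np.ndarray] = {}
    start = 0
    for name, count, sig, t10 in regions:
        idx = slice(start, start + count)
        data[idx] = sig
        low[idx] = spgr_signal(spec.m0, t10, acq.flip_low_deg, acq.tr_ms)
        high[idx] = spgr_signal(spec.m0, t10, acq.flip_high_deg, acq.tr_ms)
        m = np.zeros(n_vox, dtype=bool)
        m[idx] = True
        masks_flat[name] = m
        start += count

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, data.shape)
        low += rng.normal(0.0, spec.noise_sd, low.shape)
        high += rng.normal(0.0, spec.noise_sd, high.shape)

    shape = spec.shape
    series = DynamicSeries(data.reshape(*shape, len(times)), times,
                           n_baseline=spec.n_baseline)
    masks = {k: v.reshape(shape) for k, v in masks_flat.items()}
    truth = {
        name: {"ps_per_min": tt.ps_per_min, "vp_frac": tt.vp_frac,
               "ps_e4_per_min": tt.ps_per_min * PS_REPORT_SCALE,
               "vp_e2": tt.vp_frac * VP_REPORT_SCALE, "t10_ms": tt.t10_ms}
        for name, tt in spec.tissues.items()
    }
    truth["hct"] = spec.hct
    truth["vein_t10_ms"] = spec.vein_t10_ms
    return Phantom(series, low.reshape(shape), high.reshape(shape),
                   {k: masks[k] for k in spec.tissues}, masks["vein"],
                   truth, spec)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

PREDICTORS = ("age", "stroke_subtype", "map", "hypertension",
              "pulse_pressure", "smoking", "fazekas_total")

# Fitted association coefficients used as generator ground truth
# (reporting units per predictor unit), per tissue class.
DEFAULT_PS_COEFFICIENTS = {
    "WM":  {"age": -0.044, "fazekas_total": 0.150, "stroke_subtype": -0.398,
            "map": -0.006, "hypertension": 0.411, "pulse_pressure": 0.004,
            "smoking": -0.423},
    "WMH": {"age": -0.030, "fazekas_total": 0.092, "stroke_subtype": -0.039,
            "map": 0.002, "hypertension": 0.309, "pulse_pressure": 0.002,
            "smoking": -0.028},
    "GM":  {"age": -0.044, "fazekas_total": 0.150, "stroke_subtype": -0.285,
            "map": -0.004, "hypertension": 0.207, "pulse_pressure": 0.010,
            "smoking": 0.148},
    "RSL": {"age": 0.019, "fazekas_total": -0.067, "stroke_subtype": -2.017,
            "map": 0.027, "hypertension": 2.195, "pulse_pressure": -0.020,
            "smoking": 0.774},
}
DEFAULT_VP_COEFFICIENTS = {
    "WM":  {"age": -0.008, "fazekas_total": 0.031, "stroke_subtype": 0.060,
            "map": 0.001, "hypertension": -0.162, "pulse_pressure": 0.000,
            "smoking": -0.101},
    "WMH": {"age": -0.008, "fazekas_total": -0.088, "stroke_subtype": 0.078,
            "map": 0.001, "hypertension": -0.172, "pulse_pressure": -0.001,
            "smoking": -0.002},
    "GM":  {"age": -0.007, "fazekas_total": 0.010, "stroke_subtype": 0.073,
            "map": 0.000, "hypertension": -0.145, "pulse_pressure": -0.001,
            "smoking": -0.131},
    "RSL": {"age": -0.001, "fazekas_total": -0.026, "stroke_subtype": -0.136,
            "map": 0.001, "hypertension": -0.159, "pulse_pressure": 0.001,
            "smoking": 0.091},
}

# IQR width of a normal is 1.349 sigma; continuous covariates are fitted to
# the printed median (IQR) summaries.
_IQR_TO_SD = 1.0 / 1.349


@dataclass(frozen=True)
class CohortSpec:
    """Generator spec for a synthetic patient cohort.

    Covariates: age, MAP and pulse pressure as normals fitted to the study's
    median/IQR summaries; binary covariates at the study prevalences;
    Fazekas total score (0-6) at the study frequencies; WMH volume (% of
    intracranial volume) log-linear in Fazekas so the two burden metrics
    correlate. Each per-tissue outcome (reporting units) is

        intercept + sum_j beta_j x_j + Normal(0, residual_sd).

    ``coefficients[("ps"|"vp", tissue)]`` maps predictor -> beta.
    Intercepts are solved so expected outcomes hit ``outcome_means``;
    residual SDs are solved so outcome variances hit ``outcome_sds``
    (floored at 30% of the target SD). Haematocrit is drawn per patient.
    """

    n_patients: int = 201
    age_mean: float = 66.7
    age_sd: float = (75.2 - 56.8) * _IQR_TO_SD
    lacunar_prop: float = 0.458
    map_mean: float = 141.0
    map_sd: float = (159.0 - 130.0) * _IQR_TO_SD
    hypertension_prop: float = 0.731
    pp_mean: float = 60.0
    pp_sd: float = (76.0 - 49.0) * _IQR_TO_SD
    smoking_prop: float = 0.358
    fazekas_probs: tuple = (0.0348, 0.0846, 0.3682, 0.1144, 0.1443,
                            0.0995, 0.1542)
    wmh_log_slope: float = 0.50
    wmh_log_sd: float = 1.0
    wmh_median_pct: float = 0.91
    hct_mean: float = 0.45
    hct_sd: float = 0.03
    coefficients: dict = field(default_factory=lambda: {
        **{("ps", t): dict(DEFAULT_PS_COEFFICIENTS[t]) for t in TISSUE_CLASSES},
        **{("vp", t): dict(DEFAULT_VP_COEFFICIENTS[t]) for t in TISSUE_CLASSES},
    })
    outcome_means: dict = field(default_factory=lambda: {
        **{("ps", t): DEFAULT_PS_MEAN_SD[t][0] for t in TISSUE_CLASSES},
        **{("vp", t): DEFAULT_VP_MEAN_SD[t][0] for t in TISSUE_CLASSES},
    })
    outcome_sds: dict = field(default_factory=lambda: {
        **{("ps", t): DEFAULT_PS_MEAN_SD[t][1] for t in TISSUE_CLASSES},
        **{("vp", t): DEFAULT_VP_MEAN_SD[t][1] for t in TISSUE_CLASSES},
    })
    residual_sd_override: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for p in (self.lacunar_prop, self.hypertension_prop,
                  self.smoking_prop):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must be in [0, 1]")
        probs = np.asarray(self.fazekas_probs, dtype=float)
        if probs.size != 7 or np.any(probs < 0):
            raise ValueError("fazekas_probs must be 7 non-negative weights")
        if not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValueError("fazekas_probs must sum to 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    # -- moments of the covariate distributions (used for calibration) ----
    def covariate_means(self) -> dict[str, float]:
        faz = np.arange(7)
        probs = np.asarray(self.fazekas_probs) / np.sum(self.fazekas_probs)
        return {
            "age": self.age_mean,
            "stroke_subtype": self.lacunar_prop,
            "map": self.map_mean,
            "hypertension": self.hypertension_prop,
            "pulse_pressure": self.pp_mean,
            "smoking": self.smoking_prop,
            "fazekas_total": float(np.sum(faz * probs)),
        }

    def covariate_variances(self) -> dict[str, float]:
        faz = np.arange(7)
        probs = np.asarray(self.fazekas_probs) / np.sum(self.fazekas_probs)
        mu = float(np.sum(faz * probs))
        return {
            "age": self.age_sd ** 2,
            "stroke_subtype": self.lacunar_prop * (1 - self.lacunar_prop),
            "map": self.map_sd ** 2,
            "hypertension": self.hypertension_prop * (1 - self.hypertension_prop),
            "pulse_pressure": self.pp_sd ** 2,
            "smoking": self.smoking_prop * (1 - self.smoking_prop),
            "fazekas_total": float(np.sum((faz - mu) ** 2 * probs)),
        }

    def residual_sd(self, outcome: tuple[str, str]) -> float:
        """Residual SD by variance decomposition of the target outcome SD.

        Covariates are generated independently, so explained variance is
        sum_j beta_j^2 var(x_j); the residual picks up the remainder,
        floored at 30% of the target SD to stay positive when the stated
        coefficients over-explain the stated spread.
        """
        if outcome in self.residual_sd_override:
            return float(self.residual_sd_override[outcome])
        var_x = self.covariate_variances()
        beta = self.coefficients[outcome]
        explained = sum(beta.get(p, 0.0) ** 2 * var_x[p] for p in PREDICTORS)
        total = self.outcome_sds[outcome] ** 2
        return float(np.sqrt(max(total - explained, (0.3 ** 2) * total)))

    def intercept(self, outcome: tuple[str, str]) -> float:
        mu = self.covariate_means()
        beta = self.coefficients[outcome]
        return float(self.outcome_means[outcome]
                     - sum(beta.get(p, 0.0) * mu[p] for p in PREDICTORS))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table, one row per patient.

    Columns: patient_id, hct, the seven covariates, wmh_icv_pct, and the
    per-tissue outcomes ``ps_wm .. vp_rsl`` in reporting units
    (PS 1e-4 min^-1, v_p 1e-2). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    probs = np.asarray(spec.fazekas_probs, dtype=float)
    probs = probs / probs.sum()

    df = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "age": rng.normal(spec.age_mean, spec.age_sd, n),
        "stroke_subtype": (rng.random(n) < spec.lacunar_prop).astype(int),
        "map": rng.normal(spec.map_mean, spec.map_sd, n),
        "hypertension": (rng.random(n) < spec.hypertension_prop).astype(int),
        "pulse_pressure": rng.normal(spec.pp_mean, spec.pp_sd, n),
        "smoking": (rng.random(n) < spec.smoking_prop).astype(int),
        "fazekas_total": rng.choice(7, size=n, p=probs),
        "hct": np.clip(rng.normal(spec.hct_mean, spec.hct_sd, n), 0.2, 0.65),
    })
    # WMH volume (% ICV): log-linear in Fazekas, anchored at the median score.
    faz_median = float(np.searchsorted(np.cumsum(probs), 0.5))
    log_wmh = (np.log(spec.wmh_median_pct)
               + spec.wmh_log_slope * (df["fazekas_total"] - faz_median)
               + rng.normal(0.0, spec.wmh_log_sd, n))
    df["wmh_icv_pct"] = np.exp(log_wmh)

    for (param, tissue), beta in spec.coefficients.items():
        lin = np.full(n, spec.intercept((param, tissue)))
        for p in PREDICTORS:
            lin = lin + beta.get(p, 0.0) * df[p].to_numpy(dtype=float)
        sd = spec.residual_sd((param, tissue))
        df[f"{param}_{tissue.lower()}"] = lin + rng.normal(0.0, sd, n)
    return df
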