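"""Spoiled gradient-echo (SPGR) signal physics.

Forward steady-state signal model, two-point variable-flip-angle (VFA) T1
estimation, relative enhancement, and conversion of a dynamic signal curve
into gadolinium concentration via algebraic inversion of the SPGR equation.

All angles are accepted in degrees and converted internally once; all
relaxation times are in milliseconds at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ConcentrationCurve, SignalCurve

__all__ = [
    "AcquisitionParams",
    "T1Estimate",
    "spgr_signal",
    "fit_vfa_t1",
    "vfa_t1_map",
    "enhancement",
    "concentration_from_signal",
]

# Fallback T1 bounds (ms) used when noise pushes the two-point VFA solution
# outside the physical branch E1 in (0, 1).
_T1_FLOOR_MS = 1.0
_T1_CEIL_MS = 20_000.0


@dataclass(frozen=True)
class AcquisitionParams:
    """Dynamic SPGR acquisition geometry and contrast-agent relaxivity.

    Defaults follow a 1.5 T FSPGR brain protocol: TR/TE = 8.24/3.1 ms,
    variable flip angles 2 and 12 degrees, 20 dynamic frames at 73 s, and
    gadoterate longitudinal relaxivity r1 = 4.5 s^-1 mM^-1.
    """

    tr_ms: float = 8.24
    te_ms: float = 3.1
    flip_low_deg: float = 2.0
    flip_high_deg: float = 12.0
    frame_interval_s: float = 73.0
    n_frames: int = 20
    r1_per_s_mM: float = 4.5

    def __post_init__(self):
        if not self.tr_ms > 0:
            raise ValueError("tr_ms must be positive")
        if not (0 < self.flip_low_deg < self.flip_high_deg <= 90):
            raise ValueError("require 0 < flip_low_deg < flip_high_deg <= 90")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 3:
            raise ValueError("n_frames must be at least 3")
        if not self.r1_per_s_mM > 0:
            raise ValueError("relaxivity r1 must be positive")

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * float(self.frame_interval_s)


@dataclass(frozen=True)
class T1Estimate:
    """Pre-contrast T1 (``t10_ms``) and equilibrium signal scale ``m0``.

    ``flagged`` marks estimates where the raw two-point solution was
    non-physical and the fallback clamp was applied.
    """

    t10_ms: float
    m0: float
    flagged: bool = False

    def __post_init__(self):
        if not self.t10_ms > 0:
            raise ValueError("t10_ms must be positive")
        if not self.m0 > 0:
            raise ValueError("m0 must be positive")


def spgr_signal(m0, t1_ms, flip_deg, tr_ms):
    """Steady-state spoiled gradient-echo signal.

    S = m0 * sin(a) * (1 - E1) / (1 - cos(a) * E1),  E1 = exp(-TR/T1).

    Accepts scalars or broadcastable arrays; T2*/TE decay is absorbed into
    ``m0`` (constant across the dynamic series at fixed TE).
    """
    t1_ms = np.asarray(t1_ms, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be positive")
    tr_ms = np.asarray(tr_ms, dtype=float)
    if np.any(tr_ms <= 0):
        raise ValueError("tr_ms must be positive")
    flip_deg = np.asarray(flip_deg, dtype=float)
    if np.any(flip_deg <= 0) or np.any(flip_deg > 90):
        raise ValueError("flip_deg must be in (0, 90]")
    alpha = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    out = m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)
    return out if out.ndim else float(out)


def _vfa_invert(signal_low, signal_high, params: AcquisitionParams,
                strict: bool = True):
    """Vectorised two-point VFA solution. Returns (t10_ms, m0, flagged)."""
    s_l = np.asarray(signal_low, dtype=float)
    s_h = np.asarray(signal_high, dtype=float)
    a_l = np.deg2rad(params.flip_low_deg)
    a_h = np.deg2rad(params.flip_high_deg)
    # Linearised SPGR: S/sin(a) = E1 * S/tan(a) + m0 * (1 - E1)
    y_l, x_l = s_l / np.sin(a_l), s_l / np.tan(a_l)
    y_h, x_h = s_h / np.sin(a_h), s_h / np.tan(a_h)
    dx = x_l - x_h
    degenerate = np.abs(dx) <= 1e-9 * np.maximum(np.abs(x_l), np.abs(x_h))
    if strict and np.any(degenerate):
        raise ValueError("degenerate VFA input: identical effective points")
    e1 = (y_l - y_h) / np.where(degenerate, 1.0, dx)
    e1_lo = np.exp(-params.tr_ms / _T1_FLOOR_MS)
    e1_hi = np.exp(-params.tr_ms / _T1_CEIL_MS)
    flagged = degenerate | (e1 <= e1_lo) | (e1 >= e1_hi)
    e1_c = np.clip(np.where(degenerate, e1_hi, e1), e1_lo, e1_hi)
    t10 = -params.tr_ms / np.log(e1_c)
    m0 = (y_l - e1_c * x_l) / (1.0 - e1_c)
    return t10, m0, flagged


def fit_vfa_t1(signal_low: float, signal_high: float,
               params: AcquisitionParams) -> T1Estimate:
    """Closed-form two-point variable flip angle T1 estimate.

    Solves the linearised SPGR relation through the (low, high) flip-angle
    signal pair; round-trips :func:`spgr_signal` exactly on noiseless input.
    A solution implying E1 outside (0, 1) (noise) is clamped to the T1 range
    [1 ms, 20 s] and flagged.
    """
    if not (signal_low > 0 and signal_high > 0):
        raise ValueError("VFA signals must be positive")
    t10, m0, flagged = _vfa_invert(signal_low, signal_high, params)
    if m0 <= 0:  # degenerate under flagging; keep a usable scale
        m0 = max(float(signal_high), 1e-12)
        flagged = True
    return T1Estimate(float(t10), float(m0), bool(flagged))


def vfa_t1_map(vol_low: np.ndarray, vol_high: np.ndarray,
               params: AcquisitionParams,
               mask: np.ndarray | None = None):
    """Voxelwise two-point VFA T1 map.

    Returns ``(t10_ms, m0, flagged)`` arrays shaped like the inputs; voxels
    outside ``mask`` (or with non-positive signal) are zero and flagged.
    """
    vol_low = np.asarray(vol_low, dtype=float)
    vol_high = np.asarray(vol_high, dtype=float)
    if vol_low.shape != vol_high.shape:
        raise ValueError("VFA volumes must share a grid")
    valid = (vol_low > 0) & (vol_high > 0)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    t10 = np.zeros(vol_low.shape)
    m0 = np.zeros(vol_low.shape)
    flagged = ~valid
    if np.any(valid):
        t, m, f = _vfa_invert(vol_low[valid], vol_high[valid], params,
                              strict=False)
        t10[valid], m0[valid] = t, m
        flagged[valid] = f
    return t10, m0, flagged


def enhancement(curve: SignalCurve) -> np.ndarray:
    """Relative signal enhancement E_i = (S_i - S_0) / S_0 per frame."""
    return (curve.values - curve.s0) / curve.s0


def concentration_from_signal(curve: SignalCurve, t10: T1Estimate,
                              params: AcquisitionParams,
                              flip_deg: float | None = None,
                              compartment: str = "tissue") -> ConcentrationCurve:
    """Convert a dynamic SPGR signal curve to gadolinium concentration.

    Inverts the SPGR equation through the scanner-gain-free signal ratio
    S_i/S_0 at the dynamic flip angle: given the pre-contrast T1 the ratio
    determines the post-contrast T1(t), and

        C_i = (1/r1) * (1/T1(t_i) - 1/T10)    [mM, with T1 in seconds].

    Frames where the implied T1 falls outside (0, T10] (noise-driven
    negative enhancement or an inadmissible inversion) are clamped to zero
    concentration and counted in ``n_clamped``.
    """
    flip = params.flip_high_deg if flip_deg is None else flip_deg
    alpha = np.deg2rad(flip)
    c = np.cos(alpha)
    e10 = np.exp(-params.tr_ms / t10.t10_ms)
    g0 = (1.0 - e10) / (1.0 - c * e10)  # relative SPGR saturation factor at T10
    ratio = curve.values / curve.s0
    a = ratio * g0
    e1 = (1.0 - a) / (1.0 - a * c)
    admissible = (e1 > 0.0) & (e1 < 1.0)
    conc = np.zeros(len(curve))
    if np.any(admissible):
        t1_ms = -params.tr_ms / np.log(e1[admissible])
        conc[admissible] = (1000.0 / params.r1_per_s_mM) * (
            1.0 / t1_ms - 1.0 / t10.t10_ms
        )
    n_clamped = int(np.sum(~admissible) + np.sum(conc < -1e-12))
    np.maximum(conc, 0.0, out=conc)
    return ConcentrationCurve(curve.times_s.copy(), conc, compartment, n_clamped)
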