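"""Time-series containers shared by the signal and kinetic stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPARTMENTS = ("whole_blood", "plasma", "tissue")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SignalCurve:
    """ROI-median SPGR signal intensity over the dynamic frames.

    Parameters
    ----------
    times_s:
        Frame mid-times from contrast injection, seconds, strictly increasing.
    values:
        Signal intensity per frame (scanner arbitrary units).
    s0:
        Pre-contrast baseline signal ``S_0`` (same units), must be positive.
    """

    times_s: np.ndarray
    values: np.ndarray
    s0: float

    def __post_init__(self):
        times = _as_1d(self.times_s, "times_s")
        values = _as_1d(self.values, "values")
        if times.size != values.size:
            raise ValueError("times_s and values must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if not self.s0 > 0:
            raise ValueError("baseline signal s0 must be positive")
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class ConcentrationCurve:
    """Gadolinium concentration over time for one compartment.

    ``compartment`` is one of ``whole_blood`` (measured in a venous mask),
    ``plasma`` (haematocrit-corrected input function) or ``tissue``.
    ``n_clamped`` counts frames where the signal-to-concentration inversion
    was non-physical and the concentration was clamped to zero (QC).
    """

    times_s: np.ndarray
    conc_mM: np.ndarray
    compartment: str
    n_clamped: int = 0

    def __post_init__(self):
        times = _as_1d(self.times_s, "times_s")
        conc = _as_1d(self.conc_mM, "conc_mM")
        if times.size != conc.size:
            raise ValueError("times_s and conc_mM must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "conc_mM", conc)

    def __len__(self) -> int:
        return self.times_s.size

    def with_conc(self, conc_mM, compartment: str | None = None,
                  n_clamped: int | None = None) -> "ConcentrationCurve":
        """Copy of this curve with new concentration values on the same grid."""
        return ConcentrationCurve(
            self.times_s.copy(),
            np.asarray(conc_mM, dtype=float),
            compartment or self.compartment,
            self.n_clamped if n_clamped is None else n_clamped,
        )
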