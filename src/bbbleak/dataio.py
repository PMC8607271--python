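"""File formats and configuration: NIfTI volumes, YAML config, dose helper."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .spgr import AcquisitionParams

__all__ = [
    "DynamicSeries",
    "read_dynamic_series",
    "read_volume",
    "read_mask",
    "write_volume",
    "RunConfig",
    "dose_mmol_per_kg",
]


@dataclass(frozen=True)
class DynamicSeries:
    """4D dynamic acquisition: (x, y, z, frame) data with frame timestamps.

    ``n_baseline`` is the number of leading pre-contrast frames (the default
    protocol acquires one dynamic frame before injection).
    """

    data: np.ndarray
    times_s: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_baseline: int = 1

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times_s, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"dynamic series must be 4D, got {data.ndim}D")
        if data.shape[3] < 3:
            raise ValueError("dynamic series needs at least 3 frames")
        if times.shape != (data.shape[3],):
            raise ValueError("times_s length must equal the frame count")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not 1 <= self.n_baseline < data.shape[3]:
            raise ValueError("n_baseline must be in [1, n_frames)")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times_s", times)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


def read_dynamic_series(path, frame_interval_s: float,
                        n_baseline: int = 1) -> DynamicSeries:
    """Load a 4D NIfTI dynamic series; timestamps are i * frame_interval_s."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D dynamic series, got {data.ndim}D")
    times = np.arange(data.shape[3]) * float(frame_interval_s)
    return DynamicSeries(data, times, np.asarray(img.affine), n_baseline)


def read_volume(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return data


def read_mask(path) -> np.ndarray:
    """Binary mask volume (anything > 0.5 counts as inside)."""
    return read_volume(path) > 0.5


def write_volume(data: np.ndarray, path, affine: np.ndarray | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine if affine is not None
                             else np.eye(4)), str(path))


@dataclass
class RunConfig:
    """Full pipeline configuration.

    ``patients`` is a list of dicts with keys ``id``, ``series``,
    ``vfa_low``, ``vfa_high``, ``vein_mask`` and ``masks`` (tissue class ->
    NIfTI path). ``cohort_csv`` carries per-patient haematocrit and clinical
    covariates.
    """

    out_dir: str
    patients: list = field(default_factory=list)
    cohort_csv: str | None = None
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    exclude_n_early: int = 2
    n_baseline: int = 1
    hct_default: float = 0.45
    blood_t10_ms: float | None = None
    burden_metrics: tuple = ("fazekas", "wmh_volume")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        acq = AcquisitionParams(**raw.pop("acquisition", {}))
        burden = tuple(raw.pop("burden_metrics", ("fazekas", "wmh_volume")))
        return cls(acquisition=acq, burden_metrics=burden, **raw)

    def to_yaml(self, path):
        raw = {
            "out_dir": self.out_dir,
            "patients": self.patients,
            "cohort_csv": self.cohort_csv,
            "acquisition": {
                "tr_ms": self.acquisition.tr_ms,
                "te_ms": self.acquisition.te_ms,
                "flip_low_deg": self.acquisition.flip_low_deg,
                "flip_high_deg": self.acquisition.flip_high_deg,
                "frame_interval_s": self.acquisition.frame_interval_s,
                "n_frames": self.acquisition.n_frames,
                "r1_per_s_mM": self.acquisition.r1_per_s_mM,
            },
            "exclude_n_early": self.exclude_n_early,
            "n_baseline": self.n_baseline,
            "hct_default": self.hct_default,
            "blood_t10_ms": self.blood_t10_ms,
            "burden_metrics": list(self.burden_metrics),
            "seed": self.seed,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def dose_mmol_per_kg(dose_ml_per_kg: float, agent_mmol_per_ml: float) -> float:
    """Contrast dose conversion: ml/kg of agent at mmol/ml -> mmol/kg.

    The standard protocol, 0.2 ml/kg of a 0.5 mmol/ml gadolinium agent,
    gives 0.1 mmol/kg body weight.
    """
    if dose_ml_per_kg < 0 or agent_mmol_per_ml < 0:
        raise ValueError("dose quantities must be non-negative")
    return dose_ml_per_kg * agent_mmol_per_ml
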