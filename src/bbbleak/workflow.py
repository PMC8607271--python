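"""End-to-end pipeline: images + cohort CSV -> per-patient fits -> cohort stats.

Also provides :func:`write_imaging_dataset`, which materialises a synthetic
cohort as per-patient NIfTI phantoms plus a ready-to-run config — the
round-trip harness for the whole pipeline.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (DynamicSeries, RunConfig, read_dynamic_series, read_mask,
                     read_volume, write_volume)
from .pipeline import TISSUE_CLASSES, run_patient
from .simulate import PhantomSpec, generate_phantom
from .associations import BURDEN_COLUMNS, fit_association_model

__all__ = ["run_pipeline", "write_imaging_dataset", "write_phantom"]

log = logging.getLogger("bbbleak")


def write_phantom(phantom, out_dir) -> dict:
    """Write one phantom as a NIfTI set + ground-truth JSON; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(phantom.series.data, out / "dynamic.nii.gz")
    write_volume(phantom.vfa_low, out / "vfa_low.nii.gz")
    write_volume(phantom.vfa_high, out / "vfa_high.nii.gz")
    entry = {
        "series": str(out / "dynamic.nii.gz"),
        "vfa_low": str(out / "vfa_low.nii.gz"),
        "vfa_high": str(out / "vfa_high.nii.gz"),
        "vein_mask": str(out / "mask_vein.nii.gz"),
        "masks": {},
    }
    write_volume(phantom.vein_mask.astype(np.uint8), out / "mask_vein.nii.gz")
    for tissue, mask in phantom.masks.items():
        p = out / f"mask_{tissue.lower()}.nii.gz"
        write_volume(mask.astype(np.uint8), p)
        entry["masks"][tissue] = str(p)
    with open(out / "truth.json", "w") as fh:
        json.dump(phantom.truth, fh, indent=2)
    return entry


def write_imaging_dataset(cohort: pd.DataFrame, out_dir,
                          base_spec: PhantomSpec | None = None,
                          noise_sd: float = 0.0, seed: int = 0) -> RunConfig:
    """Materialise a cohort as per-patient phantoms and a pipeline config.

    Each patient's phantom uses that row's per-tissue PS/v_p (reporting
    units in the table, converted to natural units) and haematocrit as
    ground truth, so the pipeline output can be checked against the cohort
    table itself.
    """
    from dataclasses import replace

    base = base_spec or PhantomSpec()
    out = Path(out_dir)
    patients = []
    for i, row in cohort.reset_index(drop=True).iterrows():
        spec = base
        for tissue in TISSUE_CLASSES:
            spec = spec.with_truth(
                tissue,
                ps_per_min=float(row[f"ps_{tissue.lower()}"]) / 1e4,
                vp_frac=float(row[f"vp_{tissue.lower()}"]) / 1e2,
            )
        spec = replace(spec, hct=float(row["hct"]), noise_sd=noise_sd,
                       seed=seed + i)
        entry = write_phantom(generate_phantom(spec),
                              out / "patients" / str(row["patient_id"]))
        entry["id"] = str(row["patient_id"])
        patients.append(entry)
    cohort_csv = out / "cohort.csv"
    cohort.to_csv(cohort_csv, index=False)
    config = RunConfig(out_dir=str(out), patients=patients,
                       cohort_csv=str(cohort_csv),
                       acquisition=base.acquisition, seed=seed)
    config.to_yaml(out / "config.yaml")
    return config


def _fit_rows(result) -> list[dict]:
    rows = []
    for tissue, fit in result.fits.items():
        ps_ci = fit.ps_ci_e4_per_min
        vp_ci = fit.vp_ci_e2
        rows.append({
            "patient_id": result.patient_id,
            "tissue": tissue,
            "ps_e4_per_min": fit.ps_e4_per_min,
            "ps_ci_low": ps_ci[0],
            "ps_ci_high": ps_ci[1],
            "vp_e2": fit.vp_e2,
            "vp_ci_low": vp_ci[0],
            "vp_ci_high": vp_ci[1],
            "slope_pct_per_min": result.slopes_pct_per_min.get(tissue),
            "t10_ms": result.t10_ms.get(tissue),
            "n_frames_used": fit.n_frames_used,
            "residual_rms_mM": fit.residual_rms_mM,
            "r_squared": fit.r_squared,
            "n_clamped": result.qc["clamped_frames"].get(tissue, 0),
        })
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by a :class:`RunConfig`.

    Writes ``results.csv`` (per patient x tissue fits), ``cohort_stats.csv``
    (association models for every tissue x parameter x burden metric with a
    complete outcome column), ``qc.json`` and ``pipeline.log`` under
    ``config.out_dir``. Per-patient failures are logged and skipped; returns
    a summary dict. Re-running with the same config reproduces the outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    cohort = None
    if config.cohort_csv:
        cohort = pd.read_csv(config.cohort_csv)
        cohort["patient_id"] = cohort["patient_id"].astype(str)

    rows, qc, failures = [], {}, []
    try:
        for entry in config.patients:
            pid = str(entry["id"])
            try:
                series = read_dynamic_series(
                    entry["series"], config.acquisition.frame_interval_s,
                    config.n_baseline)
                vfa_low = read_volume(entry["vfa_low"])
                vfa_high = read_volume(entry["vfa_high"])
                vein = read_mask(entry["vein_mask"])
                masks = {t: read_mask(p)
                         for t, p in entry.get("masks", {}).items()}
                hct = None
                if cohort is not None and "hct" in cohort.columns:
                    match = cohort.loc[cohort["patient_id"] == pid, "hct"]
                    if len(match):
                        hct = float(match.iloc[0])
                result = run_patient(
                    series, vfa_low, vfa_high, masks, vein,
                    hct if hct is not None else config.hct_default,
                    config.acquisition, patient_id=pid,
                    exclude_n_early=config.exclude_n_early,
                    blood_t10_ms=config.blood_t10_ms)
                rows.extend(_fit_rows(result))
                qc[pid] = result.qc
                log.info("patient %s done (%d tissues)", pid, len(result.fits))
            except Exception as exc:  # per-patient failure: log and continue
                failures.append(pid)
                qc[pid] = {"error": str(exc)}
                log.warning("patient %s failed: %s", pid, exc)

        results = pd.DataFrame(rows)
        results.to_csv(out / "results.csv", index=False)

        stats_rows = []
        if cohort is not None and not results.empty:
            wide = results.pivot(index="patient_id", columns="tissue")
            # fitted outcomes replace any generator outcome columns
            kin_cols = [c for c in cohort.columns
                        if c.split("_")[0] in ("ps", "vp")]
            merged = cohort.drop(columns=kin_cols).set_index("patient_id").join(
                pd.concat(
                    {f"{p}_{t.lower()}": wide[("ps_e4_per_min" if p == "ps"
                                               else "vp_e2")][t]
                     for p in ("ps", "vp") for t in TISSUE_CLASSES
                     if t in wide["ps_e4_per_min"].columns},
                    axis=1,
                )
            ).reset_index()
            for param in ("ps", "vp"):
                for tissue in TISSUE_CLASSES:
                    col = f"{param}_{tissue.lower()}"
                    if col not in merged.columns:
                        continue
                    for burden in config.burden_metrics:
                        try:
                            m = fit_association_model(merged, col, burden)
                        except (ValueError, KeyError) as exc:
                            log.warning("model %s/%s skipped: %s",
                                        col, burden, exc)
                            continue
                        for pred, r in m.table.iterrows():
                            stats_rows.append({
                                "tissue": tissue, "parameter": param,
                                "burden_metric": burden, "predictor": pred,
                                "B": r["B"], "ci_low": r["ci_low"],
                                "ci_high": r["ci_high"], "p": r["p"],
                                "vif": r["vif"], "n": m.n_used,
                            })
        pd.DataFrame(stats_rows).to_csv(out / "cohort_stats.csv", index=False)

        with open(out / "qc.json", "w") as fh:
            json.dump({"patients": qc, "failed": failures}, fh, indent=2,
                      default=str)
    finally:
        log.removeHandler(handler)
        handler.close()

    return {"n_patients": len(config.patients), "n_failed": len(failures),
            "results_csv": str(out / "results.csv"),
            "cohort_stats_csv": str(out / "cohort_stats.csv"),
            "qc_json": str(out / "qc.json")}
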