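"""End-to-end reproduction driver.

Chains the Monte Carlo sweeps, detection-limit model, robustness analyses,
and synthetic phantom runs into one pass that writes tidy CSV tables (and
a machine-readable JSON summary) for:

- midline sensitivity depth profiles per wavelength x SDS, with the
  depth-of-maximum and normalized-maximum summaries;
- peak-to-noise contrast curves per SDS with maximum detection depths
  (calibrated at the NIR phantom anchor);
- optical-property (+-50% mu_a/mu_s) and cell-brightness (+-50%)
  robustness tables;
- laser-safety irradiance arithmetic for the configured power/spot;
- a synthetic flow-phantom depth sweep with matched detection counts.

Use a reduced ``n_photons`` in the configuration for desk-scale runs; the
tables are the same, only noisier.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .contrast import (
    DetectionModel,
    brightness_perturbation_sweep,
    calibrate_eta_cell,
    contrast_curve,
    irradiance_check,
    max_detection_depth,
    property_perturbation_sweep,
    sds_argmax_at_depth,
    sds_best_median,
)
from .io import save_table
from .jacobian import (
    depth_of_max_sensitivity,
    midline_depth_profile,
    normalize_profiles,
    sds_sweep,
)
from .pipeline import detect
from .synth import FlowPhantomConfig, synthesize_trace
from .tissue_optics import MCConfig, VoxelVolume

STAGES = (
    "sensitivity_sweep",
    "contrast_curves",
    "perturbations",
    "irradiance",
    "phantom_sweep",
    "summary",
)


def reproduce(config: RunConfig, dry_run: bool = False, out_dir: str | Path | None = None):
    """Run every stage and write the report bundle; returns the summary dict.

    With ``dry_run=True`` no computation happens; the stage plan is
    returned instead.
    """
    if dry_run:
        return {"plan": list(STAGES)}
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    meta = {"config_hash": chash, "seed": config.seed}
    volume = VoxelVolume((config.extent_mm,) * 3, config.voxel_size_mm)
    mc = MCConfig(
        n_photons=config.n_photons, time_gate_ns=config.time_gate_ns, seed=config.seed
    )
    summary: dict = {"config_hash": chash, "package_version": __version__}

    # --- stage 1: sensitivity sweeps -----------------------------------
    maps = {}
    for wl in config.wavelengths:
        maps[wl] = sds_sweep(wl, config.sds_mm, volume, mc)
    profiles = {
        (wl, s): midline_depth_profile(maps[wl][s])
        for wl in config.wavelengths
        for s in maps[wl]
    }
    normed = normalize_profiles(list(profiles.values()))
    rows = []
    for prof in normed:
        for depth, val in zip(prof.depths, prof.values):
            rows.append(
                dict(
                    wavelength_nm=prof.wavelength_nm,
                    sds_mm=prof.sds_mm,
                    depth_mm=depth,
                    W_normalized=val,
                )
            )
    save_table(pd.DataFrame(rows), out / "sensitivity_profiles.csv", meta)
    rows = []
    for (wl, s), prof in profiles.items():
        rows.append(
            dict(
                wavelength_nm=prof.wavelength_nm,
                sds_mm=s,
                depth_of_max_mm=depth_of_max_sensitivity(prof),
                midline_max=float(prof.values.max()),
            )
        )
    save_table(pd.DataFrame(rows), out / "sensitivity_summary.csv", meta)

    # --- stage 2: contrast curves with calibrated model ----------------
    anchor_map = maps[config.calibration_wavelength][float(config.calibration_sds_mm)]
    model = calibrate_eta_cell(
        anchor_map,
        DetectionModel(
            noise_fraction=config.noise_fraction,
            baseline_fraction=config.baseline_fraction,
            threshold_multiple=config.threshold_multiple,
        ),
        config.calibration_depth_mm,
    )
    summary["eta_cell_calibrated"] = model.eta_cell
    summary["snr_floor_db"] = model.snr_floor_db
    rows = []
    curves = {}
    for wl in config.wavelengths:
        curves[wl] = {s: contrast_curve(m, model) for s, m in maps[wl].items()}
        for s, c in curves[wl].items():
            d = max_detection_depth(c, model)
            rows.append(dict(wavelength_nm=c.wavelength_nm, sds_mm=s, max_depth_mm=d))
    save_table(pd.DataFrame(rows), out / "detection_depths.csv", meta)
    rows = []
    for wl in config.wavelengths:
        for s, c in curves[wl].items():
            for depth, v in zip(c.depths, c.snr_db):
                rows.append(
                    dict(
                        wavelength_nm=c.wavelength_nm,
                        sds_mm=s,
                        depth_mm=depth,
                        snr_db=v if np.isfinite(v) else np.nan,
                    )
                )
    save_table(pd.DataFrame(rows), out / "contrast_curves.csv", meta)
    nir = curves[config.calibration_wavelength]
    small = {s: c for s, c in nir.items() if s <= 5.0}
    if len(small) >= 2:
        summary["sds_argmax_3mm"] = sds_argmax_at_depth(small, 3.0, config.voxel_size_mm)
        summary["sds_best_median_2_4mm"] = sds_best_median(
            small, (2.0, 4.0), voxel_mm=config.voxel_size_mm
        )

    # --- stage 3: robustness -------------------------------------------
    pert_sds = [s for s in (0.3, 3.0) if s in maps[config.calibration_wavelength]]
    pp = property_perturbation_sweep(
        config.calibration_wavelength,
        model,
        sds_list=pert_sds,
        volume=volume,
        config=mc,
        baseline_maps={s: maps[config.calibration_wavelength][s] for s in pert_sds},
    )
    save_table(pp, out / "property_perturbations.csv", meta)
    bp = brightness_perturbation_sweep(model, {s: nir[s] for s in pert_sds})
    save_table(bp, out / "brightness_perturbations.csv", meta)
    summary["max_abs_delta_depth_properties_mm"] = float(pp.delta_mm.abs().max())
    summary["max_abs_delta_depth_brightness_mm"] = float(bp.delta_mm.abs().max())

    # --- stage 4: irradiance -------------------------------------------
    irr, ok = irradiance_check(config.laser_power_mw, config.spot_diameter_mm)
    irr1, ok1 = irradiance_check(config.laser_power_mw, 1.0)
    save_table(
        pd.DataFrame(
            [
                dict(power_mw=config.laser_power_mw, spot_diameter_mm=config.spot_diameter_mm,
                     irradiance_mw_cm2=irr, iec_compliant=ok),
                dict(power_mw=config.laser_power_mw, spot_diameter_mm=1.0,
                     irradiance_mw_cm2=irr1, iec_compliant=ok1),
            ]
        ),
        out / "irradiance.csv",
        meta,
    )
    summary["irradiance_mw_cm2"] = irr
    summary["irradiance_compliant"] = bool(ok)

    # --- stage 5: synthetic phantom depth sweep ------------------------
    rows = []
    for wl in config.wavelengths:
        wl_model = model
        smap = maps[wl].get(float(config.calibration_sds_mm))
        if smap is None:
            continue
        for depth in config.phantom_depths_mm:
            fc = FlowPhantomConfig(
                concentration_per_ml=config.phantom_concentration_per_ml,
                flow_rate_ul_min=config.phantom_flow_rate_ul_min,
                vessel_depth_mm=depth,
                duration_s=config.phantom_duration_s,
                sampling_rate_hz=config.sampling_rate_hz,
                seed=config.seed + int(depth * 100),
            )
            tr = synthesize_trace(smap, wl_model, fc)
            matches, per_ch = detect(tr)
            rows.append(
                dict(
                    wavelength_nm=smap.wavelength_nm,
                    sds_mm=smap.sds,
                    depth_mm=depth,
                    true_events=len(tr.events),
                    matched_detections=len(matches),
                    rate_per_min=len(matches) / tr.duration_min,
                )
            )
    phantom = pd.DataFrame(rows)
    save_table(phantom, out / "phantom_counts.csv", meta)

    # --- stage 6: summary ----------------------------------------------
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
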