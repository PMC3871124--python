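"""End-to-end reproduction of the package's headline results.

Runs every stage on synthetic inputs with pinned seeds and checks the
model-level claims: series/finite-difference agreement, threshold
coverage at 4 mm, the exact initial condition, secretion-source extents,
reporter calibration and timing, viability recovery, classifier
self-consistency and the scan round trip.  Used by the ``reproduce`` CLI
command.
"""

from __future__ import annotations

import math
from typing import Any

import numpy as np

from . import classify, response, scans, synth
from .config import RunConfig, config_hash
from .diffusion import (
    SecretionSource,
    calibrate_secretion_rate,
    fd_reference_solver,
    induction_extent,
    step_source_concentration,
)

__all__ = ["run_reproduce"]


def _series_vs_fd(cfg: RunConfig) -> dict[str, Any]:
    geom, tp = cfg.geometry(), cfg.transport()
    h, c0 = geom.source_extent_h, tp.c0_initial
    step_ic = lambda x: np.where(x < h, c0, np.where(x == h, 0.5 * c0, 0.0))
    times = [600.0, 3600.0, 21600.0]
    fld = fd_reference_solver(
        geom, tp.d_effective, step_ic, None, max(times),
        grid_spacing=0.05, time_step=1.0, save_times=times,
    )
    sup = 0.0
    for i, t in enumerate(fld.times):
        ser = step_source_concentration(fld.positions, t, geom, tp)
        sup = max(sup, float(np.abs(ser - fld.values[i]).max()))
    xs = np.linspace(0.0, geom.domain_length_l, 2001)
    mass_err = 0.0
    for t in times:
        mass = np.trapezoid(step_source_concentration(xs, t, geom, tp), xs)
        mass_err = max(mass_err, abs(mass - c0 * h) / (c0 * h))
    return {
        "sup_norm_diff_uM": sup,
        "mass_rel_err": mass_err,
        "pass": bool(sup < 1e-3 * c0 and mass_err < 1e-3),
    }


def _threshold_coverage(cfg: RunConfig) -> dict[str, Any]:
    geom, tp = cfg.geometry(), cfg.transport()
    thr_nM = cfg["response"]["induction_threshold_nM"]
    c_nM = step_source_concentration(geom.source_extent_h + 4.0, 21600.0, geom, tp) * 1e3
    c0_back = step_source_concentration(2.5, 1e-3, geom, tp)
    return {
        "conc_4mm_6h_nM": float(c_nM),
        "initial_condition_uM": float(c0_back),
        "pass": bool(c_nM >= thr_nM and abs(c0_back - tp.c0_initial) <= 1e-6 * tp.c0_initial),
    }


def _secretion_extents(cfg: RunConfig) -> dict[str, Any]:
    geom, tp = cfg.geometry(), cfg.transport()
    sec = cfg["source"]["secretion"]
    q = sec["per_od_rate"]
    if q is None:
        q = calibrate_secretion_rate(
            geom, tp, sec["reference_c0_uM"], sec["reference_od"],
            sec["reference_time_h"] * 3600.0,
        )
    thr_uM = cfg["response"]["induction_threshold_nM"] / 1e3
    extents = {}
    for od in cfg["od_levels"]:
        src = SecretionSource(od600=od, per_od_rate=q)
        extents[str(od)] = induction_extent(21600.0, thr_uM, geom, tp, source=src)
    vals = list(extents.values())
    return {
        "per_od_rate_uM_per_s": q,
        "extent_mm_by_od": extents,
        "pass": bool(vals[0] >= 1.0 and all(b >= a for a, b in zip(vals, vals[1:]))),
    }


def _reporter_timing(cfg: RunConfig) -> dict[str, Any]:
    geom, tp = cfg.geometry(), cfg.transport()
    dose, rep = cfg.dose(), cfg.reporter()
    fold20 = response.promoter_fold(20.0, math.inf, rep, dose)

    def conc_nM(t_min: float) -> float:
        return step_source_concentration(
            geom.source_extent_h + 0.5, max(t_min, 0.0) * 60.0, geom, tp
        ) * 1e3

    induced = response.reporter_timecourse(conc_nM, rep, dose, 360.0, 0.1)
    basal = response.reporter_timecourse(lambda t: 0.0, rep, dose, 360.0, 0.1)
    t_det = response.detection_time(
        induced, basal, rep.detection_factor, background=float(basal.mature[-1])
    )
    report = response.timescale_report(1.0, geom, tp, rep, dose)
    return {
        "fold_20min_saturating": float(fold20),
        "detection_time_h_at_0p5mm": t_det / 60.0,
        "reporter_limited_at_1mm": report.reporter_limited,
        "pass": bool(
            abs(fold20 - cfg["response"]["max_fold_at_20min"]) < 1e-9
            and t_det / 60.0 <= 4.0
            and report.reporter_limited
        ),
    }


def _viability(cfg: RunConfig, seed: int) -> dict[str, Any]:
    p = cfg["synth"]["survival_prob"]
    n_alive, n_dead = synth.synth_viability(1000, p, seed=seed)
    est = n_alive / 1000.0
    return {
        "survival_estimate_pct": est * 100.0,
        "pass": bool(abs(est - p) <= 0.03),
    }


def _classifier_suite(cfg: RunConfig, seed: int) -> dict[str, Any]:
    dose = cfg.dose()
    s = cfg["synth"]
    cl = cfg["classifier"]
    params = synth.MicroscopySynthParams(
        positions=cl["positions"],
        spacing_mm=cl["spacing_mm"],
        offset_mm=cl["offset_mm"],
        cells_per_position=s["cells_per_position"],
        image_size=(s["image_size_px"], s["image_size_px"]),
        noise_sd=s["noise_sd"],
        background_level=s["background_level"],
        foreground_level=s["foreground_level"],
        psf_sigma=s["psf_sigma_px"],
        survival_prob=s["survival_prob"],
        seed=seed,
    )
    cutoff_mm = 3.0
    distances = [params.offset_mm + i * params.spacing_mm for i in range(params.positions)]
    profile = []
    for d in distances:
        ps = max(0.0, 0.6 * (1.0 - d / cutoff_mm))
        pe = 0.2
        profile.append((1.0 - ps - pe, pe, ps))
    images, truth = synth.synth_phenotype_field(profile, params, dose)

    thresholds = cfg.thresholds()
    frames = []
    matched = 0
    confused = 0
    for pos, (bf, fl) in enumerate(images):
        cells = classify.measure_cells(
            bf, fl, pos, thresholds=thresholds,
            spacing_mm=params.spacing_mm, offset_mm=params.offset_mm,
        )
        frames.append(cells)
        tpos = truth[truth.position_index == pos]
        for _, rec in tpos.iterrows():
            d = np.hypot(cells.row - rec.row, cells.col - rec.col)
            if len(d) and d.min() <= 3.0:
                matched += 1
                if cells.iloc[int(np.argmin(d.values))].phenotype != rec.true_class:
                    confused += 1
    import pandas as pd

    all_cells = pd.concat(frames, ignore_index=True)
    prof = classify.spatial_profile(
        all_cells, range(params.positions), params.spacing_mm, params.offset_mm
    )
    extent = classify.shmoo_extent(prof, 0.05)
    # Truth extent: farthest position whose programmed shmoo fraction >= 0.05.
    truth_extent = max(
        (d for d, p in zip(distances, profile) if p[2] >= 0.05), default=0.0
    )
    recall = matched / len(truth)
    confusion = confused / matched if matched else 1.0
    return {
        "n_cells_truth": int(len(truth)),
        "segmentation_recall": recall,
        "class_confusion": confusion,
        "shmoo_extent_mm": extent,
        "shmoo_extent_truth_mm": truth_extent,
        "pass": bool(
            recall >= 0.95
            and confusion <= 0.05
            and abs(extent - truth_extent) <= 0.3 + 1e-9
        ),
    }


def _scan_round_trip(cfg: RunConfig, seed: int) -> dict[str, Any]:
    sc = cfg["scan"]
    curve = lambda d: np.exp(-d / 1.5)
    scan, truth = synth.synth_scan(
        curve, pixel_size_mm=sc["pixel_size_mm"], compartment_mm=sc["compartment_mm"],
        seed=seed,
    )
    raw = scans.plot_profile(scan)
    # constitutive-reference scan at the same settings
    ref_scan, _ = synth.synth_scan(
        lambda d: np.ones_like(d), pixel_size_mm=sc["pixel_size_mm"],
        compartment_mm=sc["compartment_mm"], seed=seed + 1,
    )
    ref_raw = scans.plot_profile(ref_scan)
    background = scans.estimate_background(ref_scan, (0, 8, 0, 8))
    reference = float(np.median(ref_raw.intensity))
    prof = scans.normalize_profile(raw, reference, background)
    ref_prof = scans.normalize_profile(ref_raw, reference, background)
    extent = scans.detection_extent(prof, sc["rel_threshold"])
    analytic = truth.distance_mm[truth.relative_intensity >= sc["rel_threshold"]].max()
    return {
        "extent_mm": float(extent),
        "analytic_extent_mm": float(analytic),
        "reference_max_relative": float(ref_prof.relative_intensity.max()),
        "pass": bool(
            abs(extent - analytic) <= sc["pixel_size_mm"] + 1e-9
            and abs(ref_prof.relative_intensity.max() - 1.0) <= 0.02
        ),
    }


def run_reproduce(cfg: RunConfig, seed: int | None = None) -> dict[str, Any]:
    """Run all reproduction experiments; returns a serializable report."""
    seed = cfg["seed"] if seed is None else seed
    stages = {
        "series_vs_fd": _series_vs_fd(cfg),
        "threshold_coverage": _threshold_coverage(cfg),
        "secretion_extents": _secretion_extents(cfg),
        "reporter_timing": _reporter_timing(cfg),
        "viability": _viability(cfg, seed),
        "classifier": _classifier_suite(cfg, seed + 1),
        "scan_round_trip": _scan_round_trip(cfg, seed + 2),
    }
    return {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stages": stages,
        "all_pass": all(s["pass"] for s in stages.values()),
    }
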