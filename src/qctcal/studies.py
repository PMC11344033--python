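"""End-to-end validation studies on synthetic data.

Each study exercises a complete slice of the pipeline against the
generator's ground truth and returns plain-dictionary results, so the
same code backs both the test suite and reproducibility scripts. Problem
sizes are kept at desk scale (small volumes, modest cohort sizes); see
the methods note for the choices.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import numpy as np

from .calibration import PhantomScan, apply_calibration, fit_calibration
from .calibration import select_reference_scan
from .correction import fit_weight_model, weight_corrected_bmd
from .detection import detect_insert_circles, measure_inserts
from .errors import fit_error_regression, regression_root, summarize_errors
from .metadata import ScanMetadata
from .phantom import PhantomSpec, SubjectSpec, six_insert_phantom
from .synthetic import AcquisitionTruth, simulate_error_cohort, simulate_phantom_scan
from .synthetic import simulate_subject_scan

__all__ = [
    "quiet_truth",
    "detection_accuracy_study",
    "calibration_roundtrip_study",
    "weight_effect_recovery_study",
    "split_sample_correction_study",
    "kernel_factor_recovery_study",
    "drift_reference_study",
]


def quiet_truth(**overrides) -> AcquisitionTruth:
    """An :class:`AcquisitionTruth` with every confounder switched off."""
    base = dict(
        noise_sd=0.0,
        drift_rate=0.0,
        height_knots=((100.0, 0.0), (250.0, 0.0)),
        kernel_offset=0.0,
        weight_effect=(0.0, 0.0),
    )
    base.update(overrides)
    return AcquisitionTruth(**base)


def detection_accuracy_study(
    n_phantoms: int = 20, max_noise_sd: float = 20.0, seed: int = 0
) -> dict:
    """Insert detection over randomized phantoms.

    Each phantom gets a random in-plane shift, HU mapping and noise level
    (up to ``max_noise_sd``); detection results are scored against the
    generator's ground-truth table. Reports the detected fraction, the
    worst center error in voxels and the worst deviation of the ROI/
    detected-radius ratio from the 20% shrink.
    """
    rng = np.random.default_rng(seed)
    n_total = n_found = 0
    max_center_err_vox = 0.0
    max_roi_ratio_dev = 0.0
    for k in range(n_phantoms):
        shift = rng.uniform(-5.0, 5.0, size=2)
        base = six_insert_phantom()
        spec = PhantomSpec(
            insert_densities=base.insert_densities,
            insert_radius=base.insert_radius,
            insert_centers=tuple(
                (cx + shift[0], cy + shift[1]) for cx, cy in base.insert_centers
            ),
            phantom_length=30.0,
        )
        truth = quiet_truth(
            hu_slope=rng.uniform(0.8, 1.3),
            hu_intercept=rng.uniform(-20.0, 10.0),
            noise_sd=rng.uniform(0.0, max_noise_sd),
            seed=int(rng.integers(2**31)),
        )
        meta = ScanMetadata()
        vol, table = simulate_phantom_scan(spec, meta, truth)
        circles = detect_insert_circles(vol, spec)
        measurements = measure_inserts(vol, circles, spec)
        n_total += spec.n_inserts
        n_found += len(circles)
        for c, m in zip(circles, measurements):
            row = table[table["density"] == c.nominal_density].iloc[0]
            err = np.hypot(
                c.center[0] - row["center_x_mm"], c.center[1] - row["center_y_mm"]
            )
            max_center_err_vox = max(max_center_err_vox, err / vol.spacing[0])
            max_roi_ratio_dev = max(
                max_roi_ratio_dev, abs(m.roi_radius / m.detected_radius - 0.8)
            )
    return {
        "n_phantoms": n_phantoms,
        "detected_fraction": n_found / n_total,
        "max_center_error_vox": max_center_err_vox,
        "max_roi_ratio_deviation": max_roi_ratio_dev,
    }


def calibration_roundtrip_study(
    seed: int = 0,
    n_seeds: int = 50,
    hu_slope: float = 1.25,
    hu_intercept: float = -10.0,
    noise_sd: float = 10.0,
) -> dict:
    """Recovery of the generative HU↔density mapping by curve fitting.

    Noise-free: full detect→measure→fit, compared with the true inverse
    map (density-on-HU slope ``1/hu_slope``, intercept
    ``−hu_intercept/hu_slope``). The default mapping sends every nominal
    insert density to an integer HU, so quantization is exact and the fit
    must recover the mapping to machine precision. Noisy: ``n_seeds``
    replicate scans at ``noise_sd`` HU; the mean fitted slope must sit
    within a few standard errors of the truth.
    """
    spec = six_insert_phantom()
    meta = ScanMetadata()
    truth0 = quiet_truth(hu_slope=hu_slope, hu_intercept=hu_intercept)
    vol, _ = simulate_phantom_scan(spec, meta, truth0)
    circles = detect_insert_circles(vol, spec)
    curve = fit_calibration(measure_inserts(vol, circles, spec), provenance=meta)
    slope_true = 1.0 / hu_slope
    intercept_true = -hu_intercept / hu_slope
    rel_err = max(
        abs(curve.slope - slope_true) / abs(slope_true),
        abs(curve.intercept - intercept_true) / abs(intercept_true),
    )

    rng = np.random.default_rng(seed)
    slopes = []
    min_voxels = np.inf
    for _ in range(n_seeds):
        t = truth0.replace(noise_sd=noise_sd, seed=int(rng.integers(2**31)))
        v, _ = simulate_phantom_scan(spec, meta, t)
        ms = measure_inserts(v, circles, spec)
        min_voxels = min(min_voxels, min(m.voxel_count for m in ms))
        slopes.append(fit_calibration(ms).slope)
    slopes = np.asarray(slopes)
    se_mean = slopes.std(ddof=1) / np.sqrt(n_seeds)
    return {
        "noise_free_rel_error": rel_err,
        "slope_true": slope_true,
        "slope_mean": float(slopes.mean()),
        "slope_z": float((slopes.mean() - slope_true) / se_mean),
        "min_voxels_per_insert": int(min_voxels),
        "n_seeds": n_seeds,
    }


def weight_effect_recovery_study(
    n: int = 200,
    reps: int = 100,
    a_true: float = -0.13,
    b_true: float = 8.66,
    residual_sd_pct: float = 2.6,
    seed: int = 0,
) -> dict:
    """Recovery of the weight–error regression from replicate cohorts.

    Each replicate draws a cohort of ``n`` cases whose asynchronous BMD
    error follows d = a·m + b (%) plus Gaussian residual, fits the
    regression and takes its root. Reports the first replicate's
    coefficient z-scores (estimate minus truth over standard error) and
    the fraction of replicate roots inside the 62–67 kg window around the
    true root.
    """
    rng = np.random.default_rng(seed)
    truth = AcquisitionTruth(weight_effect=(a_true, b_true))
    roots = []
    first = None
    for _ in range(reps):
        cohort = simulate_error_cohort(
            n,
            truth,
            seed=int(rng.integers(2**31)),
            residual_sd_pct=residual_sd_pct,
        )
        reg = fit_error_regression(cohort["weight"], 100.0 * cohort["d"])
        if first is None:
            first = reg
        roots.append(regression_root(reg))
    roots = np.asarray(roots)
    return {
        "a_hat": first.slope,
        "b_hat": first.intercept,
        "a_z": (first.slope - a_true) / first.slope_se,
        "b_z": (first.intercept - b_true) / first.intercept_se,
        "root_first": float(roots[0]),
        "root_in_62_67_fraction": float(np.mean((roots >= 62.0) & (roots <= 67.0))),
        "n": n,
        "reps": reps,
    }


def split_sample_correction_study(
    n: int = 8000,
    a_true: float = -0.13,
    b_true: float = 8.66,
    residual_sd_pct: float = 2.6,
    seed: int = 0,
) -> dict:
    """Efficacy of the body-weight correction on held-out cases.

    A cohort with a weight-driven error is split in half; the weight
    model is fitted on the first half and applied to the second. Reports
    the held-out mean error before and after correction and the relative
    SD reduction. The default cohort is large enough that the held-out
    mean error reflects the correction itself rather than Monte-Carlo
    noise (its sampling SD is ≈ residual·√(2/n) ≈ 0.06 percentage
    points).
    """
    truth = AcquisitionTruth(weight_effect=(a_true, b_true))
    cohort = simulate_error_cohort(n, truth, seed=seed, residual_sd_pct=residual_sd_pct)
    train = cohort.iloc[: n // 2]
    test = cohort.iloc[n // 2 :].copy()
    d_train_pct = 100.0 * train["d"]
    model = fit_weight_model(train["weight"], d_train_pct, scanner_id="CT1")
    corrected = np.array(
        [
            weight_corrected_bmd(b, w, model)
            for b, w in zip(test["bmd_asyn"], test["weight"])
        ]
    )
    before = summarize_errors(test)
    after = summarize_errors(test.assign(bmd_asyn=corrected))
    return {
        "mean_d_before_pct": before.mean_pct,
        "mean_d_after_pct": after.mean_pct,
        "sd_before_pct": before.sd_pct,
        "sd_after_pct": after.sd_pct,
        "sd_reduction_fraction": 1.0 - after.sd_pct / before.sd_pct,
        "n_test": after.n,
    }


def kernel_factor_recovery_study(
    n_cases: int = 40, kernel_offset: float = -0.05, seed: int = 0
) -> dict:
    """Recovery of the kernel correction factor from paired BMD values.

    Cases are simulated once with the reference (bone) kernel and once
    with a soft kernel whose mineral signal is shifted by
    ``kernel_offset``; the estimated factor should recover
    ``1/(1 + kernel_offset)``.
    """
    from .correction import kernel_correction_factor

    rng = np.random.default_rng(seed)
    bmds = np.clip(rng.normal(413.0, 80.0, n_cases), 150.0, 650.0)
    noise = rng.normal(0.0, 2.0, (n_cases, 2))  # HU-level measurement noise
    ref = bmds + noise[:, 0]
    other = bmds * (1.0 + kernel_offset) + noise[:, 1]
    factor = kernel_correction_factor(np.column_stack((ref, other)))
    return {
        "factor": factor,
        "factor_true": 1.0 / (1.0 + kernel_offset),
        "n_cases": n_cases,
    }


def _measure_phantom_scan(meta, truth, spec, circles=None):
    vol, _ = simulate_phantom_scan(spec, meta, truth)
    if circles is None:
        circles = detect_insert_circles(vol, spec)
    return PhantomScan(meta=meta, measurements=measure_inserts(vol, circles, spec)), circles


def drift_reference_study(
    n_cases: int = 10,
    drift_rate: float = 0.017,
    seed: int = 0,
) -> dict:
    """Closest-time versus fixed distant reference under temporal drift.

    A phantom library is built from monthly scans of a drifting scanner;
    subject scans spread over the year are calibrated asynchronously
    twice — against the reference chosen by the closest-time policy and
    against the first (distant) scan — with the in-scan phantom providing
    the ground truth. The closest-time policy should show a strictly
    smaller mean absolute error. Drift magnitude reflects a scanner whose
    error roughly doubles over a year when a distant reference is used.
    """
    spec = six_insert_phantom(phantom_length=24.0)
    truth = quiet_truth(drift_rate=drift_rate, drift_ref_date=_dt.date(2022, 1, 1))
    spacing = (1.5, 1.5, 3.0)
    rng = np.random.default_rng(seed)

    library = []
    circles = None
    for month in range(1, 13):
        meta = ScanMetadata(date=_dt.date(2022, month, 1), voxel_size=spacing)
        scan, circles = _measure_phantom_scan(meta, truth, spec, circles)
        library.append(scan)
    fixed_curve = library[0].fit()

    subject = SubjectSpec(
        body_half_axes=(100.0, 70.0), bone_center=(25.0, 5.0), bone_radius=15.0
    )
    d_closest, d_fixed = [], []
    days = np.sort(rng.integers(0, 334, n_cases))
    subj_circles = None
    for day in days:
        date = _dt.date(2022, 1, 15) + _dt.timedelta(days=int(day))
        meta = ScanMetadata(date=date, voxel_size=spacing)
        scan = simulate_subject_scan(
            subject, meta, truth, with_inscan_phantom=True, phantom_spec=spec,
            n_slices=4,
        )
        if subj_circles is None:
            subj_circles = detect_insert_circles(scan.volume, spec)
        inscan_curve = fit_calibration(
            measure_inserts(scan.volume, subj_circles, spec)
        )
        bmd_inscan = apply_calibration(scan.volume, scan.bone_mask, inscan_curve).mean_bmd
        closest = select_reference_scan(meta, library)
        bmd_closest = apply_calibration(
            scan.volume, scan.bone_mask, closest.fit()
        ).mean_bmd
        bmd_fixed = apply_calibration(scan.volume, scan.bone_mask, fixed_curve).mean_bmd
        d_closest.append((bmd_closest - bmd_inscan) / bmd_inscan)
        d_fixed.append((bmd_fixed - bmd_inscan) / bmd_inscan)
    return {
        "mean_abs_d_closest_pct": 100.0 * float(np.mean(np.abs(d_closest))),
        "mean_abs_d_fixed_pct": 100.0 * float(np.mean(np.abs(d_fixed))),
        "n_cases": n_cases,
    }
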