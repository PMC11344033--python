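"""Generator-level oracles: the simulated HU values must follow the
declared generative model exactly, and the confounders must act
independently."""

import datetime as dt

import numpy as np
import pytest

from qctcal import (
    CalibrationCurve,
    PhantomSpec,
    ScanMetadata,
    SubjectSpec,
    apply_calibration,
    fit_calibration,
    simulate_phantom_scan,
    simulate_subject_scan,
    simulate_error_cohort,
    six_insert_phantom,
)
from qctcal.synthetic import AcquisitionTruth
from qctcal.studies import quiet_truth

from conftest import measure_from_truth

DENSITIES = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0)


@pytest.mark.parametrize("intercept", [0.0, -10.0])
def test_insert_means_follow_affine_map(phantom6, meta, intercept):
    """Noise-free insert means equal slope·density + intercept exactly."""
    truth = quiet_truth(hu_intercept=intercept)
    vol, table = simulate_phantom_scan(phantom6, meta, truth)
    ms = measure_from_truth(vol, table, phantom6)
    for m, rho in zip(ms, DENSITIES):
        assert m.mean_hu == pytest.approx(rho + intercept, abs=1e-9)
    np.testing.assert_allclose(table["hu_noise_free"], np.array(DENSITIES) + intercept)


def test_noisy_means_within_statistical_bound(phantom6, meta):
    """With sd-10 noise the sample mean stays within 4·sd/√N of truth."""
    truth = quiet_truth(noise_sd=10.0, seed=123)
    vol, table = simulate_phantom_scan(phantom6, meta, truth)
    for m, (_, row) in zip(measure_from_truth(vol, table, phantom6), table.iterrows()):
        bound = 4 * 10.0 / np.sqrt(m.voxel_count) + 0.5  # + HU quantization
        assert abs(m.mean_hu - row["hu_noise_free"]) < bound


def test_bit_reproducibility(phantom6, meta):
    truth = AcquisitionTruth(seed=42)
    vol1, _ = simulate_phantom_scan(phantom6, meta, truth)
    vol2, _ = simulate_phantom_scan(phantom6, meta, truth)
    np.testing.assert_array_equal(vol1.voxels, vol2.voxels)


def test_linearity_doubling(meta):
    """Doubling densities doubles noise-free HU minus the intercept."""
    truth = quiet_truth(hu_intercept=-10.0)
    spec1 = PhantomSpec(insert_densities=(100.0, 200.0, 400.0))
    spec2 = PhantomSpec(insert_densities=(200.0, 400.0, 800.0))
    _, t1 = simulate_phantom_scan(spec1, meta, truth)
    _, t2 = simulate_phantom_scan(spec2, meta, truth)
    np.testing.assert_allclose(
        t2["hu_noise_free"] + 10.0, 2 * (t1["hu_noise_free"] + 10.0)
    )


def test_confounder_isolation_drift_vs_height(phantom6):
    """Temporal drift changes the date dependence of insert HU but leaves
    the height dependence untouched."""
    knots = ((100.0, 5.0), (160.0, 0.0), (250.0, -8.0))
    for drift in (0.0, 0.05):
        truth = quiet_truth(height_knots=knots, drift_rate=drift)
        date = dt.date(2023, 1, 1)
        hus = {}
        for h in (100.0, 250.0):
            meta = ScanMetadata(table_height=h, date=date)
            _, table = simulate_phantom_scan(phantom6, meta, truth)
            hus[h] = table["hu_noise_free"].to_numpy()
        # additive height offset: difference across heights is constant
        np.testing.assert_allclose(hus[100.0] - hus[250.0], 13.0, atol=1e-9)


def test_height_out_of_range_rejected(phantom6, truth_off):
    meta = ScanMetadata(table_height=300.0)
    with pytest.raises(ValueError, match="height out of simulated range"):
        simulate_phantom_scan(phantom6, meta, truth_off)


def test_invalid_phantom_specs_rejected():
    with pytest.raises(ValueError, match="increasing"):
        PhantomSpec(insert_densities=(100.0, 100.0))
    with pytest.raises(ValueError, match="separated"):
        PhantomSpec(
            insert_densities=(0.0, 100.0),
            insert_radius=9.0,
            insert_centers=((0.0, 0.0), (10.0, 0.0)),
        )
    with pytest.raises(ValueError):
        SubjectSpec(bone_center=(150.0, 0.0), bone_radius=30.0)


def test_weight_bias_anchor_value(meta):
    """78 kg with the (−0.13, 8.66) regression biases a 400 mg/cm³ bone to
    ≈394.08 mg/cm³ under asynchronous (unbiased-curve) calibration."""
    truth = quiet_truth(weight_effect=(-0.13, 8.66))
    subject = SubjectSpec(weight=78.0, true_bmd=400.0)
    scan = simulate_subject_scan(subject, meta, truth)
    identity = CalibrationCurve(slope=1.0, intercept=0.0, r_squared=1.0)
    res = apply_calibration(scan.volume, scan.bone_mask, identity)
    assert res.mean_bmd == pytest.approx(394.08, abs=0.51)  # HU quantization


def test_inscan_round_trip_recovers_true_bmd(phantom6, meta, truth_off):
    """Confounders off: calibrating with the in-scan phantom returns the
    subject's true density exactly (integer-exact mapping)."""
    subject = SubjectSpec(true_bmd=400.0)
    scan = simulate_subject_scan(
        subject, meta, truth_off, with_inscan_phantom=True, phantom_spec=phantom6
    )
    ms = measure_from_truth(scan.volume, scan.phantom_truth, phantom6)
    curve = fit_calibration(ms)
    res = apply_calibration(scan.volume, scan.bone_mask, curve)
    assert res.mean_bmd == pytest.approx(400.0, abs=1e-9)


def test_weight_at_root_makes_async_and_inscan_agree(phantom6, meta):
    """At the zero of the weight regression the bias term vanishes, so
    asynchronous and in-scan calibration coincide."""
    truth = quiet_truth(weight_effect=(-0.13, 8.66))
    subject = SubjectSpec(weight=8.66 / 0.13, true_bmd=400.0)
    scan = simulate_subject_scan(
        subject, meta, truth, with_inscan_phantom=True, phantom_spec=phantom6
    )
    pvol, ptable = simulate_phantom_scan(phantom6, meta, truth)
    async_curve = fit_calibration(measure_from_truth(pvol, ptable, phantom6))
    inscan_curve = fit_calibration(
        measure_from_truth(scan.volume, scan.phantom_truth, phantom6)
    )
    bmd_async = apply_calibration(scan.volume, scan.bone_mask, async_curve).mean_bmd
    bmd_inscan = apply_calibration(scan.volume, scan.bone_mask, inscan_curve).mean_bmd
    assert bmd_async == pytest.approx(bmd_inscan, abs=1e-9)


def test_masks_align_with_volume(meta, truth_off):
    scan = simulate_subject_scan(SubjectSpec(), meta, truth_off)
    assert scan.bone_mask.shape == scan.volume.voxels.shape
    assert scan.body_mask.shape == scan.volume.voxels.shape
    assert scan.bone_mask.sum() > 0
    assert np.all(scan.body_mask[scan.bone_mask])  # bone inside body


def test_error_cohort_is_consistent_and_deterministic():
    truth = AcquisitionTruth(weight_effect=(-0.13, 8.66))
    c1 = simulate_error_cohort(50, truth, seed=7)
    c2 = simulate_error_cohort(50, truth, seed=7)
    assert c1.equals(c2)
    np.testing.assert_allclose(
        c1["d"], (c1["bmd_asyn"] - c1["bmd_inscan"]) / c1["bmd_inscan"]
    )
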