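"""Calibration fitting, application, reference selection, interpolation."""

import datetime as dt
import random

import numpy as np
import pytest

from qctcal import (
    CalibrationCurve,
    CTVolume,
    ScanMetadata,
    apply_calibration,
    fit_calibration,
    height_interpolated_curve,
    select_reference_scan,
    simulate_phantom_scan,
    six_insert_phantom,
)
from qctcal.calibration import NoReferenceError, PhantomScan, VoltageMismatchError
from qctcal.detection import InsertMeasurement, detect_insert_circles, measure_inserts
from qctcal.studies import quiet_truth

from conftest import measure_from_truth


def make_measurements(hu_values, densities):
    return [
        InsertMeasurement(
            center=(0.0, 0.0),
            detected_radius=9.0,
            roi_radius=7.2,
            mean_hu=float(hu),
            voxel_count=100,
            slice_range=(0, 4),
            nominal_density=float(rho),
        )
        for hu, rho in zip(hu_values, densities)
    ]


DENS = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0)


class TestFit:
    def test_identity(self):
        curve = fit_calibration(make_measurements(DENS, DENS))
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_shifted_identity(self):
        hu = [10, 110, 210, 410, 610, 810]
        curve = fit_calibration(make_measurements(hu, DENS))
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(-10.0)

    def test_noisy_within_three_se(self):
        rng = np.random.default_rng(3)
        sd = 5.0
        hu = np.array(DENS) + rng.normal(0, sd, 6)
        curve = fit_calibration(make_measurements(hu, DENS))
        # regression of density on noisy HU: slope SE ≈ sd_resid-based bound
        se_slope = sd / np.sqrt(np.sum((np.array(DENS) - np.mean(DENS)) ** 2))
        assert abs(curve.slope - 1.0) < 3 * se_slope + 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration(make_measurements([100.0], [100.0]))
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration(make_measurements([100.0, 100.0], [100.0, 200.0]))


class TestApply:
    def test_identity_curve_returns_mean_hu(self):
        vol = CTVolume(np.full((2, 4, 4), 250, dtype=np.int32), (1, 1, 1))
        mask = np.zeros((2, 4, 4), dtype=bool)
        mask[:, 1:3, 1:3] = True
        res = apply_calibration(vol, mask, CalibrationCurve(1.0, 0.0, 1.0))
        assert res.mean_bmd == 250.0
        assert res.voxel_count == 8

    def test_empty_mask_rejected(self):
        vol = CTVolume(np.zeros((1, 2, 2), dtype=np.int32), (1, 1, 1))
        with pytest.raises(ValueError, match="empty ROI"):
            apply_calibration(vol, np.zeros((1, 2, 2), bool), CalibrationCurve(1, 0, 1))

    def test_grid_mismatch_rejected(self):
        vol = CTVolume(np.zeros((1, 2, 2), dtype=np.int32), (1, 1, 1))
        with pytest.raises(ValueError, match="mismatch"):
            apply_calibration(vol, np.ones((1, 3, 3), bool), CalibrationCurve(1, 0, 1))

    def test_affine_equivariance(self):
        """Rescaling HU by (g, o) and the curve by the inverse map leaves
        the BMD unchanged."""
        rng = np.random.default_rng(0)
        vox = rng.integers(0, 800, (3, 8, 8))
        g, o = 2, 100
        vol = CTVolume(vox, (1, 1, 1))
        vol2 = CTVolume(g * vox + o, (1, 1, 1))
        mask = np.ones(vox.shape, dtype=bool)
        curve = CalibrationCurve(0.9, -5.0, 1.0)
        curve2 = CalibrationCurve(curve.slope / g, curve.intercept - curve.slope * o / g, 1.0)
        r1 = apply_calibration(vol, mask, curve)
        r2 = apply_calibration(vol2, mask, curve2)
        assert r1.mean_bmd == pytest.approx(r2.mean_bmd, abs=1e-9)


def test_round_trip_recovers_generative_mapping(meta):
    """Detect → measure → fit on a noise-free phantom inverts the generative
    HU↔density map to machine precision (integer-exact mapping)."""
    spec = six_insert_phantom()
    truth = quiet_truth(hu_slope=1.25, hu_intercept=-10.0)
    vol, _ = simulate_phantom_scan(spec, meta, truth)
    circles = detect_insert_circles(vol, spec)
    curve = fit_calibration(measure_inserts(vol, circles, spec))
    assert curve.slope == pytest.approx(1 / 1.25, rel=1e-9)
    assert curve.intercept == pytest.approx(10.0 / 1.25, rel=1e-9)


def _scan(**kwargs):
    return PhantomScan(meta=ScanMetadata(**kwargs), measurements=[])


class TestReferenceSelection:
    def test_exact_match_chosen(self):
        target = _scan(scanner_id="CT1", voltage=120, kernel="bone", date=dt.date(2022, 3, 1))
        library = [_scan(scanner_id="CT1", voltage=140), target, _scan(scanner_id="CT2")]
        case = ScanMetadata(scanner_id="CT1", voltage=120, kernel="bone", date=dt.date(2022, 3, 1))
        assert select_reference_scan(case, library) is target

    def test_closest_time_wins(self):
        early = _scan(date=dt.date(2022, 1, 2))  # −30 d
        late = _scan(date=dt.date(2022, 2, 11))  # +10 d
        case = ScanMetadata(date=dt.date(2022, 2, 1))
        assert select_reference_scan(case, [early, late]) is late

    def test_voltage_mismatch_excludes_case(self):
        library = [_scan(voltage=140.0)]
        case = ScanMetadata(voltage=120.0)
        with pytest.raises(VoltageMismatchError, match="excluded"):
            select_reference_scan(case, library)

    def test_missing_scanner_rejected(self):
        with pytest.raises(NoReferenceError):
            select_reference_scan(ScanMetadata(scanner_id="CT9"), [_scan()])
        with pytest.raises(NoReferenceError):
            select_reference_scan(ScanMetadata(), [])

    def test_kernel_match_outranks_time(self):
        soft_near = _scan(kernel="soft", date=dt.date(2022, 1, 2))
        bone_far = _scan(kernel="bone", date=dt.date(2021, 6, 1))
        case = ScanMetadata(kernel="bone", date=dt.date(2022, 1, 1))
        assert select_reference_scan(case, [soft_near, bone_far]) is bone_far

    def test_date_tie_prefers_earlier(self):
        before = _scan(date=dt.date(2022, 1, 22))
        after = _scan(date=dt.date(2022, 2, 11))
        case = ScanMetadata(date=dt.date(2022, 2, 1))  # 10 d both sides
        assert select_reference_scan(case, [after, before]) is before

    def test_permutation_invariance(self):
        rng = random.Random(0)
        library = [
            _scan(date=dt.date(2022, m, d), kernel=k, protocol_id=p)
            for m in (1, 4, 7)
            for d in (1, 15)
            for k in ("bone", "soft")
            for p in ("A", "B")
        ]
        case = ScanMetadata(date=dt.date(2022, 5, 20), kernel="soft", protocol_id="B")
        chosen = select_reference_scan(case, library)
        for _ in range(10):
            rng.shuffle(library)
            assert select_reference_scan(case, library) is chosen


class TestHeightInterpolation:
    HEIGHTS = (100.0, 160.0, 250.0)

    def _series(self, offsets=(8.0, 0.0, -10.0)):
        return [
            (h, make_measurements(np.array(DENS) + off, DENS))
            for h, off in zip(self.HEIGHTS, offsets)
        ]

    def test_knot_exactness(self):
        series = self._series()
        for h, ms in series:
            direct = fit_calibration(ms)
            interp = height_interpolated_curve(series, h)
            assert interp.slope == pytest.approx(direct.slope, abs=1e-12)
            assert interp.intercept == pytest.approx(direct.intercept, abs=1e-12)

    def test_midpoint_is_arithmetic_mean(self):
        series = [
            (100.0, make_measurements([400.0, 600.0], [400.0, 600.0])),
            (200.0, make_measurements([420.0, 620.0], [400.0, 600.0])),
        ]
        curve = height_interpolated_curve(series, 150.0)
        # interpolated HU 410/610 → density = HU − 10
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(-10.0)

    def test_extrapolation_refused_and_clamped(self):
        series = self._series()
        with pytest.raises(ValueError, match="extrapolation refused"):
            height_interpolated_curve(series, 275.0)
        with pytest.warns(UserWarning, match="clamping"):
            clamped = height_interpolated_curve(series, 275.0, clamp=True)
        edge = height_interpolated_curve(series, 250.0)
        assert clamped.slope == pytest.approx(edge.slope)

    def test_piecewise_linear_in_target_height(self):
        """Between knots, the interpolated intercept varies linearly with
        target height (additive offsets shift the intercept only)."""
        series = self._series()
        hs = np.linspace(100.0, 160.0, 7)
        intercepts = np.array(
            [height_interpolated_curve(series, h).intercept for h in hs]
        )
        np.testing.assert_allclose(np.diff(intercepts, 2), 0.0, atol=1e-9)
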