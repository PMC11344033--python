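"""HU→BMD calibration: curve fitting, application, reference selection.

A calibration curve is an ordinary-least-squares fit of nominal insert
density (mg HA/cm³) on measured mean HU, so conversion is a single affine
map ``BMD = slope·HU + intercept``. Asynchronous calibration picks a
stored phantom scan by, in order: same scanner (mandatory), same voltage
(mandatory — cases without a voltage-matched reference are excluded),
most similar protocol, closest acquisition time. For table-height
personalization, per-insert HU values from phantom scans at several
heights are interpolated piecewise-linearly at the case's height and the
curve refit, which is exact at the measured heights.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detection import InsertMeasurement
from .metadata import ScanMetadata
from .volume import CTVolume

__all__ = [
    "CalibrationCurve",
    "BMDResult",
    "PhantomScan",
    "NoReferenceError",
    "VoltageMismatchError",
    "fit_calibration",
    "apply_calibration",
    "select_reference_scan",
    "height_interpolated_curve",
]


class NoReferenceError(LookupError):
    """No phantom scan exists for the case's scanner."""


class VoltageMismatchError(LookupError):
    """Excluded: no reference phantom scan matches the case voltage."""


@dataclass
class CalibrationCurve:
    """Affine HU→density map with fit quality and provenance."""

    slope: float  # (mg HA/cm³) per HU
    intercept: float  # mg HA/cm³
    r_squared: float
    provenance: ScanMetadata | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")

    def convert(self, hu):
        """Convert HU values to mg HA/cm³."""
        return self.slope * np.asarray(hu, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "provenance": self.provenance.to_dict() if self.provenance else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        prov = d.get("provenance")
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            provenance=ScanMetadata.from_dict(prov) if prov else None,
        )


@dataclass(frozen=True)
class PhantomScan:
    """One stored phantom measurement: metadata plus per-insert results."""

    meta: ScanMetadata
    measurements: list

    def fit(self) -> "CalibrationCurve":
        return fit_calibration(self.measurements, provenance=self.meta)


@dataclass(frozen=True)
class BMDResult:
    """Mean calibrated density over a region of interest."""

    mean_bmd: float  # mg HA/cm³
    voxel_count: int


def fit_calibration(
    measurements: list[InsertMeasurement],
    provenance: ScanMetadata | None = None,
) -> CalibrationCurve:
    """OLS fit of nominal density on mean insert HU.

    Requires at least two measurements with distinct HU values.
    """
    if len(measurements) < 2:
        raise ValueError("degenerate calibration input: need >= 2 inserts")
    hu = np.array([m.mean_hu for m in measurements], dtype=float)
    rho = np.array([m.nominal_density for m in measurements], dtype=float)
    if np.ptp(hu) == 0:
        raise ValueError("degenerate calibration input: zero HU variance")
    res = stats.linregress(hu, rho)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        provenance=provenance,
    )


def apply_calibration(
    volume: CTVolume, mask: np.ndarray, curve: CalibrationCurve
) -> BMDResult:
    """Mean BMD over a mask: ``slope · mean(HU) + intercept`` by linearity."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.voxels.shape:
        raise ValueError("mask/volume mismatch")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI")
    mean_hu = float(volume.voxels[mask].mean())
    return BMDResult(mean_bmd=float(curve.convert(mean_hu)), voxel_count=n)


def _protocol_similarity(case: ScanMetadata, ref: ScanMetadata) -> tuple[int, int]:
    # Kernel agreement outranks protocol-label agreement.
    return (int(case.kernel == ref.kernel), int(case.protocol_id == ref.protocol_id))


def select_reference_scan(
    case_meta: ScanMetadata, library: list
) -> object:
    """Choose the asynchronous reference phantom scan for a case.

    ``library`` items must expose a ``meta: ScanMetadata`` attribute (or
    be ``ScanMetadata`` themselves). Selection is lexicographic: same
    scanner (else :class:`NoReferenceError`), same voltage (else
    :class:`VoltageMismatchError`, mirroring the exclusion of cases whose
    voltage matches no reference scan), maximal protocol agreement
    (kernel, then protocol label), minimal absolute date difference.
    Date ties go to the earlier scan; the result is independent of
    library order.
    """
    if not library:
        raise NoReferenceError("phantom library is empty")

    def meta_of(item) -> ScanMetadata:
        return item if isinstance(item, ScanMetadata) else item.meta

    same_scanner = [s for s in library if meta_of(s).scanner_id == case_meta.scanner_id]
    if not same_scanner:
        raise NoReferenceError(f"no reference for scanner {case_meta.scanner_id!r}")
    same_voltage = [s for s in same_scanner if meta_of(s).voltage == case_meta.voltage]
    if not same_voltage:
        raise VoltageMismatchError(
            f"excluded: no matching voltage ({case_meta.voltage:g} kVp) "
            f"for scanner {case_meta.scanner_id!r}"
        )

    def key(item):
        m = meta_of(item)
        sim = _protocol_similarity(case_meta, m)
        return (
            -sim[0],
            -sim[1],
            abs((m.date - case_meta.date).days),
            m.date,  # tie: earlier scan wins
            m.protocol_id,
            m.kernel,
        )

    return min(same_voltage, key=key)


def height_interpolated_curve(
    phantom_scans_at_heights: list[tuple[float, list[InsertMeasurement]]],
    target_height: float,
    provenance: ScanMetadata | None = None,
    clamp: bool = False,
) -> CalibrationCurve:
    """Personalized calibration curve at an arbitrary table height.

    Per-insert mean HU is interpolated linearly between the two phantom
    measurements bracketing ``target_height``, then the curve is refit on
    the interpolated values — so at a measured height the result equals
    that height's direct fit. Heights outside the measured range are
    refused unless ``clamp`` is set, which snaps to the nearest height.
    """
    if len(phantom_scans_at_heights) < 2:
        raise ValueError("need phantom measurements at >= 2 heights")
    items = sorted(phantom_scans_at_heights, key=lambda hv: hv[0])
    heights = np.array([h for h, _ in items], dtype=float)
    if np.any(np.diff(heights) <= 0):
        raise ValueError("table heights must be distinct")
    if not (heights[0] <= target_height <= heights[-1]):
        if not clamp:
            raise ValueError(
                f"height extrapolation refused: {target_height} mm outside "
                f"[{heights[0]:g}, {heights[-1]:g}] mm"
            )
        import warnings

        warnings.warn(
            f"table height {target_height} mm outside measured range; "
            "clamping to nearest measurement",
            stacklevel=2,
        )
        target_height = float(np.clip(target_height, heights[0], heights[-1]))

    by_density: dict[float, list[tuple[float, InsertMeasurement]]] = {}
    for h, ms in items:
        for m in ms:
            by_density.setdefault(m.nominal_density, []).append((h, m))
    interpolated = []
    for rho, hm in sorted(by_density.items()):
        if len(hm) != len(items):
            raise ValueError(
                f"insert {rho:g} mg/cm³ missing at some table heights"
            )
        hs = np.array([h for h, _ in hm])
        hus = np.array([m.mean_hu for _, m in hm])
        order = np.argsort(hs)
        hu_t = float(np.interp(target_height, hs[order], hus[order]))
        proto = hm[int(order[0])][1]
        interpolated.append(
            InsertMeasurement(
                center=proto.center,
                detected_radius=proto.detected_radius,
                roi_radius=proto.roi_radius,
                mean_hu=hu_t,
                voxel_count=proto.voxel_count,
                slice_range=proto.slice_range,
                nominal_density=rho,
            )
        )
    return fit_calibration(interpolated, provenance=provenance)


def save_curve(curve: CalibrationCurve, path) -> None:
    with open(path, "w") as fh:
        json.dump(curve.to_dict(), fh, indent=2)


def load_curve(path) -> CalibrationCurve:
    with open(path) as fh:
        return CalibrationCurve.from_dict(json.load(fh))
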