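"""Corrections for the systematic errors of asynchronous calibration.

Four measures reduce the BMD error of asynchronous calibration:

1. **closest-time reference** — pick the phantom scan nearest in time
   (regular, e.g. monthly, phantom measurements make this effective);
2. **table-height personalization** — interpolate phantom measurements
   taken at several heights to the case's table height;
3. **body-weight correction** — with the per-scanner regression
   d = a·m + b (in %) between weight m and BMD error,
   ``BMD_asyn_corr = BMD_asyn · (1 − a·m − b)`` with (a, b) as fractions;
4. **kernel correction** — a multiplicative factor mapping a non-reference
   reconstruction kernel onto the reference kernel.

The weight and kernel corrections are both multiplicative, so they
commute; the full pipeline records an audit trail of each stage's
contribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .calibration import (
    BMDResult,
    CalibrationCurve,
    PhantomScan,
    apply_calibration,
    fit_calibration,
    height_interpolated_curve,
    select_reference_scan,
)
from .errors import fit_error_regression
from .metadata import ScanMetadata
from .volume import CTVolume

__all__ = [
    "CorrectionModel",
    "weight_corrected_bmd",
    "kernel_correction_factor",
    "fit_weight_model",
    "calibrate_asynchronous_corrected",
]


@dataclass(frozen=True)
class CorrectionModel:
    """Per-scanner correction parameters.

    ``weight_a`` (% per kg) and ``weight_b`` (%) are the coefficients of
    the weight–error regression d = a·m + b; ``kernel_factor`` multiplies
    BMD values obtained with a non-reference kernel; ``reference_kernel``
    names the kernel the factor maps onto. The model is only valid for
    the scanner it was fitted on.
    """

    weight_a: float = 0.0
    weight_b: float = 0.0
    kernel_factor: float = 1.0
    reference_kernel: str = "bone"
    scanner_id: str = ""

    def __post_init__(self) -> None:
        if self.kernel_factor <= 0:
            raise ValueError("kernel_factor must be positive")

    def to_dict(self) -> dict:
        return {
            "weight_a": self.weight_a,
            "weight_b": self.weight_b,
            "kernel_factor": self.kernel_factor,
            "reference_kernel": self.reference_kernel,
            "scanner_id": self.scanner_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionModel":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CorrectionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def weight_corrected_bmd(
    bmd_asyn: float, weight: float, model: CorrectionModel
) -> float:
    """Body-weight-corrected BMD: ``BMD_asyn · (1 − a·m − b)``.

    ``weight_a``/``weight_b`` are in % and converted to fractions here —
    the single conversion point between the regression (fitted on % errors)
    and the correction equation (consuming fractions).
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    factor = 1.0 - (model.weight_a * weight + model.weight_b) / 100.0
    if factor <= 0:
        raise ValueError(
            "non-physical correction: weight far outside the fitted range"
        )
    return bmd_asyn * factor


def kernel_correction_factor(paired_bmds) -> float:
    """Multiplicative factor mapping another kernel onto the reference.

    From paired BMD values ``(reference-kernel, other-kernel)`` of the
    same cases, the factor is the mean of per-case reference/other
    ratios; multiplying other-kernel values by it minimizes the mean
    relative deviation on the fitted set.
    """
    pairs = np.asarray(list(paired_bmds), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 (reference, other) BMD pairs")
    if np.any(pairs <= 0):
        raise ValueError("BMD values must be positive")
    return float(np.mean(pairs[:, 0] / pairs[:, 1]))


def fit_weight_model(
    weights,
    d_pct,
    scanner_id: str = "",
    kernel_factor: float = 1.0,
    reference_kernel: str = "bone",
) -> CorrectionModel:
    """Fit the weight–error regression and wrap it as a correction model."""
    reg = fit_error_regression(weights, d_pct)
    return CorrectionModel(
        weight_a=reg.slope,
        weight_b=reg.intercept,
        kernel_factor=kernel_factor,
        reference_kernel=reference_kernel,
        scanner_id=scanner_id,
    )


def _height_series(library: list[PhantomScan], chosen: PhantomScan) -> list[PhantomScan]:
    m = chosen.meta
    return [
        s
        for s in library
        if s.meta.scanner_id == m.scanner_id
        and s.meta.voltage == m.voltage
        and s.meta.kernel == m.kernel
        and s.meta.protocol_id == m.protocol_id
        and s.meta.date == m.date
    ]


def calibrate_asynchronous_corrected(
    volume: CTVolume,
    mask,
    case_meta: ScanMetadata,
    weight: float | None,
    library: list[PhantomScan],
    model: CorrectionModel | None = None,
    force_scanner: bool = False,
) -> tuple[float, dict]:
    """Fully corrected asynchronous BMD for one case, with audit trail.

    Pipeline: select the reference phantom scan (same scanner and
    voltage, closest time) → personalize the calibration curve to the
    case's table height when the reference series was measured at
    several heights → convert the masked region to BMD → apply the
    kernel factor when the case kernel differs from the model's
    reference kernel → apply the body-weight correction. Each stage's
    contribution is recorded in the returned audit dictionary.
    """
    audit: dict = {"case": case_meta.to_dict()}
    chosen = select_reference_scan(case_meta, library)
    audit["reference"] = chosen.meta.to_dict()

    series = _height_series(library, chosen)
    heights = sorted({s.meta.table_height for s in series})
    if len(heights) >= 2 and heights[0] <= case_meta.table_height <= heights[-1]:
        curve = height_interpolated_curve(
            [(s.meta.table_height, s.measurements) for s in series],
            case_meta.table_height,
            provenance=chosen.meta,
        )
        audit["height_personalized"] = True
    else:
        curve = chosen.fit()
        audit["height_personalized"] = False
    audit["curve"] = {"slope": curve.slope, "intercept": curve.intercept}

    result = apply_calibration(volume, mask, curve)
    bmd = result.mean_bmd
    audit["bmd_asyn"] = bmd

    if model is not None:
        if model.scanner_id and model.scanner_id != case_meta.scanner_id and not force_scanner:
            raise ValueError(
                f"correction model fitted on scanner {model.scanner_id!r} "
                f"cannot be applied to {case_meta.scanner_id!r} (use force_scanner)"
            )
        if case_meta.kernel != model.reference_kernel:
            bmd *= model.kernel_factor
            audit["kernel_factor_applied"] = model.kernel_factor
        else:
            audit["kernel_factor_applied"] = 1.0
        if weight is not None and (model.weight_a != 0.0 or model.weight_b != 0.0):
            bmd = weight_corrected_bmd(bmd, weight, model)
            audit["weight_correction_applied"] = True
        else:
            audit["weight_correction_applied"] = False
    audit["bmd_corrected"] = bmd
    audit["voxel_count"] = result.voxel_count
    return bmd, audit
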