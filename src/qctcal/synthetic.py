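"""Synthetic CT scans with a known HU↔density relationship.

The generator produces phantom and subject volumes whose voxel values
follow a controlled affine HU↔BMD mapping plus four acquisition
confounders observed on real scanners:

* **temporal drift** — a slow multiplicative change of the HU excess over
  air, linear in time (fractional rate per year);
* **table height** — an additive HU offset, piecewise linear in the
  isocenter-to-tabletop distance (bowtie-filter mispositioning effect);
* **body weight** — a multiplicative bias of the in-body mineral signal,
  linear in body weight (beam hardening grows with patient size and
  affects the body but not a separately scanned phantom);
* **reconstruction kernel** — a fractional shift of the mineral signal for
  non-reference kernels.

Every simulated scan comes with its ground truth, so each downstream
stage (detection, calibration, error analysis, correction) has an exact
oracle. All randomness is driven by the seed in :class:`AcquisitionTruth`;
identical inputs give bit-identical volumes.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metadata import ScanMetadata
from .phantom import PhantomSpec, SubjectSpec
from .volume import CTVolume

__all__ = [
    "AcquisitionTruth",
    "SubjectScan",
    "simulate_phantom_scan",
    "simulate_subject_scan",
    "simulate_error_cohort",
]

AIR_HU = -1000.0
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class AcquisitionTruth:
    """Generative parameters of a simulated scanner.

    ``hu_slope``/``hu_intercept`` define the true HU per (mg HA/cm³)
    mapping. ``drift_rate`` is the fractional change of HU excess over air
    per year relative to ``drift_ref_date``. ``height_knots`` define a
    piecewise-linear additive HU offset versus table height (mm); heights
    outside the knot range are rejected. ``weight_effect`` is ``(a, b)``
    of the relative BMD bias ``d = a·m + b`` in per cent, applied
    multiplicatively to the bone mineral signal. ``kernel_offset`` is the
    fractional mineral-signal change of any kernel other than
    ``reference_kernel``. ``inscan_bias_attenuation`` is the fraction by
    which an in-scan phantom's share of the weight bias is reduced: at 0
    the phantom sits in the same beam-hardening environment as the bone,
    so in-scan calibration recovers the true BMD exactly; at 1 the
    in-scan phantom is entirely unaffected by body size.
    """

    hu_slope: float = 1.0
    hu_intercept: float = 0.0
    drift_rate: float = 0.0028
    drift_ref_date: _dt.date = _dt.date(2022, 1, 1)
    height_knots: tuple[tuple[float, float], ...] = (
        (100.0, 8.0),
        (160.0, 0.0),
        (250.0, -10.0),
    )
    weight_effect: tuple[float, float] = (-0.13, 8.66)
    kernel_offset: float = -0.05
    reference_kernel: str = "bone"
    inscan_bias_attenuation: float = 0.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hu_slope <= 0:
            raise ValueError("hu_slope must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        hs = [h for h, _ in self.height_knots]
        if len(hs) < 2 or any(b <= a for a, b in zip(hs[1:], hs[:-1])):
            # knots must be sorted ascending
            object.__setattr__(
                self, "height_knots", tuple(sorted(self.height_knots))
            )

    # -- confounder terms ----------------------------------------------------
    def height_offset(self, table_height: float) -> float:
        """Additive HU offset at a table height, piecewise linear in mm."""
        hs = np.array([h for h, _ in self.height_knots])
        vs = np.array([v for _, v in self.height_knots])
        if not (hs[0] <= table_height <= hs[-1]):
            raise ValueError(
                f"height out of simulated range [{hs[0]}, {hs[-1]}] mm: "
                f"{table_height}"
            )
        return float(np.interp(table_height, hs, vs))

    def drift_factor(self, date: _dt.date) -> float:
        dt_years = (date - self.drift_ref_date).days / DAYS_PER_YEAR
        return 1.0 + self.drift_rate * dt_years

    def kernel_factor(self, kernel: str) -> float:
        return 1.0 if kernel == self.reference_kernel else 1.0 + self.kernel_offset

    def weight_bias(self, weight: float) -> float:
        """Fractional mineral-signal bias for a body of the given weight."""
        a, b = self.weight_effect
        return (a * weight + b) / 100.0

    def replace(self, **kwargs) -> "AcquisitionTruth":
        return dataclasses.replace(self, **kwargs)


def _grid_1d(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.ceil((hi - lo) / step))
    return lo + step * (np.arange(n) + 0.5)


def _finalize(
    hu: np.ndarray,
    material: np.ndarray,
    meta: ScanMetadata,
    truth: AcquisitionTruth,
) -> np.ndarray:
    """Apply drift, height offset and noise; quantize to integer HU."""
    drift = truth.drift_factor(meta.date)
    hu = AIR_HU + (hu - AIR_HU) * drift
    hu = hu + truth.height_offset(meta.table_height) * material
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        hu = hu + rng.normal(0.0, truth.noise_sd, size=hu.shape)
    return np.rint(hu).astype(np.int32)


def _noise_free_insert_hu(
    density: float, meta: ScanMetadata, truth: AcquisitionTruth, bias: float = 0.0
) -> float:
    """Noise-free HU of an insert/bone region after all enabled confounders."""
    kfac = truth.kernel_factor(meta.kernel)
    base = truth.hu_intercept + truth.hu_slope * density * kfac * (1.0 + bias)
    drift = truth.drift_factor(meta.date)
    return AIR_HU + (base - AIR_HU) * drift + truth.height_offset(meta.table_height)


def simulate_phantom_scan(
    spec: PhantomSpec,
    meta: ScanMetadata,
    truth: AcquisitionTruth,
    margin_mm: float = 12.0,
) -> tuple[CTVolume, pd.DataFrame]:
    """Simulate a CT scan of a calibration phantom.

    Returns the volume and a ground-truth table with one row per insert:
    true center (world mm), radius (mm), nominal density and the
    noise-free HU after all enabled confounders.
    """
    dx, dy, dz = meta.voxel_size
    centers = np.asarray(spec.insert_centers, dtype=float)
    r = spec.insert_radius
    slab_pad = 1.5 * r
    x_lo = centers[:, 0].min() - r - slab_pad - margin_mm
    x_hi = centers[:, 0].max() + r + slab_pad + margin_mm
    y_lo = centers[:, 1].min() - r - slab_pad - margin_mm
    y_hi = centers[:, 1].max() + r + slab_pad + margin_mm
    xs = _grid_1d(x_lo, x_hi, dx)
    ys = _grid_1d(y_lo, y_hi, dy)
    z_air = max(2.0 * dz, 4.0)
    zs = _grid_1d(-z_air, spec.phantom_length + z_air, dz)

    xx, yy = np.meshgrid(xs, ys)  # (ny, nx)
    slab = (
        (xx >= centers[:, 0].min() - r - slab_pad)
        & (xx <= centers[:, 0].max() + r + slab_pad)
        & (yy >= centers[:, 1].min() - r - slab_pad)
        & (yy <= centers[:, 1].max() + r + slab_pad)
    )
    kfac = truth.kernel_factor(meta.kernel)
    plane = np.where(slab, spec.background_hu, AIR_HU)
    for (cx, cy), rho in zip(centers, spec.insert_densities):
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        plane = np.where(
            inside, truth.hu_intercept + truth.hu_slope * rho * kfac, plane
        )

    in_phantom_z = (zs >= 0.0) & (zs <= spec.phantom_length)
    hu = np.where(in_phantom_z[:, None, None], plane[None], AIR_HU)
    material = np.where(in_phantom_z[:, None, None], slab[None], False)
    voxels = _finalize(hu, material, meta, truth)

    vol = CTVolume(voxels, (dx, dy, dz), (float(xs[0]), float(ys[0]), float(zs[0])))
    z_idx = np.nonzero(in_phantom_z)[0]
    table = pd.DataFrame(
        {
            "insert_id": np.arange(spec.n_inserts),
            "density": list(spec.insert_densities),
            "center_x_mm": centers[:, 0],
            "center_y_mm": centers[:, 1],
            "radius_mm": r,
            "hu_noise_free": [
                _noise_free_insert_hu(rho, meta, truth)
                for rho in spec.insert_densities
            ],
            "z_lo": int(z_idx[0]),
            "z_hi": int(z_idx[-1]),
        }
    )
    return vol, table


@dataclass
class SubjectScan:
    """A simulated subject acquisition with voxel-aligned ground truth."""

    volume: CTVolume
    bone_mask: np.ndarray
    body_mask: np.ndarray
    phantom_truth: pd.DataFrame | None = None

    def __iter__(self):  # allow tuple-style unpacking
        yield self.volume
        yield self.bone_mask
        yield self.body_mask


def simulate_subject_scan(
    subject: SubjectSpec,
    meta: ScanMetadata,
    truth: AcquisitionTruth,
    with_inscan_phantom: bool = False,
    phantom_spec: PhantomSpec | None = None,
    n_slices: int = 8,
    margin_mm: float = 12.0,
) -> SubjectScan:
    """Simulate a CT scan of a simplified subject.

    The bone region's mineral signal is scaled by ``1 + (a·m + b)/100``
    relative to the phantom mapping, emulating weight-dependent beam
    hardening that biases the body but not a separately scanned phantom.
    When ``with_inscan_phantom`` is set, a calibration phantom is placed
    below the body (toward the table); it shares the scan's drift, height
    offset and — by default — the body's full beam-hardening bias, so
    in-scan calibration recovers the true BMD.
    """
    dx, dy, dz = meta.voxel_size
    a, b = subject.body_half_axes
    if with_inscan_phantom and phantom_spec is None:
        from .phantom import six_insert_phantom

        phantom_spec = six_insert_phantom()

    y_hi = b + margin_mm
    phantom_y = None
    if with_inscan_phantom:
        pc = np.asarray(phantom_spec.insert_centers, dtype=float)
        pr = phantom_spec.insert_radius
        phantom_y = b + 1.5 * pr + 10.0  # phantom row below the body (+y = table)
        y_hi = phantom_y + pr + 1.5 * pr + margin_mm
        x_half = max(a, np.abs(pc[:, 0]).max() + pr + 1.5 * pr) + margin_mm
    else:
        x_half = a + margin_mm
    xs = _grid_1d(-x_half, x_half, dx)
    ys = _grid_1d(-(b + margin_mm), y_hi, dy)
    zs = _grid_1d(0.0, n_slices * dz, dz)

    xx, yy = np.meshgrid(xs, ys)
    body = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    cx, cy = subject.bone_center
    bone = (xx - cx) ** 2 + (yy - cy) ** 2 <= subject.bone_radius**2
    bone &= body
    if not bone.any():
        raise ValueError("bone region lies outside the simulated volume")

    kfac = truth.kernel_factor(meta.kernel)
    wbias = truth.weight_bias(subject.weight)
    plane = np.where(body, subject.soft_tissue_hu, AIR_HU)
    bone_hu = truth.hu_intercept + truth.hu_slope * subject.true_bmd * kfac * (
        1.0 + wbias
    )
    plane = np.where(bone, bone_hu, plane)
    material = body.copy()

    phantom_truth = None
    if with_inscan_phantom:
        pc = np.asarray(phantom_spec.insert_centers, dtype=float)
        pr = phantom_spec.insert_radius
        pad = 1.5 * pr
        slab = (
            (xx >= pc[:, 0].min() - pr - pad)
            & (xx <= pc[:, 0].max() + pr + pad)
            & (yy >= phantom_y - pr - pad)
            & (yy <= phantom_y + pr + pad)
        )
        slab &= ~body
        plane = np.where(slab, phantom_spec.background_hu, plane)
        pbias = (1.0 - truth.inscan_bias_attenuation) * wbias
        for (px, py0), rho in zip(pc, phantom_spec.insert_densities):
            py = py0 + phantom_y
            inside = (xx - px) ** 2 + (yy - py) ** 2 <= pr**2
            plane = np.where(
                inside,
                truth.hu_intercept + truth.hu_slope * rho * kfac * (1.0 + pbias),
                plane,
            )
        material |= slab
        phantom_truth = pd.DataFrame(
            {
                "insert_id": np.arange(phantom_spec.n_inserts),
                "density": list(phantom_spec.insert_densities),
                "center_x_mm": pc[:, 0],
                "center_y_mm": pc[:, 1] + phantom_y,
                "radius_mm": pr,
                "hu_noise_free": [
                    _noise_free_insert_hu(rho, meta, truth, bias=pbias)
                    for rho in phantom_spec.insert_densities
                ],
                "z_lo": 0,
                "z_hi": len(zs) - 1,
            }
        )

    hu = np.broadcast_to(plane[None], (len(zs),) + plane.shape).copy()
    material3 = np.broadcast_to(material[None], hu.shape)
    voxels = _finalize(hu, material3, meta, truth)
    vol = CTVolume(voxels, (dx, dy, dz), (float(xs[0]), float(ys[0]), float(zs[0])))
    bone3 = np.broadcast_to(bone[None], hu.shape).copy()
    body3 = np.broadcast_to(body[None], hu.shape).copy()
    return SubjectScan(vol, bone3, body3, phantom_truth)


def simulate_error_cohort(
    n: int,
    truth: AcquisitionTruth | None = None,
    seed: int | None = None,
    weight_mean: float = 78.0,
    weight_sd: float = 15.0,
    weight_range: tuple[float, float] = (35.0, 140.0),
    bmd_mean: float = 413.0,
    bmd_sd: float = 80.0,
    bmd_range: tuple[float, float] = (150.0, 650.0),
    residual_sd_pct: float = 2.6,
    scanner_id: str = "CT1",
) -> pd.DataFrame:
    """Draw a cohort of paired in-scan / asynchronous BMD measurements.

    This is the statistical layer of the generator: it samples body
    weights and true densities, then produces the relative BMD error of
    asynchronous calibration directly from the generative weight-bias
    model, ``d = (a·m + b)/100 + ε`` with Gaussian residual ``ε``
    (per-case noise from all other sources, in per cent). It matches what
    a full image-level simulation converges to, at a cost allowing
    thousands of cases. Returns a cohort table with columns ``case_id``,
    ``weight``, ``bmd_inscan``, ``bmd_asyn``, ``d``.
    """
    truth = truth or AcquisitionTruth()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    weights = np.clip(
        rng.normal(weight_mean, weight_sd, n), *weight_range
    )
    bmd_true = np.clip(rng.normal(bmd_mean, bmd_sd, n), *bmd_range)
    d = truth.weight_bias(weights) + rng.normal(0.0, residual_sd_pct / 100.0, n)
    return pd.DataFrame(
        {
            "case_id": [f"{scanner_id}-{i:04d}" for i in range(n)],
            "scanner_id": scanner_id,
            "weight": weights,
            "bmd_inscan": bmd_true,
            "bmd_asyn": bmd_true * (1.0 + d),
            "d": d,
        }
    )
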