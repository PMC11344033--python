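"""Locate calibration-phantom inserts and measure their mean HU.

Inserts are found with a Hough-transform circle detection on an average
of the central phantom slices. Detected circles are matched to the
phantom layout by a rigid 2D point-set fit (least squares over rotations
and translations), so the nominal density labels never depend on the HU
values themselves. Before averaging, each detected radius is reduced by
20% to keep partial-volume boundary voxels out of the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_gradient_magnitude
from scipy.optimize import linear_sum_assignment
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .phantom import PhantomSpec
from .volume import CTVolume

__all__ = [
    "DetectedCircle",
    "InsertMeasurement",
    "PhantomNotFoundError",
    "detect_insert_circles",
    "measure_inserts",
    "phantom_slice_range",
]


class PhantomNotFoundError(RuntimeError):
    """Raised when circle detection cannot account for every insert."""


@dataclass(frozen=True)
class DetectedCircle:
    """One detected insert: center (world mm), radius (mm), accumulator
    score, and the nominal density assigned by the layout match."""

    center: tuple[float, float]
    radius: float
    score: float
    nominal_density: float


@dataclass(frozen=True)
class InsertMeasurement:
    """Mean HU of one insert inside a shrunken ROI."""

    center: tuple[float, float]
    detected_radius: float
    roi_radius: float
    mean_hu: float
    voxel_count: int
    slice_range: tuple[int, int]
    nominal_density: float


def phantom_slice_range(
    volume: CTVolume, central_fraction: float = 0.6, material_hu: float = -300.0
) -> tuple[int, int]:
    """Index range (inclusive) of the central slices of the scanned object.

    Slices containing material (HU above ``material_hu`` in at least 1% of
    voxels) delimit the object's z-extent; the central ``central_fraction``
    of that extent is returned, to keep end-of-phantom partial slices out
    of the averaging.
    """
    frac = (volume.voxels > material_hu).mean(axis=(1, 2))
    occupied = np.nonzero(frac > 0.01)[0]
    if occupied.size == 0:
        raise PhantomNotFoundError("phantom not found: no material in volume")
    z_lo, z_hi = int(occupied[0]), int(occupied[-1])
    n = z_hi - z_lo + 1
    trim = int(np.floor(n * (1.0 - central_fraction) / 2.0))
    return z_lo + trim, z_hi - trim


def _rigid_match(
    spec_pts: np.ndarray, cand_pts: np.ndarray, tol: float
) -> np.ndarray | None:
    """Match layout points to candidates under the best rigid transform.

    Tries rotations defined by every (layout-pair, candidate-pair) with
    compatible separation, solves the assignment problem under each, and
    returns candidate indices (one per layout point) for the lowest total
    residual, or None if no transform places every point within ``tol``.
    """
    n, m = len(spec_pts), len(cand_pts)
    best_cost, best_assign = np.inf, None
    pairs_s = [(i, j) for i in range(n) for j in range(n) if i != j]
    pairs_c = [(p, q) for p in range(m) for q in range(m) if p != q]
    for i, j in pairs_s:
        v_s = spec_pts[j] - spec_pts[i]
        d_s = np.hypot(*v_s)
        for p, q in pairs_c:
            v_c = cand_pts[q] - cand_pts[p]
            d_c = np.hypot(*v_c)
            if abs(d_c - d_s) > tol:
                continue
            ang = np.arctan2(v_c[1], v_c[0]) - np.arctan2(v_s[1], v_s[0])
            c, s = np.cos(ang), np.sin(ang)
            rot = np.array([[c, -s], [s, c]])
            moved = (spec_pts - spec_pts[i]) @ rot.T + cand_pts[p]
            dist = np.linalg.norm(moved[:, None, :] - cand_pts[None, :, :], axis=2)
            row, col = linear_sum_assignment(dist)
            resid = dist[row, col]
            if resid.max() > tol:
                continue
            cost = float(resid.sum())
            if cost < best_cost:
                best_cost, best_assign = cost, col
    return best_assign


def detect_insert_circles(
    volume: CTVolume,
    spec: PhantomSpec,
    central_fraction: float = 0.6,
    radius_window: float = 0.25,
    peak_rel_threshold: float = 0.5,
    smoothing_sigma: float = 1.0,
    edge_rel_threshold: float = 0.015,
) -> list[DetectedCircle]:
    """Detect one circle per phantom insert in a CT volume.

    The central phantom slices are averaged to suppress noise; edges come
    from a Canny detector whose hysteresis thresholds are set relative to
    the strongest gradient in the image (the air/phantom boundary sets
    the scale, so even low-contrast inserts keep their — thin — edges). A
    circular Hough transform is run over radii within ``radius_window``
    of the expected insert radius; accumulator peaks stronger than
    ``peak_rel_threshold`` times the best peak become candidates, which
    are matched to the phantom layout. Each returned circle carries the
    nominal density of its matched insert.

    Raises :class:`PhantomNotFoundError` when fewer circles than inserts
    survive, reporting how many were found.
    """
    dx, dy, _ = volume.spacing
    if abs(dx - dy) > 1e-6 * max(dx, dy):
        raise ValueError("anisotropic in-plane spacing is not supported")
    z_lo, z_hi = phantom_slice_range(volume, central_fraction)
    image = volume.voxels[z_lo : z_hi + 1].mean(axis=0)

    if np.ptp(image) < 1e-9:
        raise PhantomNotFoundError("phantom not found: uniform image")
    image = image.astype(float)
    grad_max = float(gaussian_gradient_magnitude(image, smoothing_sigma).max())
    if grad_max <= 0:
        raise PhantomNotFoundError("phantom not found: no edges detected")
    edges = canny(
        image,
        sigma=smoothing_sigma,
        low_threshold=0.5 * edge_rel_threshold * grad_max,
        high_threshold=edge_rel_threshold * grad_max,
    )
    if not edges.any():
        raise PhantomNotFoundError("phantom not found: no edges detected")

    r_px = spec.insert_radius / dx
    radii = np.arange(
        max(2, int(np.floor(r_px * (1 - radius_window)))),
        int(np.ceil(r_px * (1 + radius_window))) + 1,
    )
    accum = hough_circle(edges, radii)
    n_cand = spec.n_inserts + 6
    accums, cxs, cys, rads = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=int(2 * r_px),
        min_ydistance=int(2 * r_px),
        total_num_peaks=n_cand,
        threshold=peak_rel_threshold * float(accum.max()),
    )
    if len(cxs) < spec.n_inserts:
        raise PhantomNotFoundError(
            f"phantom not found / incomplete detection: "
            f"{len(cxs)} of {spec.n_inserts} circles"
        )

    x0, y0, _ = volume.origin
    cand_mm = np.column_stack((x0 + np.asarray(cxs) * dx, y0 + np.asarray(cys) * dy))
    spec_pts = np.asarray(spec.insert_centers, dtype=float)
    assign = _rigid_match(spec_pts, cand_mm, tol=spec.insert_radius)
    if assign is None:
        raise PhantomNotFoundError(
            "phantom not found: detected circles do not match the layout"
        )
    return [
        DetectedCircle(
            center=(float(cand_mm[k, 0]), float(cand_mm[k, 1])),
            radius=float(rads[k] * dx),
            score=float(accums[k]),
            nominal_density=float(rho),
        )
        for k, rho in zip(assign, spec.insert_densities)
    ]


def measure_inserts(
    volume: CTVolume,
    circles: list[DetectedCircle],
    spec: PhantomSpec,
    shrink: float = 0.2,
    slice_range: tuple[int, int] | None = None,
    central_fraction: float = 0.6,
) -> list[InsertMeasurement]:
    """Mean HU per insert over a shrunken circular ROI.

    The ROI radius is ``(1 - shrink)`` times the detected radius (default
    20% reduction against partial-volume contamination). Voxels whose
    centers fall within the ROI across the slice range are pooled.
    """
    if not 0 <= shrink < 1:
        raise ValueError("shrink must be in [0, 1)")
    dx, dy, _ = volume.spacing
    if slice_range is None:
        slice_range = phantom_slice_range(volume, central_fraction)
    z_lo, z_hi = slice_range
    xs, ys, _ = volume.world_coords()
    xx, yy = np.meshgrid(xs, ys)

    out = []
    for c in circles:
        roi_r = (1.0 - shrink) * c.radius
        if roi_r < max(dx, dy):
            raise ValueError(f"ROI degenerate: radius {roi_r:.2f} mm < 1 voxel")
        inside = (xx - c.center[0]) ** 2 + (yy - c.center[1]) ** 2 <= roi_r**2
        n_plane = int(inside.sum())
        if n_plane == 0:
            raise ValueError("ROI degenerate: no voxel centers inside")
        block = volume.voxels[z_lo : z_hi + 1, inside]
        out.append(
            InsertMeasurement(
                center=c.center,
                detected_radius=c.radius,
                roi_radius=roi_r,
                mean_hu=float(block.mean()),
                voxel_count=int(block.size),
                slice_range=(z_lo, z_hi),
                nominal_density=c.nominal_density,
            )
        )
    return out
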