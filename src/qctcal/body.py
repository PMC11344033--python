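"""Body-size covariates correlated with calibration error.

The body contour is segmented by Otsu thresholding of the HU histogram;
from the mask come the average slice volume, the polar moment of area
about the slice centroid (a cross-sectional size/shape measure), and,
with weight and height, the BMI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .volume import CTVolume

__all__ = ["BodyMetrics", "segment_body_otsu", "compute_body_metrics"]


@dataclass(frozen=True)
class BodyMetrics:
    avg_slice_volume: float  # cm³ per occupied slice
    polar_moment: float  # mm⁴, about the per-slice centroid, averaged
    bmi: float | None  # kg/m², None when weight/height unknown
    voxel_count: int


def segment_body_otsu(
    volume: CTVolume, slice_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Binary body mask from Otsu thresholding of the HU histogram.

    The threshold separates the air background from the body; the largest
    connected component is kept and its holes filled slicewise. Returns a
    boolean mask on the full volume grid (False outside ``slice_range``).
    """
    if slice_range is None:
        slice_range = (0, volume.voxels.shape[0] - 1)
    z_lo, z_hi = slice_range
    sub = volume.voxels[z_lo : z_hi + 1]
    if np.ptp(sub) == 0:
        raise ValueError("degenerate histogram: constant image")
    thr = threshold_otsu(sub.astype(float))
    fg = sub > thr
    if not fg.any():
        raise ValueError("degenerate histogram: empty foreground")
    labels = label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    body = labels == largest
    for k in range(body.shape[0]):
        body[k] = ndimage.binary_fill_holes(body[k])
    mask = np.zeros(volume.voxels.shape, dtype=bool)
    mask[z_lo : z_hi + 1] = body
    return mask


def compute_body_metrics(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    weight: float | None = None,
    height: float | None = None,
) -> BodyMetrics:
    """Body-size covariates from a binary mask.

    ``avg_slice_volume`` is total mask volume divided by the number of
    occupied slices, in cm³. The polar moment Σ((x−x̄)² + (y−ȳ)²)·dA is
    computed per slice about that slice's centroid and averaged over the
    occupied slices, in mm⁴. BMI is weight/height² (kg/m²) and is omitted
    when either anthropometric is missing.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be a non-empty 3D array")
    dx, dy, dz = spacing
    counts = mask.sum(axis=(1, 2))
    occupied = counts > 0
    total_voxels = int(counts.sum())
    avg_slice_volume = total_voxels * dx * dy * dz / occupied.sum() / 1000.0

    d_area = dx * dy
    moments = []
    ys = dy * np.arange(mask.shape[1])
    xs = dx * np.arange(mask.shape[2])
    xx, yy = np.meshgrid(xs, ys)
    for k in np.nonzero(occupied)[0]:
        sl = mask[k]
        xbar = xx[sl].mean()
        ybar = yy[sl].mean()
        moments.append(
            float((((xx[sl] - xbar) ** 2 + (yy[sl] - ybar) ** 2) * d_area).sum())
        )
    polar = float(np.mean(moments))

    bmi = None
    if weight is not None and height is not None:
        if height <= 0:
            raise ValueError("height must be positive for BMI")
        bmi = weight / height**2
    return BodyMetrics(
        avg_slice_volume=avg_slice_volume,
        polar_moment=polar,
        bmi=bmi,
        voxel_count=total_voxels,
    )
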