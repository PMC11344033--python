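"""CT volume container and file I/O.

Volumes are stored as integer Hounsfield-unit grids indexed ``[z, y, x]``
(slices along z). World coordinates are millimetres; the y axis points
toward the scanning table. NIfTI is the canonical on-disk format; DICOM
series are supported read-only, with the rescale slope/intercept applied
to reach HU.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

__all__ = ["CTVolume", "read_volume", "write_volume", "read_mask", "write_mask"]


@dataclass
class CTVolume:
    """A 3D CT image in Hounsfield units.

    Parameters
    ----------
    voxels
        Integer HU grid of shape ``(nz, ny, nx)``.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, all positive.
    origin
        World coordinate (mm) of the centre of voxel ``[0, 0, 0]``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            self.voxels = np.rint(self.voxels).astype(np.int32)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # (nz, ny, nx)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Centre-of-voxel world coordinates (x, y, z), each 1D, in mm."""
        nz, ny, nx = self.voxels.shape
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        return (
            x0 + dx * np.arange(nx),
            y0 + dy * np.arange(ny),
            z0 + dz * np.arange(nz),
        )

    def same_grid(self, other: "CTVolume | np.ndarray") -> bool:
        if isinstance(other, CTVolume):
            return (
                self.voxels.shape == other.voxels.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin)
            )
        return self.voxels.shape == np.asarray(other).shape


def _affine(vol: CTVolume) -> np.ndarray:
    # nibabel data axes are (x, y, z); we store (z, y, x), so transpose on I/O.
    dx, dy, dz = vol.spacing
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = vol.origin
    return aff


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (int16 HU)."""
    data = np.ascontiguousarray(vol.voxels.T.astype(np.int16))
    img = nib.Nifti1Image(data, _affine(vol))
    img.header.set_xyzt_units("mm")
    nib.save(img, os.fspath(path))


def write_mask(mask: np.ndarray, like: CTVolume, path: str | os.PathLike) -> None:
    """Write a binary mask on the grid of ``like`` as uint8 NIfTI."""
    if mask.shape != like.voxels.shape:
        raise ValueError("mask/volume mismatch")
    data = np.ascontiguousarray(np.asarray(mask, dtype=np.uint8).T)
    img = nib.Nifti1Image(data, _affine(like))
    nib.save(img, os.fspath(path))


def _read_nifti(path: str) -> CTVolume:
    img = nib.load(path)
    aff = img.affine
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got shape {data.shape}")
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in aff[:3, 3])
    return CTVolume(np.rint(np.asarray(data.T)).astype(np.int32),
                    (spacing[0], spacing[1], spacing[2]), origin)


def _read_dicom_series(directory: str) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory}")
    try:
        datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    except Exception:
        datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))

    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError("cannot establish HU scale: missing rescale tags")
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        slices.append(hu)
    first = datasets[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    if len(datasets) > 1:
        zs = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
        dzs = np.diff(zs)
        if np.ptp(dzs) > 1e-3:
            raise ValueError("non-uniform slice spacing; resampling refused")
        dz = float(dzs[0])
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    x0, y0, z0 = (float(v) for v in first.ImagePositionPatient)
    return CTVolume(
        np.rint(np.stack(slices)).astype(np.int32), (dx, dy, abs(dz)), (x0, y0, z0)
    )


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume in HU from a NIfTI file or a DICOM series directory."""
    path = os.fspath(path)
    if os.path.isdir(path):
        return _read_dicom_series(path)
    return _read_nifti(path)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary NIfTI mask as a boolean ``[z, y, x]`` array."""
    img = nib.load(os.fspath(path))
    return np.asanyarray(img.dataobj).T > 0
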