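"""Calibration-phantom and subject geometry specifications.

A density calibration phantom is a resin slab containing cylindrical
inserts of known hydroxyapatite (HA) concentration, scanned to map HU to
volumetric bone mineral density (mg HA/cm³). Two standard layouts are
provided: a 6-insert phantom spanning 0–800 mg HA/cm³ and a 3-insert
variant spanning 300–800 mg HA/cm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomSpec", "SubjectSpec", "six_insert_phantom", "three_insert_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and nominal HA densities of a calibration phantom.

    Insert densities are in mg HA/cm³, strictly increasing and
    non-negative; insert centers are (x, y) in mm in the phantom frame and
    must be separated by more than twice the insert radius so that the
    cylinders do not overlap.
    """

    insert_densities: tuple[float, ...]
    insert_radius: float = 9.0
    insert_centers: tuple[tuple[float, float], ...] = ()
    phantom_length: float = 40.0
    background_hu: float = 30.0

    def __post_init__(self) -> None:
        dens = np.asarray(self.insert_densities, dtype=float)
        if dens.size < 2:
            raise ValueError("a phantom needs at least 2 inserts")
        if np.any(dens < 0) or np.any(np.diff(dens) <= 0):
            raise ValueError("insert densities must be non-negative and strictly increasing")
        if self.insert_radius <= 0:
            raise ValueError("insert radius must be positive")
        centers = self.insert_centers
        if not centers:
            # Default layout: a single row, 3 diameters apart.
            pitch = 3.0 * self.insert_radius
            n = dens.size
            xs = pitch * (np.arange(n) - (n - 1) / 2.0)
            centers = tuple((float(x), 0.0) for x in xs)
            object.__setattr__(self, "insert_centers", centers)
        if len(centers) != dens.size:
            raise ValueError("one center per insert required")
        pts = np.asarray(centers, dtype=float)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.hypot(*(pts[i] - pts[j])) <= 2 * self.insert_radius:
                    raise ValueError("insert centers must be separated by > 2·radius")

    @property
    def n_inserts(self) -> int:
        return len(self.insert_densities)


def six_insert_phantom(**kwargs) -> PhantomSpec:
    """The broad-range phantom: 0–800 mg HA/cm³ in 6 inserts."""
    return PhantomSpec(insert_densities=(0.0, 100.0, 200.0, 400.0, 600.0, 800.0), **kwargs)


def three_insert_phantom(**kwargs) -> PhantomSpec:
    """The compact clinical phantom: 300–800 mg HA/cm³ in 3 inserts."""
    return PhantomSpec(insert_densities=(300.0, 550.0, 800.0), **kwargs)


@dataclass(frozen=True)
class SubjectSpec:
    """A simplified subject: an elliptical soft-tissue cross-section with a
    cylindrical bone region of known true density.

    The bone cylinder (center (x, y) mm, radius mm) must lie inside the
    body ellipse given by ``body_half_axes`` (a, b) in mm.
    """

    weight: float = 78.0
    height: float = 1.75
    body_half_axes: tuple[float, float] = (160.0, 110.0)
    bone_center: tuple[float, float] = (40.0, 10.0)
    bone_radius: float = 20.0
    true_bmd: float = 400.0
    soft_tissue_hu: float = 40.0

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")
        if self.true_bmd < 0:
            raise ValueError("true_bmd must be non-negative")
        a, b = self.body_half_axes
        cx, cy = self.bone_center
        r = self.bone_radius
        # The bone circle must fit inside the ellipse; conservative check on
        # the scaled radial coordinate of the farthest bone-circle point.
        if r <= 0 or a <= 0 or b <= 0:
            raise ValueError("non-positive geometry")
        u = np.hypot((abs(cx) + r) / a, (abs(cy) + r) / b)
        if u >= 1.0:
            raise ValueError("bone region extends outside the body ellipse")
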