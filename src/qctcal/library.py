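"""On-disk phantom-scan library.

A library is a directory with one measurement CSV and one metadata JSON
per phantom scan, sharing a basename: ``<name>.csv`` + ``<name>.json``.
The CSV columns mirror :class:`~qctcal.detection.InsertMeasurement`.
"""

from __future__ import annotations

import json
import os

import pandas as pd

from .calibration import PhantomScan
from .detection import InsertMeasurement
from .metadata import ScanMetadata

__all__ = ["measurements_to_frame", "save_phantom_scan", "load_phantom_library"]

_COLUMNS = [
    "insert_id",
    "nominal_density",
    "center_x_mm",
    "center_y_mm",
    "roi_radius_mm",
    "mean_hu",
    "voxel_count",
]


def measurements_to_frame(measurements: list[InsertMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "insert_id": range(len(measurements)),
            "nominal_density": [m.nominal_density for m in measurements],
            "center_x_mm": [m.center[0] for m in measurements],
            "center_y_mm": [m.center[1] for m in measurements],
            "roi_radius_mm": [m.roi_radius for m in measurements],
            "mean_hu": [m.mean_hu for m in measurements],
            "voxel_count": [m.voxel_count for m in measurements],
        }
    )


def save_phantom_scan(directory: str | os.PathLike, name: str, scan: PhantomScan) -> None:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    measurements_to_frame(scan.measurements).to_csv(
        os.path.join(directory, f"{name}.csv"), index=False
    )
    with open(os.path.join(directory, f"{name}.json"), "w") as fh:
        json.dump(scan.meta.to_dict(), fh, indent=2)


def _frame_to_measurements(df: pd.DataFrame) -> list[InsertMeasurement]:
    out = []
    for _, row in df.iterrows():
        out.append(
            InsertMeasurement(
                center=(float(row["center_x_mm"]), float(row["center_y_mm"])),
                detected_radius=float(row["roi_radius_mm"]) / 0.8,
                roi_radius=float(row["roi_radius_mm"]),
                mean_hu=float(row["mean_hu"]),
                voxel_count=int(row["voxel_count"]),
                slice_range=(0, 0),
                nominal_density=float(row["nominal_density"]),
            )
        )
    return out


def load_phantom_library(directory: str | os.PathLike) -> list[PhantomScan]:
    """Load every ``<name>.csv`` + ``<name>.json`` pair, sorted by name."""
    directory = os.fspath(directory)
    scans = []
    for fname in sorted(os.listdir(directory)):
        if not fname.endswith(".csv"):
            continue
        name = fname[:-4]
        meta_path = os.path.join(directory, f"{name}.json")
        if not os.path.exists(meta_path):
            continue
        with open(meta_path) as fh:
            meta = ScanMetadata.from_dict(json.load(fh))
        df = pd.read_csv(os.path.join(directory, fname))
        scans.append(PhantomScan(meta=meta, measurements=_frame_to_measurements(df)))
    if not scans:
        raise FileNotFoundError(f"no phantom scans found in {directory}")
    return scans
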