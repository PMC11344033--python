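"""Acquisition metadata attached to every scan.

Table height follows the scanner convention: the distance from the
isocenter to the tabletop, positive below the isocenter.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict

__all__ = ["ScanMetadata"]


@dataclass(frozen=True)
class ScanMetadata:
    """Descriptors of a CT acquisition used for reference matching.

    Attributes
    ----------
    scanner_id : str
        Identifier of the CT scanner.
    voltage : float
        Tube voltage in kVp. Must match between case and reference phantom.
    protocol_id : str
        Acquisition protocol label.
    kernel : str
        Reconstruction kernel (e.g. a bone/sharp vs soft-tissue/smooth filter).
    table_height : float
        Isocenter-to-tabletop distance in mm, positive below the isocenter.
    date : datetime.date
        Acquisition date.
    voxel_size : tuple of float
        (dx, dy, dz) in mm.
    """

    scanner_id: str = "CT1"
    voltage: float = 120.0
    protocol_id: str = "default"
    kernel: str = "bone"
    table_height: float = 160.0
    date: _dt.date = _dt.date(2022, 1, 1)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if isinstance(self.date, str):
            object.__setattr__(self, "date", _dt.date.fromisoformat(self.date))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["date"] = self.date.isoformat()
        d["voxel_size"] = list(self.voxel_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanMetadata":
        d = dict(d)
        if isinstance(d.get("date"), str):
            d["date"] = _dt.date.fromisoformat(d["date"])
        if "voxel_size" in d:
            d["voxel_size"] = tuple(d["voxel_size"])
        return cls(**d)
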