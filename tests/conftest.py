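import numpy as np
import pytest

from qctcal import ScanMetadata, six_insert_phantom
from qctcal.detection import DetectedCircle, measure_inserts
from qctcal.studies import quiet_truth


@pytest.fixture
def phantom6():
    return six_insert_phantom()


@pytest.fixture
def meta():
    return ScanMetadata()


@pytest.fixture
def truth_off():
    """Acquisition truth with all confounders and noise switched off."""
    return quiet_truth()


def circles_from_truth(table, radius_scale: float = 1.0):
    """Detection-free oracle circles straight from a ground-truth table."""
    return [
        DetectedCircle(
            center=(row["center_x_mm"], row["center_y_mm"]),
            radius=row["radius_mm"] * radius_scale,
            score=1.0,
            nominal_density=row["density"],
        )
        for _, row in table.iterrows()
    ]


def measure_from_truth(volume, table, spec, **kwargs):
    """Measure inserts using ground-truth geometry instead of detection."""
    return measure_inserts(volume, circles_from_truth(table), spec, **kwargs)


@pytest.fixture
def gt_measure():
    return measure_from_truth
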