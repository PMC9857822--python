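from datetime import datetime

import numpy as np
import pytest

from spectquant.quantify import (
    ActivityRecord,
    PatientPhysiology,
    SuvVolume,
    VoxelGrid,
)

T0 = datetime(2022, 6, 1, 9, 0, 0)


@pytest.fixture
def male_80_180():
    return PatientPhysiology(weight_kg=80.0, height_cm=180.0, sex="male")


@pytest.fixture
def coincident_record():
    """All four timestamps equal: every decay factor is exactly 1."""
    return ActivityRecord(measured_activity_MBq=800.0, residual_activity_MBq=40.0,
                          measured_time=T0, administered_time=T0,
                          postinjection_time=T0, scan_time=T0)


def make_suv_volume(values, voxel_size_mm=4.0, origin=(0.0, 0.0, 0.0)):
    return SuvVolume(values=np.asarray(values, dtype=float),
                     voxel_size_mm=voxel_size_mm, origin_mm=np.asarray(origin))


def make_grid(values, voxel_size_mm=4.0, origin=(0.0, 0.0, 0.0)):
    return VoxelGrid(values=np.asarray(values, dtype=float),
                     voxel_size_mm=voxel_size_mm, origin_mm=np.asarray(origin))


@pytest.fixture
def uniform_volume():
    """16^3 grid at 4 mm filled with SUV 7."""
    return make_suv_volume(np.full((16, 16, 16), 7.0))
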