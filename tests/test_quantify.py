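"""SUV_lbm conversion chain and VOI statistics, checked against closed forms
and brute-force oracles."""

import math
from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectquant.quantify import (
    ActivityRecord,
    LesionMeasurement,
    PatientPhysiology,
    QuantificationError,
    SphereVoi,
    actual_activity,
    compute_lbm,
    decay_factor,
    decay_lambda,
    measure_lesion,
    normal_tissue_suv,
    suv_max,
    suv_peak,
    tln_ratio,
    to_suv_volume,
)

from conftest import T0, make_grid, make_suv_volume

HALF_LIFE = 6.0067


# ---------------------------------------------------------------------------
# Lean body mass
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sex, weight, height, expected",
    [
        # direct evaluation of the sex-specific James formulas
        ("male", 80.0, 180.0, 1.10 * 80 - 120 * (80 / 180) ** 2),       # 64.296
        ("female", 60.0, 165.0, 1.07 * 60 - 148 * (60 / 165) ** 2),     # 44.630
    ],
)
def test_lbm_golden_values(sex, weight, height, expected):
    phys = PatientPhysiology(weight_kg=weight, height_cm=height, sex=sex)
    assert compute_lbm(phys) == pytest.approx(expected, abs=1e-9)
    assert compute_lbm(phys) == pytest.approx(
        {"male": 64.296, "female": 44.630}[sex], abs=5e-4)


def test_lbm_zero_weight_limit():
    phys = PatientPhysiology(weight_kg=0.0, height_cm=180.0, sex="male",
                             allow_out_of_range=True)
    assert compute_lbm(phys) == 0.0


def test_lbm_nonpositive_rejected_with_inputs_named():
    # extreme weight-to-height ratio drives the estimate negative
    phys = PatientPhysiology(weight_kg=290.0, height_cm=110.0, sex="male")
    with pytest.raises(QuantificationError, match="290"):
        compute_lbm(phys)


def test_physiology_sanity_bounds():
    with pytest.raises(QuantificationError):
        PatientPhysiology(weight_kg=10.0, height_cm=180.0, sex="male")
    with pytest.raises(QuantificationError):
        PatientPhysiology(weight_kg=80.0, height_cm=90.0, sex="female")
    PatientPhysiology(weight_kg=10.0, height_cm=180.0, sex="male",
                      allow_out_of_range=True)


# ---------------------------------------------------------------------------
# Decay cascade
# ---------------------------------------------------------------------------

def test_decay_factor_identity_and_half_life():
    lam = decay_lambda(HALF_LIFE)
    assert decay_factor(lam, 0.0) == 1.0
    # one half-life backwards in time halves the activity; with the
    # 0.693-based lambda the exact value is exp(-0.693) = 0.500074
    assert decay_factor(lam, -HALF_LIFE) == pytest.approx(math.exp(-0.693),
                                                          rel=1e-12)
    assert decay_factor(lam, -HALF_LIFE) == pytest.approx(0.5000, abs=1e-4)


@settings(max_examples=50, deadline=None)
@given(a=st.floats(-10, 10), b=st.floats(-10, 10))
def test_decay_factor_composition(a, b):
    lam = decay_lambda(HALF_LIFE)
    assert decay_factor(lam, a) * decay_factor(lam, b) == pytest.approx(
        decay_factor(lam, a + b), rel=1e-12)


def test_actual_activity_all_timestamps_equal(coincident_record):
    assert actual_activity(coincident_record) == pytest.approx(760.0)


def test_actual_activity_decays_to_scan_time():
    rec = ActivityRecord(800.0, 40.0, T0, T0, T0,
                         T0 + timedelta(hours=HALF_LIFE))
    assert actual_activity(rec) == pytest.approx(760.0 * math.exp(-0.693),
                                                 rel=1e-9)
    assert actual_activity(rec) == pytest.approx(380.0, abs=0.1)


def test_actual_activity_no_residual_upper_dose():
    rec = ActivityRecord(740.0, 0.0, T0, T0, T0, T0)
    assert actual_activity(rec) == pytest.approx(740.0)


def test_actual_activity_negative_net_rejected():
    # residual back-decayed over many half-lives exceeds the measurement
    rec = ActivityRecord(100.0, 90.0, T0, T0,
                         T0 + timedelta(hours=4 * HALF_LIFE), T0)
    with pytest.raises(QuantificationError, match="exceeds measured"):
        actual_activity(rec)


def test_activity_record_invariants():
    with pytest.raises(QuantificationError):
        ActivityRecord(100.0, 110.0, T0, T0, T0, T0)  # residual > measured
    with pytest.raises(QuantificationError):
        ActivityRecord(100.0, 0.0, T0 + timedelta(hours=1), T0, T0, T0)
    with pytest.raises(QuantificationError):
        ActivityRecord(100.0, 0.0, T0, T0 + timedelta(hours=2), T0,
                       T0 + timedelta(hours=1))


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

def test_suv_conversion_worked_example(male_80_180):
    # numeric-hour timestamps: actual activity exactly 380 MBq
    rec = ActivityRecord(380.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    grid = make_grid(np.full((8, 8, 8), 5000.0))
    suv = to_suv_volume(grid, male_80_180, rec)
    lbm = compute_lbm(male_80_180)
    expected = 5000.0 * lbm * 1000.0 / 380e6
    assert suv.values[0, 0, 0] == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.846, abs=5e-4)


def test_suv_conversion_linearity(male_80_180, coincident_record):
    grid = make_grid(np.random.default_rng(0).uniform(0, 1e4, (6, 6, 6)))
    suv = to_suv_volume(grid, male_80_180, coincident_record)
    doubled = make_grid(2 * grid.values)
    suv2 = to_suv_volume(doubled, male_80_180, coincident_record)
    np.testing.assert_allclose(suv2.values, 2 * suv.values, rtol=1e-12)
    zero = to_suv_volume(make_grid(np.zeros((6, 6, 6))), male_80_180,
                         coincident_record)
    assert np.all(zero.values == 0)


def test_suv_scales_with_lbm_and_activity(coincident_record):
    grid = make_grid(np.full((4, 4, 4), 1000.0))
    light = PatientPhysiology(60.0, 180.0, "male")
    # doubling actual activity halves SUV
    rec_double = ActivityRecord(1600.0, 80.0, T0, T0, T0, T0)
    s1 = to_suv_volume(grid, light, coincident_record).values[0, 0, 0]
    s2 = to_suv_volume(grid, light, rec_double).values[0, 0, 0]
    assert s1 == pytest.approx(2 * s2, rel=1e-12)


# ---------------------------------------------------------------------------
# SUVmax / SUVpeak against brute-force oracles
# ---------------------------------------------------------------------------

def _brute_suv_max(vol, voi):
    best = None
    c = np.asarray(voi.center_mm)
    for idx in np.ndindex(vol.shape):
        pos = vol.origin_mm + np.array(idx) * vol.voxel_size_mm
        if np.sum((pos - c) ** 2) <= voi.radius_mm**2:
            v = vol.values[idx]
            best = v if best is None else max(best, v)
    return best


def _brute_suv_peak(vol, voi, kernel_volume_cm3=1.0):
    r_k = (3 * kernel_volume_cm3 * 1000 / (4 * math.pi)) ** (1 / 3)
    c = np.asarray(voi.center_mm)
    centers = []
    for idx in np.ndindex(vol.shape):
        pos = vol.origin_mm + np.array(idx) * vol.voxel_size_mm
        if np.sum((pos - c) ** 2) <= voi.radius_mm**2:
            centers.append(pos)
    best = None
    for pos in centers:
        members = []
        for idx in np.ndindex(vol.shape):
            q = vol.origin_mm + np.array(idx) * vol.voxel_size_mm
            if np.sum((q - pos) ** 2) <= r_k**2:
                members.append(vol.values[idx])
        mean = float(np.mean(members))
        best = mean if best is None else max(best, mean)
    return best


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_suv_max_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    vol = make_suv_volume(rng.uniform(0, 20, (10, 10, 10)))
    center = tuple(rng.uniform(8, 28, 3))
    voi = SphereVoi(center, radius_mm=float(rng.uniform(5, 12)))
    assert suv_max(vol, voi) == pytest.approx(_brute_suv_max(vol, voi))


@pytest.mark.parametrize("seed", [3, 4])
def test_suv_peak_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    vol = make_suv_volume(rng.uniform(0, 20, (10, 10, 10)))
    center = tuple(rng.uniform(12, 24, 3))
    voi = SphereVoi(center, radius_mm=float(rng.uniform(5, 10)))
    assert suv_peak(vol, voi) == pytest.approx(_brute_suv_peak(vol, voi))


def test_uniform_field_peak_equals_max(uniform_volume):
    voi = SphereVoi((32.0, 32.0, 32.0), 12.0)
    assert suv_max(uniform_volume, voi) == 7.0
    assert suv_peak(uniform_volume, voi) == pytest.approx(7.0)


def test_isolated_hot_voxel_dilutes_peak():
    values = np.ones((16, 16, 16))
    values[8, 8, 8] = 12.44
    vol = make_suv_volume(values)
    voi = SphereVoi((32.0, 32.0, 32.0), 10.0)
    assert suv_max(vol, voi) == 12.44
    assert suv_peak(vol, voi) < suv_max(vol, voi)


def test_peak_bounded_by_neighbourhood_max():
    rng = np.random.default_rng(7)
    vol = make_suv_volume(rng.uniform(0, 15, (12, 12, 12)))
    voi = SphereVoi((24.0, 24.0, 24.0), 8.0)
    # kernel support may extend ~6.2 mm beyond the VOI
    hull = SphereVoi((24.0, 24.0, 24.0), 8.0 + 6.21)
    assert suv_peak(vol, voi) <= suv_max(vol, hull) + 1e-12


def test_empty_voi_rejected(uniform_volume):
    with pytest.raises(QuantificationError, match="no voxel centers"):
        suv_max(uniform_volume, SphereVoi((500.0, 500.0, 500.0), 5.0))


def test_kernel_larger_than_grid_rejected():
    vol = make_suv_volume(np.ones((3, 3, 3)), voxel_size_mm=2.0)  # 6 mm extent
    with pytest.raises(QuantificationError, match="kernel diameter"):
        suv_peak(vol, SphereVoi((2.0, 2.0, 2.0), 3.0))


# ---------------------------------------------------------------------------
# Normal tissue reference and TL/N
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("level", [3.34, 8.01, 0.0])
def test_normal_tissue_suv_uniform_background(level):
    vol = make_suv_volume(np.full((16, 16, 16), level))
    assert normal_tissue_suv(vol, (32.0, 32.0, 32.0)) == pytest.approx(level)


def test_normal_tissue_sphere_must_stay_inside_grid():
    vol = make_suv_volume(np.ones((16, 16, 16)))
    with pytest.raises(QuantificationError, match="exits the grid"):
        normal_tissue_suv(vol, (2.0, 32.0, 32.0))


def test_tln_ratio():
    assert tln_ratio(12.44, 3.34) == pytest.approx(12.44 / 3.34)  # 3.724
    assert tln_ratio(5.0, 5.0) == 1.0
    with pytest.raises(QuantificationError):
        tln_ratio(5.0, 0.0)


def test_measurement_without_reference_has_no_ratio(uniform_volume):
    voi = SphereVoi((32.0, 32.0, 32.0), 10.0, label="L1", site="lymph_node")
    m = measure_lesion(uniform_volume, voi, "L1")  # splenectomy: no reference
    assert m.tln_ratio is None
    m2 = measure_lesion(uniform_volume, voi, "L1", reference_suv=3.5)
    assert m2.tln_ratio == pytest.approx(2.0)


def test_lesion_measurement_invariant():
    with pytest.raises(QuantificationError):
        LesionMeasurement("x", suv_max=5.0, suv_peak=6.0)
    with pytest.raises(QuantificationError):
        LesionMeasurement("x", suv_max=5.0, suv_peak=4.0, tln_ratio=-1.0)


# ---------------------------------------------------------------------------
# peak <= max on lesion-like fields
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_peak_never_exceeds_max_on_lesion_fields(seed):
    """For VOIs that contain their local hot spot (the lesion reading), the
    kernel average cannot exceed the hottest voxel."""
    rng = np.random.default_rng(seed)
    values = np.ones((16, 16, 16))
    # hot blob inside the VOI
    values[6:10, 6:10, 6:10] = rng.uniform(5, 15, (4, 4, 4))
    vol = make_suv_volume(values)
    voi = SphereVoi((30.0, 30.0, 30.0), 14.0)
    assert suv_peak(vol, voi) <= suv_max(vol, voi) + 1e-12
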