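"""Synthetic-data generator: ground-truth construction, determinism and
calibration of the sampled uptake distributions."""

import numpy as np
import pandas as pd
import pytest

from spectquant.calibration import accuracy
from spectquant.quantify import suv_max, suv_peak, to_suv_volume
from spectquant.synthetic import (
    DEFAULT_METASTASIS_SUVMAX,
    GeneratorConfig,
    LesionSpec,
    PhantomSpec,
    ScanPlan,
    SyntheticDataError,
    TrajectorySpec,
    cohort14_plan,
    generate_cohort,
    generate_patient_volume,
    generate_phantom,
    nema_six_sphere_phantom,
    sample_suv_pairs,
    sample_truncated_suv,
)

CFG_NOISELESS = GeneratorConfig(seed=1, grid_shape=(32, 32, 32), noise_cv=0.0)
CENTER = (64.0, 64.0, 64.0)


# ---------------------------------------------------------------------------
# Patient volumes
# ---------------------------------------------------------------------------

def test_noise_free_volume_recovers_true_suv_exactly():
    lesion = LesionSpec(CENTER, radius_mm=9.0, true_suv=10.0, site="liver")
    bundle = generate_patient_volume(CFG_NOISELESS, [lesion])
    suv = to_suv_volume(bundle.activity, bundle.physiology,
                        bundle.activity_record)
    # every voxel whose center lies in the sphere maps back to SUV 10 exactly
    inside = bundle.suv_truth.values == 10.0
    assert inside.sum() == bundle.truth["n_voxels"].iloc[0]
    np.testing.assert_allclose(suv.values[inside], 10.0, rtol=1e-12)
    assert suv_max(suv, bundle.lesion_vois[0]) == pytest.approx(10.0, rel=1e-12)


def test_volume_generation_is_deterministic():
    cfg = GeneratorConfig(seed=7, grid_shape=(32, 32, 32), noise_cv=0.05)
    lesion = LesionSpec(CENTER, radius_mm=9.0, true_suv=8.0, site="bone")
    a = generate_patient_volume(cfg, [lesion]).activity.values
    b = generate_patient_volume(cfg, [lesion]).activity.values
    assert np.array_equal(a, b)


def test_overlapping_lesions_rejected_with_pair_named():
    lesions = [LesionSpec(CENTER, 9.0, 10.0, site="liver"),
               LesionSpec((70.0, 64.0, 64.0), 9.0, 5.0, site="bone")]
    with pytest.raises(SyntheticDataError, match="0.*and 1.*overlap"):
        generate_patient_volume(CFG_NOISELESS, lesions)


def test_lesion_must_fit_in_grid():
    with pytest.raises(SyntheticDataError, match="exits the grid"):
        generate_patient_volume(
            CFG_NOISELESS, [LesionSpec((4.0, 64.0, 64.0), 9.0, 10.0)])


def test_two_compartment_lesion_hits_requested_peak():
    lesion = LesionSpec(CENTER, radius_mm=9.0, true_suv=12.44, site="liver",
                        true_peak=10.15)
    bundle = generate_patient_volume(CFG_NOISELESS, [lesion])
    suv = to_suv_volume(bundle.activity, bundle.physiology,
                        bundle.activity_record)
    voi = bundle.lesion_vois[0]
    assert suv_max(suv, voi) == pytest.approx(12.44, rel=1e-12)
    assert suv_peak(suv, voi) == pytest.approx(10.15, rel=1e-9)
    assert bundle.truth["true_suv_peak"].iloc[0] == pytest.approx(10.15, rel=1e-9)


def test_two_compartment_infeasible_rim_rejected():
    # requested kernel mean so low the rim would fall below background
    lesion = LesionSpec(CENTER, radius_mm=9.0, true_suv=12.0, true_peak=1.2)
    with pytest.raises(SyntheticDataError, match="rim uptake"):
        generate_patient_volume(CFG_NOISELESS, [lesion])


def test_generator_config_validation():
    with pytest.raises(SyntheticDataError):
        GeneratorConfig(noise_cv=1.5)
    with pytest.raises(SyntheticDataError):
        GeneratorConfig(voxel_size_mm=-1.0)
    with pytest.raises(SyntheticDataError):
        GeneratorConfig(grid_shape=(2, 64, 64))  # thinner than the peak kernel


# ---------------------------------------------------------------------------
# Calibrated distributions
# ---------------------------------------------------------------------------

def test_truncated_normal_recovers_target_mean():
    """Post-truncation sample mean converges to the configured mean."""
    rng = np.random.default_rng(11)
    mean, sd = DEFAULT_METASTASIS_SUVMAX["liver"]
    sample = sample_truncated_suv(rng, mean, sd, 500)
    assert np.all(sample > 0)
    se = sd / np.sqrt(500)
    assert abs(sample.mean() - mean) < 3 * se


def test_truncated_normal_heavy_truncation_calibrated():
    # lymph-node row: sigma comparable to mu, truncation bites hard
    rng = np.random.default_rng(12)
    mean, sd = DEFAULT_METASTASIS_SUVMAX["lymph_node"]
    sample = sample_truncated_suv(rng, mean, sd, 2000)
    assert abs(sample.mean() - mean) < 3 * sample.std(ddof=1) / np.sqrt(2000)


def test_suv_pair_sampler_calibrated_and_feasible():
    rng = np.random.default_rng(13)
    pairs = sample_suv_pairs(rng, 4000, 12.44, 7.76, 10.15, 6.79, 0.982,
                             core_fraction=1 / 19, min_rim=1.0)
    smax, speak = pairs[:, 0], pairs[:, 1]
    assert np.all(speak <= smax)
    assert np.all((speak - smax / 19) / (1 - 1 / 19) >= 1.0 - 1e-9)
    assert abs(smax.mean() - 12.44) < 3 * 7.76 / np.sqrt(4000)
    assert abs(speak.mean() - 10.15) < 3 * 6.79 / np.sqrt(4000)
    assert np.corrcoef(smax, speak)[0, 1] > 0.95


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

def test_phantom_zero_deviation_identity():
    table = generate_phantom(nema_six_sphere_phantom(0.0), seed=3)
    np.testing.assert_allclose(table["measured_concentration"],
                               table["true_concentration"], rtol=1e-15)


def test_phantom_bounded_deviation_bounds_accuracy():
    table = generate_phantom(nema_six_sphere_phantom(0.05), seed=5)
    for _, row in table.iterrows():
        acc = accuracy(row["true_concentration"], row["measured_concentration"])
        assert acc >= 95.0


def test_phantom_deterministic():
    a = generate_phantom(nema_six_sphere_phantom(0.05), seed=9)
    b = generate_phantom(nema_six_sphere_phantom(0.05), seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_phantom_overlapping_spheres_rejected():
    with pytest.raises(SyntheticDataError, match="overlap"):
        PhantomSpec(sphere_specs=(((0, 0, 0), 10.0, 1000.0),
                                  ((5, 0, 0), 10.0, 1000.0)))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def test_empty_cohort():
    bundle = generate_cohort(seed=0, n_patients=0, outcome_plan=[])
    assert len(bundle.patients) == 0 and len(bundle.lesions) == 0
    assert "suv_max" in bundle.lesions.columns


def test_cohort_summed_suvmax_matches_plan_exactly():
    plan = [TrajectorySpec("P1", (ScanPlan(0.65),), n_baseline_lesions=5)]
    bundle = generate_cohort(seed=2, n_patients=1, outcome_plan=plan)
    by_scan = bundle.lesions.groupby("scan_id")["suv_max"].sum()
    assert by_scan["P1_scan1"] == pytest.approx(0.65 * by_scan["P1_scan0"],
                                                rel=1e-9)


def test_cr_plan_with_residual_uptake_rejected():
    with pytest.raises(SyntheticDataError, match="CR"):
        ScanPlan(multiplier=0.65, expected="CR")


def test_cohort_deterministic():
    plan = cohort14_plan()
    a = generate_cohort(1, 14, plan)
    b = generate_cohort(1, 14, plan)
    pd.testing.assert_frame_equal(a.lesions, b.lesions)
    pd.testing.assert_frame_equal(a.patients, b.patients)


def test_ki67_independent_of_suv():
    """ki67 is sampled independently of lesion uptake (null correlation)."""
    bundle = generate_cohort(seed=21, n_patients=300)
    mean_suv = bundle.lesions.groupby("patient_id")["suv_max"].mean()
    merged = bundle.patients.set_index("patient_id").join(
        mean_suv.rename("mean_suv"))
    r = np.corrcoef(merged["ki67_pct"], merged["mean_suv"])[0, 1]
    assert abs(r) < 3 / np.sqrt(len(merged))  # ~0.17 at n=300


def test_new_lesions_only_where_planned():
    plan = [TrajectorySpec("P1", (ScanPlan(0.8, new_lesions=2),
                                  ScanPlan(1.0)))]
    bundle = generate_cohort(seed=5, n_patients=1, outcome_plan=plan)
    new_by_scan = bundle.lesions.groupby("scan_id")["is_new"].sum()
    assert new_by_scan["P1_scan1"] == 2
    assert new_by_scan["P1_scan2"] == 0
    flags = bundle.scans.set_index("scan_id")["new_lesion_flag"]
    assert bool(flags["P1_scan1"]) and not bool(flags["P1_scan2"])
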