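"""Synthetic data for the quantitative SPECT/CT pipeline.

Everything the pipeline consumes can be generated here with known ground
truth: single-patient activity volumes with spherical lesions, hot-sphere
calibration phantoms, and longitudinal patient cohorts with prescribed
response trajectories.  Defaults are calibrated to reported
somatostatin-receptor (⁹⁹ᵐTc-EDDA/HYNIC-TOC) SPECT/CT cohort statistics in
neuroendocrine-tumour patients, so parameter-recovery tests run against
realistic uptake levels.

Lesions are uniform-uptake spheres (voxel-center membership), which makes
the true SUVmax analytically known.  A lesion may optionally carry a target
1-cm³ kernel mean (``true_peak``); it is then built as a two-compartment
sphere — a single hot core voxel at ``true_suv`` inside a cooler rim whose
uptake is solved from the discrete kernel geometry so the best kernel
placement recovers ``true_peak`` exactly in the noise-free volume.

Site-stratified SUV distributions are truncated normals (support > 0) whose
location parameter is re-calibrated numerically so the *post-truncation*
mean equals the requested mean; recovery targets therefore refer to the
mean actually generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import truncnorm

from .quantify import (
    ActivityRecord,
    PatientPhysiology,
    SphereVoi,
    SuvVolume,
    VoxelGrid,
    actual_activity,
    compute_lbm,
    kernel_offsets,
    sphere_indices,
    suv_peak,
)

# ---------------------------------------------------------------------------
# Reported cohort statistics used as generator defaults (mean, SD)
# ---------------------------------------------------------------------------

#: Metastasis SUVmax (g/mL) by site.
DEFAULT_METASTASIS_SUVMAX = {
    "liver": (12.44, 7.76),
    "lymph_node": (11.98, 10.45),
    "bone": (5.90, 3.68),
}

#: Healthy reference-tissue SUVmax (g/mL); the reference for lymph-node
#: metastases is the spleen, for bone the normal vertebra.
DEFAULT_HEALTHY_SUVMAX = {
    "liver": (3.34, 0.93),
    "spleen": (8.01, 5.31),
    "vertebra": (0.66, 0.37),
}

#: Target-lesion to normal-tissue ratio by metastasis site.
DEFAULT_TLN = {
    "liver": (4.20, 2.67),
    "lymph_node": (1.84, 1.53),
    "bone": (9.37, 2.91),
}

#: Metastasis SUVpeak (g/mL) by site.
DEFAULT_METASTASIS_SUVPEAK = {
    "liver": (10.15, 6.79),
    "lymph_node": (8.81, 7.99),
    "bone": (5.55, 2.47),
}

#: Pearson correlation between per-lesion SUVmax and SUVpeak, by site.
DEFAULT_SUV_CORRELATION = {"liver": 0.982, "lymph_node": 0.980, "bone": 0.920}

#: ki67 proliferation index (%) across patients.
DEFAULT_KI67 = (7.0, 6.25)

#: Immunohistochemical / biochemical marker positivity probabilities.
DEFAULT_MARKER_POSITIVITY = {"CGA": 0.857, "SYN": 0.929, "NSE": 0.214, "CD56": 0.143}

#: Lesion-level site frequencies (liver / lymph node / bone / other).
DEFAULT_SITE_FREQUENCIES = {"liver": 0.52, "lymph_node": 0.203, "bone": 0.057, "other": 0.22}

REFERENCE_SITE_FOR = {"liver": "liver", "lymph_node": "spleen", "bone": "vertebra"}


class SyntheticDataError(ValueError):
    """Raised for invalid generator specifications."""


# ---------------------------------------------------------------------------
# Configuration and specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Voxel geometry and noise settings for synthetic volumes.

    ``noise_cv`` is the coefficient of variation of multiplicative Gaussian
    voxel noise (mean 1, clipped at 0); 0 disables noise.
    """

    seed: int = 0
    voxel_size_mm: float = 4.0
    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    background_uptake: float = 1.0
    noise_cv: float = 0.02

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise SyntheticDataError("voxel size must be positive")
        if not (0 <= self.noise_cv < 1):
            raise SyntheticDataError("noise_cv must be in [0, 1)")
        if self.background_uptake < 0:
            raise SyntheticDataError("background uptake must be >= 0")
        kernel_diam_vox = 2 * 6.2035 / self.voxel_size_mm
        if any(d < kernel_diam_vox for d in self.grid_shape):
            raise SyntheticDataError(
                "grid dimensions must exceed the 1-cm^3 kernel diameter "
                f"({kernel_diam_vox:.1f} voxels)"
            )


@dataclass(frozen=True)
class LesionSpec:
    """Uniform-uptake spherical lesion with known true SUVmax.

    If ``true_peak`` is set the lesion is two-compartment (hot core voxel in
    a cooler rim) so that the noise-free 1-cm³ kernel mean equals
    ``true_peak``.
    """

    center_mm: Tuple[float, float, float]
    radius_mm: float
    true_suv: float
    site: str = "other"
    true_peak: Optional[float] = None

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise SyntheticDataError("lesion radius must be positive")
        if self.true_suv <= 0:
            raise SyntheticDataError("true_suv must be positive")
        if self.true_peak is not None and not (0 < self.true_peak <= self.true_suv):
            raise SyntheticDataError("true_peak must be in (0, true_suv]")


@dataclass(frozen=True)
class PhantomSpec:
    """Hot-sphere phantom: (center_mm, radius_mm, true_concentration Bq/mL)."""

    sphere_specs: Tuple[Tuple[Tuple[float, float, float], float, float], ...]
    background_concentration: float = 0.0
    measurement_deviation: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.measurement_deviation <= 1):
            raise SyntheticDataError("measurement_deviation must be in [0, 1]")
        if self.background_concentration < 0:
            raise SyntheticDataError("background concentration must be >= 0")
        specs = list(self.sphere_specs)
        for _, r, conc in specs:
            if conc < 0:
                raise SyntheticDataError("sphere concentrations must be >= 0")
            if r <= 0:
                raise SyntheticDataError("sphere radii must be positive")
        for i in range(len(specs)):
            for j in range(i + 1, len(specs)):
                ci, ri, _ = specs[i]
                cj, rj, _ = specs[j]
                d = math.dist(ci, cj)
                if d < ri + rj:
                    raise SyntheticDataError(f"phantom spheres {i} and {j} overlap")


def default_physiology() -> PatientPhysiology:
    return PatientPhysiology(weight_kg=78.0, height_cm=176.0, sex="male")


def default_activity_record(scan_delay_h: float = 4.0) -> ActivityRecord:
    """Typical administration: ~740 MBq measured, scan 4 h post-injection."""
    t0 = datetime(2022, 6, 1, 9, 0, 0)
    return ActivityRecord(
        measured_activity_MBq=740.0,
        residual_activity_MBq=25.0,
        measured_time=t0,
        administered_time=t0 + timedelta(minutes=10),
        postinjection_time=t0 + timedelta(minutes=12),
        scan_time=t0 + timedelta(minutes=10, hours=scan_delay_h),
    )


# ---------------------------------------------------------------------------
# Calibrated distributions
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _truncnorm_loc(mean: float, sd: float, lower: float = 0.0) -> float:
    """Location of a normal(loc, sd) truncated at ``lower`` whose
    post-truncation mean equals ``mean``."""
    if sd <= 0:
        raise SyntheticDataError("sd must be positive")
    if mean <= lower:
        raise SyntheticDataError("target mean must exceed the truncation bound")

    def post_mean(loc: float) -> float:
        a = (lower - loc) / sd
        return truncnorm.mean(a, np.inf, loc=loc, scale=sd)

    return float(optimize.brentq(lambda mu: post_mean(mu) - mean,
                                 mean - 10 * sd, mean + sd, xtol=1e-10))


def sample_truncated_suv(rng: np.random.Generator, mean: float, sd: float,
                         size: int, lower: float = 0.0) -> np.ndarray:
    """Draw from a truncated normal whose post-truncation mean is ``mean``."""
    loc = _truncnorm_loc(mean, sd, lower)
    a = (lower - loc) / sd
    return truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=size, random_state=rng)


def _pair_constraint(pairs: np.ndarray, core_fraction: float,
                     min_rim: float) -> np.ndarray:
    """Feasibility of (SUVmax, SUVpeak) pairs for a two-compartment lesion.

    ``core_fraction`` is the fraction of kernel voxels occupied by the hot
    core; the implied rim uptake must lie in [min_rim, max].
    """
    smax, speak = pairs[:, 0], pairs[:, 1]
    rim = (speak - core_fraction * smax) / (1.0 - core_fraction)
    return (smax > 0) & (speak > 0) & (speak <= smax) & (rim >= min_rim)


@lru_cache(maxsize=None)
def _calibrated_pair_loc(mean_max: float, sd_max: float, mean_peak: float,
                         sd_peak: float, rho: float, core_fraction: float,
                         min_rim: float) -> Tuple[float, float]:
    """Bivariate-normal location such that, after the feasibility
    constraints, the accepted-sample means equal the requested means.

    Fixed-point iteration against a large internal sample with a fixed
    internal seed; independent of user-facing randomness.
    """
    cov = np.array([
        [sd_max**2, rho * sd_max * sd_peak],
        [rho * sd_max * sd_peak, sd_peak**2],
    ])
    chol = np.linalg.cholesky(cov)
    cal_rng = np.random.default_rng(987654321)
    z = cal_rng.standard_normal((200_000, 2))
    base = z @ chol.T
    loc = np.array([mean_max, mean_peak], dtype=float)
    target = loc.copy()
    for _ in range(30):
        pairs = base + loc
        ok = _pair_constraint(pairs, core_fraction, min_rim)
        emp = pairs[ok].mean(axis=0)
        step = target - emp
        loc = loc + step
        if np.max(np.abs(step)) < 1e-4:
            break
    return float(loc[0]), float(loc[1])


def sample_suv_pairs(rng: np.random.Generator, n: int, mean_max: float,
                     sd_max: float, mean_peak: float, sd_peak: float,
                     rho: float, core_fraction: float,
                     min_rim: float = 0.0) -> np.ndarray:
    """Sample n feasible (SUVmax, SUVpeak) pairs with calibrated means.

    Rejection sampling from a correlated bivariate normal whose location was
    shifted so the accepted pairs average to (mean_max, mean_peak).
    """
    loc = np.array(_calibrated_pair_loc(mean_max, sd_max, mean_peak, sd_peak,
                                        rho, core_fraction, min_rim))
    cov = np.array([
        [sd_max**2, rho * sd_max * sd_peak],
        [rho * sd_max * sd_peak, sd_peak**2],
    ])
    chol = np.linalg.cholesky(cov)
    out = np.empty((0, 2))
    while len(out) < n:
        z = rng.standard_normal((max(2 * n, 64), 2))
        pairs = z @ chol.T + loc
        pairs = pairs[_pair_constraint(pairs, core_fraction, min_rim)]
        out = np.vstack([out, pairs])
    return out[:n]


# ---------------------------------------------------------------------------
# Patient volumes
# ---------------------------------------------------------------------------

@dataclass
class PatientVolumeBundle:
    """A synthetic activity volume with its paired records and ground truth."""

    activity: VoxelGrid                 # Bq/mL
    physiology: PatientPhysiology
    activity_record: ActivityRecord
    truth: pd.DataFrame                 # one row per lesion
    lesion_vois: List[SphereVoi]
    reference_vois: List[SphereVoi]
    suv_truth: SuvVolume                # noise-free SUV field


def _check_disjoint(specs: Sequence[LesionSpec]) -> None:
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            d = math.dist(specs[i].center_mm, specs[j].center_mm)
            if d < specs[i].radius_mm + specs[j].radius_mm:
                raise SyntheticDataError(
                    f"lesion spheres {i} ({specs[i].site}) and {j} "
                    f"({specs[j].site}) overlap (centre distance {d:.1f} mm)"
                )


def _paint_lesion(grid: VoxelGrid, spec: LesionSpec, background: float) -> dict:
    """Set lesion voxels in-place; returns ground-truth attributes."""
    idx = sphere_indices(grid, spec.center_mm, spec.radius_mm)
    if len(idx) == 0:
        raise SyntheticDataError(
            f"lesion at {spec.center_mm} (r={spec.radius_mm} mm) contains no voxel centers"
        )
    lower, upper = grid.bounding_box_mm()
    c = np.asarray(spec.center_mm, dtype=float)
    if np.any(c - spec.radius_mm < lower) or np.any(c + spec.radius_mm > upper):
        raise SyntheticDataError(f"lesion at {spec.center_mm} exits the grid")

    rim_suv = None
    if spec.true_peak is None:
        grid.values[idx[:, 0], idx[:, 1], idx[:, 2]] = spec.true_suv
    else:
        # Hot core = voxel nearest the lesion center; rim solves the
        # discrete kernel mean for the requested true_peak.
        core = np.rint((c - grid.origin_mm) / grid.voxel_size_mm).astype(int)
        offs = kernel_offsets(grid.voxel_size_mm, 1.0)
        n_k = len(offs)
        rim_suv = (n_k * spec.true_peak - spec.true_suv) / (n_k - 1)
        if rim_suv > spec.true_suv + 1e-12:
            raise SyntheticDataError("true_peak exceeds what a hot core allows")
        if rim_suv < background:
            raise SyntheticDataError(
                f"two-compartment lesion infeasible: rim uptake {rim_suv:.3f} "
                f"below background {background}"
            )
        grid.values[idx[:, 0], idx[:, 1], idx[:, 2]] = rim_suv
        grid.values[core[0], core[1], core[2]] = spec.true_suv
    return {"rim_suv": rim_suv, "n_voxels": len(idx)}


def generate_patient_volume(config: GeneratorConfig,
                            lesions: Sequence[LesionSpec],
                            reference_tissues: Sequence[LesionSpec] = (),
                            physiology: Optional[PatientPhysiology] = None,
                            activity_record: Optional[ActivityRecord] = None,
                            ) -> PatientVolumeBundle:
    """Build an activity-concentration volume (Bq/mL) with known lesions.

    The volume is constructed so that converting it back to SUV with the
    bundled physiology/activity record reproduces each lesion's ``true_suv``
    exactly in the noise-free case.
    """
    all_specs = list(lesions) + list(reference_tissues)
    _check_disjoint(all_specs)
    phys = physiology or default_physiology()
    rec = activity_record or default_activity_record()

    suv = SuvVolume(
        values=np.full(config.grid_shape, float(config.background_uptake)),
        voxel_size_mm=config.voxel_size_mm,
    )
    rows = []
    lesion_vois, reference_vois = [], []
    for k, spec in enumerate(all_specs):
        attrs = _paint_lesion(suv, spec, config.background_uptake)
        voi = SphereVoi(tuple(spec.center_mm), spec.radius_mm,
                        label=f"lesion_{k}", site=spec.site)
        is_lesion = k < len(lesions)
        (lesion_vois if is_lesion else reference_vois).append(voi)
        rows.append({
            "lesion_id": f"lesion_{k}",
            "site": spec.site,
            "is_reference": not is_lesion,
            "true_suv_max": spec.true_suv,
            "requested_peak": spec.true_peak,
            "rim_suv": attrs["rim_suv"],
            "n_voxels": attrs["n_voxels"],
            "center_x_mm": spec.center_mm[0],
            "center_y_mm": spec.center_mm[1],
            "center_z_mm": spec.center_mm[2],
            "radius_mm": spec.radius_mm,
        })
    truth = pd.DataFrame(rows)

    # Noise-free ground-truth SUVpeak evaluated on the clean field.
    peaks = []
    for voi in lesion_vois + reference_vois:
        peaks.append(suv_peak(suv, voi))
    truth["true_suv_peak"] = peaks

    noisy = suv.values
    if config.noise_cv > 0:
        rng = np.random.default_rng(config.seed)
        noise = np.clip(rng.normal(1.0, config.noise_cv, size=suv.values.shape), 0, None)
        noisy = suv.values * noise

    # SUV -> Bq/mL with the bundled conversion factor.
    bq_per_suv = actual_activity(rec) * 1e6 / (compute_lbm(phys) * 1000.0)
    activity = VoxelGrid(values=noisy * bq_per_suv,
                         voxel_size_mm=config.voxel_size_mm)
    return PatientVolumeBundle(activity=activity, physiology=phys,
                               activity_record=rec, truth=truth,
                               lesion_vois=lesion_vois,
                               reference_vois=reference_vois, suv_truth=suv)


# ---------------------------------------------------------------------------
# Calibration phantom
# ---------------------------------------------------------------------------

def nema_six_sphere_phantom(measurement_deviation: float = 0.05,
                            true_concentration: float = 30_000.0,
                            background_concentration: float = 3_000.0) -> PhantomSpec:
    """Conventional six-hot-sphere layout (10-37 mm diameters on a ring)."""
    diameters = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    ring_radius = 57.0
    spheres = []
    for k, d in enumerate(diameters):
        angle = 2 * math.pi * k / len(diameters)
        center = (ring_radius * math.cos(angle), ring_radius * math.sin(angle), 0.0)
        spheres.append((center, d / 2.0, true_concentration))
    return PhantomSpec(sphere_specs=tuple(spheres),
                       background_concentration=background_concentration,
                       measurement_deviation=measurement_deviation)


def generate_phantom(spec: PhantomSpec, seed: int) -> pd.DataFrame:
    """Simulate measured sphere concentrations.

    ``measured = true * (1 + delta)`` with ``delta ~ Uniform(-d, d)`` drawn
    independently per sphere, ``d = measurement_deviation``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k, (center, radius, true_conc) in enumerate(spec.sphere_specs):
        delta = rng.uniform(-spec.measurement_deviation, spec.measurement_deviation)
        measured = true_conc * (1.0 + delta)
        if measured < 0:
            raise SyntheticDataError("negative measured concentration")
        rows.append({
            "sphere_id": f"sphere_{k}",
            "radius_mm": radius,
            "true_concentration": true_conc,
            "measured_concentration": measured,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Longitudinal cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanPlan:
    """One follow-up scan: summed-SUVmax multiplier relative to baseline,
    number of new lesions, and (optionally) the response category the plan
    is meant to elicit, used for validation."""

    multiplier: float
    new_lesions: int = 0
    expected: Optional[str] = None

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise SyntheticDataError("multiplier must be >= 0")
        if self.new_lesions < 0:
            raise SyntheticDataError("new_lesions must be >= 0")
        if self.expected == "CR" and (self.multiplier > 0 or self.new_lesions > 0):
            raise SyntheticDataError(
                "trajectory requests CR while lesions retain uptake or new lesions appear"
            )


@dataclass(frozen=True)
class TrajectorySpec:
    """Per-patient longitudinal plan; multipliers are relative to baseline."""

    patient_id: str
    scan_plans: Tuple[ScanPlan, ...]
    n_baseline_lesions: int = 4

    def __post_init__(self) -> None:
        if self.n_baseline_lesions < 1:
            raise SyntheticDataError("need at least one baseline lesion")
        if len(self.scan_plans) < 1:
            raise SyntheticDataError("need at least one follow-up scan plan")


@dataclass
class CohortBundle:
    patients: pd.DataFrame
    scans: pd.DataFrame
    lesions: pd.DataFrame


_PATIENT_COLUMNS = ["patient_id", "sex", "weight_kg", "height_cm", "ki67_pct",
                    "CGA", "SYN", "NSE", "CD56"]
_SCAN_COLUMNS = ["patient_id", "scan_id", "scan_index", "new_lesion_flag",
                 "expected_category"]
_LESION_COLUMNS = ["patient_id", "scan_id", "lesion_id", "site", "suv_max",
                   "suv_peak", "is_new"]


def _sample_patient(rng: np.random.Generator, patient_id: str) -> dict:
    sex = "male" if rng.random() < 0.643 else "female"
    if sex == "male":
        weight = float(np.clip(rng.normal(80, 12), 50, 130))
        height = float(np.clip(rng.normal(177, 7), 155, 200))
    else:
        weight = float(np.clip(rng.normal(66, 11), 45, 110))
        height = float(np.clip(rng.normal(164, 7), 145, 190))
    row = {
        "patient_id": patient_id,
        "sex": sex,
        "weight_kg": round(weight, 1),
        "height_cm": round(height, 1),
        # ki67 sampled independently of every SUV draw
        "ki67_pct": float(np.clip(sample_truncated_suv(rng, *DEFAULT_KI67, 1)[0], 0, 100)),
    }
    for marker, p in DEFAULT_MARKER_POSITIVITY.items():
        row[marker] = bool(rng.random() < p)
    return row


def _sample_lesion_pair(rng: np.random.Generator, site: str) -> Tuple[float, float]:
    """(suv_max, suv_peak) for one lesion at a site (liver params for 'other')."""
    key = site if site in DEFAULT_METASTASIS_SUVMAX else "liver"
    m, s = DEFAULT_METASTASIS_SUVMAX[key]
    mp, sp = DEFAULT_METASTASIS_SUVPEAK[key]
    rho = DEFAULT_SUV_CORRELATION[key]
    pair = sample_suv_pairs(rng, 1, m, s, mp, sp, rho, core_fraction=1 / 19)[0]
    return float(pair[0]), float(pair[1])


def generate_cohort(seed: int, n_patients: int,
                    outcome_plan: Optional[Sequence[TrajectorySpec]] = None,
                    ) -> CohortBundle:
    """Generate a longitudinal cohort of patients, scans and lesion tables.

    Per-scan lesion SUVmax values are baseline values scaled uniformly by
    the plan multiplier, so the summed-SUVmax change matches the request
    exactly.  New lesions appear only on scans whose plan asks for them.
    """
    rng = np.random.default_rng(seed)
    if outcome_plan is None:
        outcome_plan = [
            TrajectorySpec(
                patient_id=f"P{i + 1:02d}",
                scan_plans=(ScanPlan(multiplier=float(rng.uniform(0.75, 1.25))),),
                n_baseline_lesions=int(rng.integers(2, 9)),
            )
            for i in range(n_patients)
        ]
    if len(outcome_plan) != n_patients:
        raise SyntheticDataError("outcome_plan length must equal n_patients")

    patients, scans, lesions = [], [], []
    site_names = list(DEFAULT_SITE_FREQUENCIES)
    site_probs = np.array(list(DEFAULT_SITE_FREQUENCIES.values()))
    site_probs = site_probs / site_probs.sum()

    for traj in outcome_plan:
        patients.append(_sample_patient(rng, traj.patient_id))
        baseline_scan = f"{traj.patient_id}_scan0"
        scans.append({"patient_id": traj.patient_id, "scan_id": baseline_scan,
                      "scan_index": 0, "new_lesion_flag": False,
                      "expected_category": None})
        base_rows = []
        for j in range(traj.n_baseline_lesions):
            site = str(rng.choice(site_names, p=site_probs))
            smax, speak = _sample_lesion_pair(rng, site)
            base_rows.append({
                "patient_id": traj.patient_id, "scan_id": baseline_scan,
                "lesion_id": f"{traj.patient_id}_L{j}", "site": site,
                "suv_max": smax, "suv_peak": speak, "is_new": False,
            })
        lesions.extend(base_rows)

        for s, plan in enumerate(traj.scan_plans, start=1):
            scan_id = f"{traj.patient_id}_scan{s}"
            scans.append({"patient_id": traj.patient_id, "scan_id": scan_id,
                          "scan_index": s, "new_lesion_flag": plan.new_lesions > 0,
                          "expected_category": plan.expected})
            for row in base_rows:
                lesions.append({
                    "patient_id": traj.patient_id, "scan_id": scan_id,
                    "lesion_id": row["lesion_id"], "site": row["site"],
                    "suv_max": row["suv_max"] * plan.multiplier,
                    "suv_peak": row["suv_peak"] * plan.multiplier,
                    "is_new": False,
                })
            for k in range(plan.new_lesions):
                site = str(rng.choice(site_names, p=site_probs))
                smax, speak = _sample_lesion_pair(rng, site)
                lesions.append({
                    "patient_id": traj.patient_id, "scan_id": scan_id,
                    "lesion_id": f"{traj.patient_id}_N{s}_{k}", "site": site,
                    "suv_max": smax, "suv_peak": speak, "is_new": True,
                })

    return CohortBundle(
        patients=pd.DataFrame(patients, columns=_PATIENT_COLUMNS),
        scans=pd.DataFrame(scans, columns=_SCAN_COLUMNS),
        lesions=pd.DataFrame(lesions, columns=_LESION_COLUMNS),
    )


def cohort14_plan() -> List[TrajectorySpec]:
    """14-patient preset: 9 SD / 2 PD / 3 PR final outcomes, including the
    four multi-follow-up trajectories (continuous PD; SD,SD,PR; PD,PR,SD;
    PD,SD) assessed against baseline, final category from the last scan."""
    plans = [
        # multi-follow-up patients
        TrajectorySpec("P01", (ScanPlan(1.40, expected="PD"),
                               ScanPlan(1.85, expected="PD"),
                               ScanPlan(2.40, expected="PD"))),
        TrajectorySpec("P02", (ScanPlan(1.10, expected="SD"),
                               ScanPlan(0.90, expected="SD"),
                               ScanPlan(0.65, expected="PR"))),
        TrajectorySpec("P03", (ScanPlan(1.50, expected="PD"),
                               ScanPlan(0.60, expected="PR"),
                               ScanPlan(0.90, expected="SD"))),
        TrajectorySpec("P04", (ScanPlan(1.40, expected="PD"),
                               ScanPlan(1.05, expected="SD"))),
        # single-follow-up patients: 1 PD (new lesions despite lower sums),
        # 7 SD, 2 PR
        TrajectorySpec("P05", (ScanPlan(0.80, new_lesions=2, expected="PD"),)),
        TrajectorySpec("P06", (ScanPlan(1.05, expected="SD"),)),
        TrajectorySpec("P07", (ScanPlan(0.95, expected="SD"),)),
        TrajectorySpec("P08", (ScanPlan(1.15, expected="SD"),)),
        TrajectorySpec("P09", (ScanPlan(0.85, expected="SD"),)),
        TrajectorySpec("P10", (ScanPlan(1.25, expected="SD"),)),
        TrajectorySpec("P11", (ScanPlan(0.75, expected="SD"),)),
        TrajectorySpec("P12", (ScanPlan(1.00, expected="SD"),)),
        TrajectorySpec("P13", (ScanPlan(0.60, expected="PR"),)),
        TrajectorySpec("P14", (ScanPlan(0.55, expected="PR"),)),
    ]
    return plans
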