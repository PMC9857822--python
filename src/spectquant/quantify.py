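"""Lean-body-mass SUV quantification for reconstructed SPECT/CT volumes.

Converts voxel activity concentrations (Bq/mL) to SUV_lbm (g/mL) using the
injected-dose decay cascade, and extracts per-VOI uptake statistics
(SUVmax, SUVpeak, healthy-tissue reference, target-to-normal ratio).

Conventions
-----------
* Voxel grids are isotropic; ``origin_mm`` is the world coordinate of the
  *center* of voxel ``(0, 0, 0)`` (the nibabel affine convention), so the
  center of voxel ``i`` is ``origin_mm + i * voxel_size_mm``.
* Sphere membership is by voxel-center inclusion: a voxel belongs to a
  sphere iff its center lies within the radius.  No partial-volume
  weighting is applied.
* Activities are stored in MBq and converted to Bq inside the SUV formula;
  concentrations are Bq/mL; SUV values are g/mL; times are absolute
  datetimes (or plain numbers interpreted as hours).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

#: Physical half-life of Tc-99m in hours (configurable per record).
TC99M_HALF_LIFE_H = 6.0067

#: Default SUVpeak kernel volume (cm^3).
PEAK_KERNEL_VOLUME_CM3 = 1.0

#: Radius of the 10-mm healthy-tissue reference sphere.
NORMAL_TISSUE_RADIUS_MM = 10.0

LESION_SITES = ("liver", "lymph_node", "bone", "spleen", "vertebra", "other")


class QuantificationError(ValueError):
    """Raised for invalid physiology, activity records or VOIs."""


# ---------------------------------------------------------------------------
# Patient physiology and lean body mass
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientPhysiology:
    """Weight (kg), height (cm) and sex, as used by the LBM estimate.

    ``allow_out_of_range`` bypasses the adult sanity bounds
    (20-300 kg, 100-250 cm) for deliberately extreme inputs.
    """

    weight_kg: float
    height_cm: float
    sex: str
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise QuantificationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.weight_kg < 0 or self.height_cm <= 0:
            raise QuantificationError("weight must be >= 0 and height > 0")
        if not self.allow_out_of_range:
            if not (20.0 <= self.weight_kg <= 300.0):
                raise QuantificationError(
                    f"weight {self.weight_kg} kg outside sanity bounds 20-300 kg "
                    "(set allow_out_of_range=True to override)"
                )
            if not (100.0 <= self.height_cm <= 250.0):
                raise QuantificationError(
                    f"height {self.height_cm} cm outside sanity bounds 100-250 cm "
                    "(set allow_out_of_range=True to override)"
                )


def compute_lbm(phys: PatientPhysiology) -> float:
    """Lean body mass in kg from the sex-specific James estimate.

    Males:   ``1.10 * w - 120 * (w / h)^2``
    Females: ``1.07 * w - 148 * (w / h)^2``

    with ``w`` in kg and ``h`` in cm.  A non-positive result (possible for
    extreme weight-to-height ratios) is rejected, except for the degenerate
    zero-weight limit which is exactly 0.
    """
    w, h = phys.weight_kg, phys.height_cm
    ratio2 = (w / h) ** 2
    if phys.sex == "male":
        lbm = 1.10 * w - 120.0 * ratio2
    else:
        lbm = 1.07 * w - 148.0 * ratio2
    if lbm < 0 or (lbm == 0 and w > 0):
        raise QuantificationError(
            f"non-positive LBM ({lbm:.3f} kg) for {phys.sex}, "
            f"weight={w} kg, height={h} cm"
        )
    return lbm


# ---------------------------------------------------------------------------
# Decay cascade and actual activity
# ---------------------------------------------------------------------------

def decay_lambda(half_life_h: float = TC99M_HALF_LIFE_H) -> float:
    """Decay constant lambda = 0.693 / half-life (per hour)."""
    if half_life_h <= 0:
        raise QuantificationError("half-life must be positive")
    return 0.693 / half_life_h


def decay_factor(lambda_per_h: float, delta_t_h: float) -> float:
    """exp(lambda * delta_t) with delta_t signed as written in each factor.

    decay1 uses (measured - administered), decay2 (postinjection - measured),
    decay-scan (administered - scan); negative delta_t decays forward in time.
    """
    return math.exp(lambda_per_h * delta_t_h)


def _hours(later, earlier) -> float:
    """Signed difference ``later - earlier`` in hours.

    Accepts datetimes or plain numbers already expressed in hours.
    """
    if isinstance(later, datetime) and isinstance(earlier, datetime):
        return (later - earlier) / timedelta(hours=1)
    if isinstance(later, datetime) or isinstance(earlier, datetime):
        raise QuantificationError("cannot mix datetime and numeric timestamps")
    return float(later) - float(earlier)


@dataclass(frozen=True)
class ActivityRecord:
    """Syringe activity measurements and the four timestamps of the protocol.

    ``measured_activity_MBq`` is the pre-injection syringe activity at
    ``measured_time``; ``residual_activity_MBq`` is the post-injection
    syringe remainder at ``postinjection_time``.  All activities in MBq.
    """

    measured_activity_MBq: float
    residual_activity_MBq: float
    measured_time: object
    administered_time: object
    postinjection_time: object
    scan_time: object
    half_life_h: float = TC99M_HALF_LIFE_H

    def __post_init__(self) -> None:
        if self.measured_activity_MBq < 0 or self.residual_activity_MBq < 0:
            raise QuantificationError("activities must be non-negative")
        if self.residual_activity_MBq > self.measured_activity_MBq:
            raise QuantificationError("residual activity exceeds measured activity")
        if self.half_life_h <= 0:
            raise QuantificationError("half-life must be positive")
        if _hours(self.administered_time, self.measured_time) < 0:
            raise QuantificationError("measured_time must not be after administered_time")
        if _hours(self.scan_time, self.administered_time) < 0:
            raise QuantificationError("administered_time must not be after scan_time")
        if _hours(self.postinjection_time, self.measured_time) < 0:
            raise QuantificationError("measured_time must not be after postinjection_time")


def actual_activity(rec: ActivityRecord) -> float:
    """Net injected activity decayed to scan time, in MBq.

    ``decay_scan * decay1 * (measured - decay2 * residual)`` where

    * ``decay1  = exp(lambda * (measured_time - administered_time))`` decays
      the syringe measurement forward to injection time,
    * ``decay2  = exp(lambda * (postinjection_time - measured_time))``
      back-corrects the residual to the measurement time,
    * ``decay_scan = exp(lambda * (administered_time - scan_time))`` decays
      the net injected activity to the scan.
    """
    lam = decay_lambda(rec.half_life_h)
    d1 = decay_factor(lam, _hours(rec.measured_time, rec.administered_time))
    d2 = decay_factor(lam, _hours(rec.postinjection_time, rec.measured_time))
    d_scan = decay_factor(lam, _hours(rec.administered_time, rec.scan_time))
    net = rec.measured_activity_MBq - d2 * rec.residual_activity_MBq
    if net < 0:
        raise QuantificationError(
            "net activity negative: back-decayed residual "
            f"({d2 * rec.residual_activity_MBq:.2f} MBq) exceeds measured "
            f"({rec.measured_activity_MBq:.2f} MBq)"
        )
    return d_scan * d1 * net


# ---------------------------------------------------------------------------
# Voxel volumes
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Isotropic voxel grid with world-coordinate geometry.

    ``values`` is a 3-D array; units depend on context (Bq/mL for activity
    volumes, g/mL for SUV volumes).
    """

    values: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.values.ndim != 3:
            raise QuantificationError("volume must be 3-D")
        if self.voxel_size_mm <= 0:
            raise QuantificationError("voxel size must be positive")
        if self.origin_mm.shape != (3,):
            raise QuantificationError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def voxel_center(self, index: Sequence[int]) -> np.ndarray:
        return self.origin_mm + np.asarray(index, dtype=float) * self.voxel_size_mm

    def bounding_box_mm(self) -> tuple:
        """(lower, upper) world-coordinate corners of the voxelized extent."""
        lower = self.origin_mm - 0.5 * self.voxel_size_mm
        upper = self.origin_mm + (np.array(self.shape) - 0.5) * self.voxel_size_mm
        return lower, upper


class SuvVolume(VoxelGrid):
    """Voxel grid of SUV_lbm values (g/mL)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise QuantificationError("SUV values must be non-negative")


def to_suv_volume(activity: VoxelGrid, phys: PatientPhysiology,
                  rec: ActivityRecord) -> SuvVolume:
    """Convert an activity-concentration volume (Bq/mL) to SUV_lbm (g/mL).

    ``SUV = C[Bq/mL] * LBM[kg] * 1000 / actual_activity[Bq]`` — linear in C.
    """
    a_mbq = actual_activity(rec)
    if a_mbq <= 0:
        raise QuantificationError("actual activity must be positive for SUV conversion")
    factor = compute_lbm(phys) * 1000.0 / (a_mbq * 1e6)
    return SuvVolume(values=activity.values * factor,
                     voxel_size_mm=activity.voxel_size_mm,
                     origin_mm=activity.origin_mm.copy())


# ---------------------------------------------------------------------------
# VOIs and uptake statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereVoi:
    """Spherical volume of interest in world coordinates (mm)."""

    center_mm: tuple
    radius_mm: float
    label: str = ""
    site: str = "other"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise QuantificationError("VOI radius must be positive")
        if self.site not in LESION_SITES:
            raise QuantificationError(f"unknown site {self.site!r}")


def sphere_indices(grid: VoxelGrid, center_mm, radius_mm: float) -> np.ndarray:
    """Indices (n, 3) of voxels whose centers lie inside the sphere."""
    center = np.asarray(center_mm, dtype=float)
    lo = np.maximum(
        np.floor((center - radius_mm - grid.origin_mm) / grid.voxel_size_mm), 0
    ).astype(int)
    hi = np.minimum(
        np.ceil((center + radius_mm - grid.origin_mm) / grid.voxel_size_mm) + 1,
        np.array(grid.shape),
    ).astype(int)
    if np.any(hi <= lo):
        return np.empty((0, 3), dtype=int)
    axes = [np.arange(lo[k], hi[k]) for k in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = grid.origin_mm + idx * grid.voxel_size_mm
    d2 = np.sum((centers - center) ** 2, axis=1)
    return idx[d2 <= radius_mm**2]


def suv_max(vol: VoxelGrid, voi: SphereVoi) -> float:
    """Maximum voxel value among voxel centers inside the VOI."""
    idx = sphere_indices(vol, voi.center_mm, voi.radius_mm)
    if len(idx) == 0:
        raise QuantificationError(
            f"VOI {voi.label or voi.center_mm} contains no voxel centers"
        )
    return float(vol.values[idx[:, 0], idx[:, 1], idx[:, 2]].max())


def _kernel_radius_mm(kernel_volume_cm3: float) -> float:
    return (3.0 * kernel_volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def kernel_offsets(voxel_size_mm: float, kernel_volume_cm3: float) -> np.ndarray:
    """Integer voxel offsets whose centers lie within the kernel radius."""
    r = _kernel_radius_mm(kernel_volume_cm3)
    m = int(math.floor(r / voxel_size_mm))
    rng = np.arange(-m, m + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    off = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    d2 = np.sum((off * voxel_size_mm) ** 2, axis=1)
    return off[d2 <= r**2]


def suv_peak(vol: VoxelGrid, voi: SphereVoi,
             kernel_volume_cm3: float = PEAK_KERNEL_VOLUME_CM3) -> float:
    """Maximum kernel-averaged SUV over kernel placements inside the VOI.

    The kernel is a sphere of the requested volume (1 cm^3 by default,
    radius ~6.204 mm).  It is centered on each voxel center inside the VOI;
    its membership may extend beyond the VOI boundary but not beyond the
    grid — voxels falling outside the grid are excluded from the average.
    Returns the maximum of the kernel means.
    """
    r = _kernel_radius_mm(kernel_volume_cm3)
    extent = np.array(vol.shape) * vol.voxel_size_mm
    if np.any(2.0 * r > extent):
        raise QuantificationError(
            f"kernel diameter {2 * r:.1f} mm exceeds grid extent {extent}"
        )
    centers = sphere_indices(vol, voi.center_mm, voi.radius_mm)
    if len(centers) == 0:
        raise QuantificationError(
            f"VOI {voi.label or voi.center_mm} contains no voxel centers"
        )
    offsets = kernel_offsets(vol.voxel_size_mm, kernel_volume_cm3)
    # Pad with NaN so out-of-grid kernel voxels drop out of the mean.
    m = int(np.abs(offsets).max())
    padded = np.full(np.array(vol.shape) + 2 * m, np.nan)
    padded[m:-m or None, m:-m or None, m:-m or None] = vol.values
    coords = centers[:, None, :] + offsets[None, :, :] + m  # (n, k, 3)
    gathered = padded[coords[..., 0], coords[..., 1], coords[..., 2]]
    with np.errstate(invalid="ignore"):
        means = np.nanmean(gathered, axis=1)
    return float(np.max(means))


def normal_tissue_suv(vol: VoxelGrid, center_mm, site: str = "other",
                      radius_mm: float = NORMAL_TISSUE_RADIUS_MM) -> float:
    """SUVmax over a 10-mm-radius sphere placed in imagistically normal tissue.

    The sphere must lie fully inside the voxelized grid extent.
    """
    center = np.asarray(center_mm, dtype=float)
    lower, upper = vol.bounding_box_mm()
    if np.any(center - radius_mm < lower) or np.any(center + radius_mm > upper):
        raise QuantificationError(
            f"reference sphere at {center.tolist()} (r={radius_mm} mm) exits the grid"
        )
    return suv_max(vol, SphereVoi(tuple(center), radius_mm, label="normal", site=site))


def tln_ratio(lesion_suv_max: float, reference_suv_max: float) -> float:
    """Target-lesion to normal-tissue ratio: lesion SUVmax / reference SUVmax.

    An absent reference (e.g. spleen after splenectomy) must be represented
    as a missing value upstream, never as zero.
    """
    if reference_suv_max <= 0:
        raise QuantificationError("reference SUVmax must be positive for TL/N")
    return lesion_suv_max / reference_suv_max


# ---------------------------------------------------------------------------
# Per-lesion measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionMeasurement:
    """SUVmax / SUVpeak (g/mL) and optional TL/N ratio for one lesion."""

    lesion_id: str
    suv_max: float
    suv_peak: float
    site: str = "other"
    tln_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.suv_peak <= self.suv_max * (1 + 1e-12)):
            raise QuantificationError(
                f"lesion {self.lesion_id}: requires 0 <= suv_peak <= suv_max, "
                f"got peak={self.suv_peak}, max={self.suv_max}"
            )
        if self.tln_ratio is not None and self.tln_ratio <= 0:
            raise QuantificationError("tln_ratio must be positive when present")


def measure_lesion(vol: VoxelGrid, voi: SphereVoi, lesion_id: str,
                   reference_suv: Optional[float] = None,
                   kernel_volume_cm3: float = PEAK_KERNEL_VOLUME_CM3) -> LesionMeasurement:
    """Extract SUVmax, SUVpeak and (if a reference is given) TL/N for one VOI."""
    smax = suv_max(vol, voi)
    speak = suv_peak(vol, voi, kernel_volume_cm3)
    ratio = tln_ratio(smax, reference_suv) if reference_suv is not None else None
    return LesionMeasurement(lesion_id=lesion_id, suv_max=smax,
                             suv_peak=min(speak, smax), site=voi.site,
                             tln_ratio=ratio)
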