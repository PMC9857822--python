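#!/usr/bin/env python
"""Simulate the study inputs: a 14-patient longitudinal cohort and one
example patient volume.

The cohort preset encodes 14 patients with a baseline scan and 1-3
follow-ups (35 scans in total), with prescribed summed-SUVmax trajectories:
nine patients end stable (SD), two progress (PD, one of them through new
lesions despite decreasing sums) and three respond partially (PR).  Tables
go to results/; the example NIfTI volume goes to scratch/ (binary).
"""

from pathlib import Path

from spectquant import io as qio
from spectquant.synthetic import (
    GeneratorConfig,
    LesionSpec,
    cohort14_plan,
    generate_cohort,
    generate_patient_volume,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    bundle = generate_cohort(SEED, 14, cohort14_plan())
    bundle.patients.to_csv(RESULTS / "cohort_patients.csv", index=False)
    bundle.scans.to_csv(RESULTS / "cohort_scans.csv", index=False)
    bundle.lesions.to_csv(RESULTS / "cohort_lesions.csv", index=False)
    print(f"cohort (seed {SEED}): {len(bundle.patients)} patients, "
          f"{len(bundle.scans)} scans, {len(bundle.lesions)} lesion rows")
    print(f"  lesion sites: {bundle.lesions['site'].value_counts().to_dict()}")

    # one example 64^3 volume with a liver lesion and a healthy-liver sphere
    config = GeneratorConfig(seed=SEED)
    lesion = LesionSpec((128.0, 128.0, 128.0), radius_mm=12.0, true_suv=12.44,
                        site="liver", true_peak=10.15)
    reference = LesionSpec((180.0, 128.0, 128.0), radius_mm=14.0,
                           true_suv=3.34, site="other")
    vol = generate_patient_volume(config, [lesion], reference_tissues=[reference])
    qio.save_volume(vol.activity, SCRATCH / "example_activity.nii.gz")
    qio.save_vois(vol.lesion_vois + vol.reference_vois, RESULTS / "example_vois.json")
    vol.truth.to_csv(RESULTS / "example_truth.csv", index=False)
    print(f"example volume: grid {config.grid_shape}, voxel "
          f"{config.voxel_size_mm} mm -> scratch/example_activity.nii.gz")


if __name__ == "__main__":
    main()
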