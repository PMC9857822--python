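# spectquant

Quantitative SPECT/CT uptake analysis for somatostatin-receptor imaging
(⁹⁹ᵐTc-EDDA/HYNIC-TOC, Tektrotyd) in neuroendocrine-tumour patients — and,
more generally, for any reconstructed single-photon volume with a paired
activity-administration record.

Quantitative SPECT has lagged behind PET because absolute calibration and
standardized uptake values (SUV) are harder to obtain from gamma cameras.
This package implements the complete measurement chain a nuclear-medicine
physicist needs to do PET-style quantification and response monitoring on
SPECT/CT:

* **SUV conversion.** Voxel activity concentrations *C* (Bq/mL) are
  normalized to lean body mass:

  ```
  SUV_lbm = C [Bq/mL] × LBM [kg] × 1000 / A_actual [Bq]     (g/mL)
  ```

  with LBM from the sex-specific James estimate
  (males `1.10·w − 120·(w/h)²`, females `1.07·w − 148·(w/h)²`; *w* in kg,
  *h* in cm) and the net injected activity decayed to scan time through a
  three-factor cascade over the four protocol timestamps (syringe
  measurement, injection, residual measurement, scan) with
  λ = 0.693 / T½ (T½ = 6.0067 h for ⁹⁹ᵐTc).
* **VOI statistics.** SUVmax (hottest voxel in a spherical VOI), SUVpeak
  (maximum mean over a 1-cm³ spherical kernel placed on every voxel center
  inside the VOI), 10-mm healthy-tissue reference spheres (liver, spleen,
  vertebra) and target-to-normal (TL/N) ratios.
* **Scanner qualification.** The hot-sphere accuracy equation
  `accuracy(%) = (1 − |A_true − a_meas|/A_true) × 100` per phantom sphere
  against the 90% vendor threshold, plus the 0–5% band on the planar/SPECT
  sensitivity conversion-factor deviation.
* **Response classification.** An adapted PERCIST 1.0 over the summed
  SUVmax of up to five target lesions: CR (no uptake above the healthy
  background, no new lesions), PR (decrease > 30%), SD (change < 30%),
  PD (new foci or increase > 30%); exactly ±30% falls to SD; longitudinal
  series take the final category from the last scan.
* **Cohort statistics.** Site-stratified mean ± SD tables, paired t-tests
  of metastasis vs healthy tissue, Pearson correlations (SUVmax–SUVpeak,
  ki67–SUV), marker positivity rates.
* **Synthetic data.** No public image data exist for this protocol, so a
  first-class generator builds phantoms, single-patient volumes with
  analytically known lesion SUVmax/SUVpeak, and longitudinal cohorts with
  prescribed response trajectories — everything downstream is testable by
  parameter recovery.

## Worked example

```python
from datetime import datetime, timedelta
import spectquant as sq

phys = sq.PatientPhysiology(weight_kg=80, height_cm=180, sex="male")
t0 = datetime(2022, 6, 1, 9, 0)
rec = sq.ActivityRecord(
    measured_activity_MBq=740, residual_activity_MBq=25,
    measured_time=t0, administered_time=t0 + timedelta(minutes=10),
    postinjection_time=t0 + timedelta(minutes=12),
    scan_time=t0 + timedelta(hours=4, minutes=10))
print(f"LBM = {sq.compute_lbm(phys):.2f} kg")
print(f"actual activity at scan = {sq.actual_activity(rec):.1f} MBq")

config = sq.GeneratorConfig(seed=7, grid_shape=(32, 32, 32), noise_cv=0.02)
lesion = sq.LesionSpec(center_mm=(64, 64, 64), radius_mm=9.0,
                       true_suv=12.44, site="liver", true_peak=10.15)
bundle = sq.generate_patient_volume(config, [lesion],
                                    physiology=phys, activity_record=rec)
suv = sq.to_suv_volume(bundle.activity, phys, rec)
m = sq.measure_lesion(suv, bundle.lesion_vois[0], "liver_lesion",
                      reference_suv=3.34)
print(f"SUVmax = {m.suv_max:.2f} g/mL, SUVpeak = {m.suv_peak:.2f} g/mL, "
      f"TL/N = {m.tln_ratio:.2f}")
```

prints

```
LBM = 64.30 kg
actual activity at scan = 441.8 MBq
SUVmax = 12.39 g/mL, SUVpeak = 10.27 g/mL, TL/N = 3.71
```

A 740-MBq syringe measured 10 minutes before injection nets 441.8 MBq at a
scan 4 h post-injection after subtracting the back-decayed 25-MBq residual.
The synthetic liver lesion was built with true SUVmax 12.44 g/mL and a true
1-cm³ kernel mean of 10.15 g/mL; with 2% voxel noise the pipeline recovers
12.39 and 10.27, and the TL/N ratio against a healthy-liver reference of
3.34 is 3.71.

## Analysis scripts

The study pipeline is organised as numbered drivers over the library, each
writing its tables under `results/`:

| script | what it does |
|---|---|
| `analysis/01_scanner_calibration.py` | six-sphere phantom accuracy + scanner qualification |
| `analysis/02_simulate_cohort.py` | 14-patient longitudinal cohort + example volume |
| `analysis/03_quantification_recovery.py` | SUVmax/SUVpeak/TL-N parameter recovery through the full pipeline |
| `analysis/04_response_classification.py` | per-scan PERCIST-adapted assessments and the final category distribution |
| `analysis/05_cohort_statistics.py` | uptake, correlation, ki67 and marker tables |

There is also a `spectquant` CLI with `generate`, `quantify`, `calibrate`,
`classify` and `report` subcommands (`spectquant --help`).

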