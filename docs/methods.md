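# Methods

## SUV_lbm quantification

Reconstructed SPECT volumes are consumed as voxel grids of activity
concentration *C* in Bq/mL; acquisition and OSEM reconstruction are out of
scope. Conversion to SUV normalized to lean body mass is

    SUV_lbm = C [Bq/mL] · LBM [kg] · 1000 / A_actual [Bq]   (g/mL),

linear in *C*. LBM uses the sex-specific James estimate (males
`1.10·w − 120·(w/h)²`, females `1.07·w − 148·(w/h)²`, *w* kg, *h* cm); a
non-positive estimate (extreme w/h) is rejected rather than clamped.
Physiology is bounds-checked to adult ranges (20–300 kg, 100–250 cm) with
an explicit override flag.

### Decay cascade

The net injected activity at scan time is

    A_actual = decay_scan · decay1 · (A_measured − decay2 · A_residual)

with `decay1 = exp(λ(t_measured − t_administered))`,
`decay2 = exp(λ(t_postinjection − t_measured))`,
`decay_scan = exp(λ(t_administered − t_scan))` and `λ = 0.693/T½`.
The signed time differences are deliberate: `decay1·decay_scan`
composes to `exp(λ(t_measured − t_scan))`, decaying the net syringe
activity forward to the scan, while `decay2` back-corrects the residual
(measured after injection) to the pre-injection measurement time. With all
four timestamps equal the cascade reduces to `A_measured − A_residual`.
λ uses the conventional rounded constant 0.693 rather than ln 2; the
relative difference is 2·10⁻⁴ and the constant is configurable through
`half_life_h` (default 6.0067 h, ⁹⁹ᵐTc). A residual that back-decays above
the measured activity is an error, as is a scan before administration.

### Geometry and VOI statistics

Grids are isotropic; the origin is the world coordinate of voxel (0,0,0)'s
center (nibabel affine convention). Sphere membership is voxel-center
inclusion with no partial-volume weighting — reproducible and directly
checkable against brute-force enumeration, at the cost of a staircase
boundary.

* `suv_max` is the maximum voxel value among centers inside the VOI.
* `suv_peak` places a spherical kernel of fixed volume (default 1 cm³,
  radius (3V/4π)^⅓ ≈ 6.204 mm) on every voxel center inside the VOI and
  returns the maximum kernel mean. Kernel membership may extend beyond the
  VOI boundary (the "1 cm³ inside a larger VOI" reading) but not beyond
  the grid; out-of-grid voxels are excluded from the mean. Whether the
  kernel may leave the drawn VOI is genuinely underdetermined in the
  source definition; this implementation takes the permissive reading and
  documents it. Consequently `suv_peak ≤ suv_max` is guaranteed over the
  kernel's reachable support, and holds for ordinary lesion VOIs that
  contain their own hot spot; `measure_lesion` additionally caps the
  reported peak at the lesion's SUVmax.
* Healthy-tissue references are 10-mm-radius spheres (liver, spleen for
  lymph-node lesions, normal vertebra for bone lesions) that must lie
  fully inside the grid; the reported reference value is the sphere's
  SUVmax, and TL/N is the per-lesion ratio lesion-SUVmax / reference-SUVmax.
  Cohort TL/N summaries average per-lesion ratios — not the ratio of the
  mean uptakes, which is systematically smaller. An absent reference
  (e.g. splenectomy) yields a measurement without a ratio, never a zero
  denominator.

## Scanner qualification

Per-sphere accuracy is `(1 − |A_true − a_meas|/A_true)·100`; it is
symmetric in the sign of the error, strictly decreasing in its magnitude,
and may go negative for errors larger than the truth (reported as-is). A
scanner qualifies when every sphere exceeds the vendor threshold (default
90%) and the planar/SPECT sensitivity conversion factors agree within 0–5%,
with the SPECT factor as denominator (quantification runs on the SPECT
reconstruction; the source does not fix the denominator). Reconstruction
itself is out of scope, so accuracy is computed on supplied true/measured
concentration pairs — from the synthetic phantom or from user files.

## Response classification

Targets are the up-to-five hottest lesions by SUVmax, ties broken by
lexicographic lesion id (deterministic and enumerable); an optional
per-organ cap exists but is off by default, since the adapted criteria do
not state one. Categories from the summed target SUVmax:

* **CR** — every baseline target's follow-up uptake at or below the
  supplied healthy-tissue background (the criteria give no numeric
  threshold, so the caller provides the reference, e.g. healthy-liver
  SUVmax) and no new lesions;
* **PD** — new lesions (overriding any decrease), or an increase > 30%;
* **PR** — a decrease > 30%;
* **SD** — otherwise. A change of exactly ±30% is SD: the PR/PD rules are
  strict inequalities and the SD rule is itself stated as "< 30%".

Lesion matching across scans is by stable lesion id; a baseline target
missing from the follow-up table counts as fully resolved. Re-appearing
uptake after a zero-sum baseline is PD with an explanatory note.
Longitudinal series are assessed per follow-up either against the original
baseline (default, PERCIST-style) or against the preceding scan; the final
patient category is the last assessment's. Which comparison the clinical
narrative used for multi-follow-up patients is ambiguous, so both modes are
implemented and neither is asserted as canonical.

## Synthetic data

The generator emulates the study conditions end to end:

* **Volumes.** 64³ grids at 4-mm isotropic voxels by default (a desk-scale
  stand-in for 128×128 acquisitions; the 1-cm³ kernel spans ≥ 3 voxels per
  axis). Lesions are uniform-uptake spheres so true SUVmax is analytically
  known; reference tissues are dedicated spheres with healthy-tissue
  parameters. Voxel noise is multiplicative Gaussian (mean 1, SD
  `noise_cv`, clipped at 0), default cv 0.02. Volumes are emitted in Bq/mL
  with a conversion factor derived from the bundled physiology/activity
  record, so noise-free volumes convert back to the true SUV exactly.
* **Two-compartment lesions.** When a target 1-cm³ kernel mean is
  requested, the lesion is a single hot core voxel at `true_suv` inside a
  cooler rim whose uptake solves the discrete kernel equation
  `rim = (n_k·peak − max)/(n_k − 1)` (n_k = 19 kernel voxels at 4-mm
  voxels), so the noise-free pipeline recovers the requested SUVpeak
  exactly; infeasible requests (rim below background) are rejected.
* **Calibrated distributions.** Site-stratified SUVmax, SUVpeak, healthy
  uptake and TL/N distributions default to reported
  ⁹⁹ᵐTc-EDDA/HYNIC-TOC NET cohort statistics (liver metastases
  12.44 ± 7.76 g/mL over healthy liver 3.34 ± 0.93, lymph nodes
  11.98 ± 10.45 over spleen 8.01 ± 5.31, bone 5.90 ± 3.68 over vertebra
  0.66 ± 0.37; SUVpeak 10.15/8.81/5.55; SUVmax–SUVpeak correlations
  0.982/0.980/0.920). Distributions are normals truncated at zero with the
  location re-calibrated numerically (Brent root-find on the truncated
  mean) so the post-truncation mean equals the table mean; the SD is the
  table SD pre-truncation. Joint (SUVmax, SUVpeak) draws come from a
  correlated bivariate normal rejection-constrained to feasibility
  (0 < peak ≤ max, rim ≥ background), with the location vector
  re-calibrated by fixed-point iteration against a large fixed-seed
  internal sample so the accepted draws average to the table means; the
  post-constraint correlation (~0.98) is the generator's effective value.
* **Recovery lesion sizes.** Uniform lesions used for SUVmax/TL-N recovery
  are minimal spheres (radius one voxel, 7 voxel centers): the true SUVmax
  of a uniform lesion is radius-independent, while the plateau's voxel
  count sets how strongly multiplicative noise inflates the measured
  maximum (a max-order statistic; ≈ +1.4% at cv 0.02 with 7 voxels, vs
  ≈ +3.7% with 19). Two-compartment lesions use 9-mm radius so the kernel
  fits inside the rim. Recovery runs use 32³ grids — one centered lesion
  plus margins — with 500 lesions per condition; everything completes in
  seconds on one CPU.
* **Cohorts.** Longitudinal trajectories are specified per patient as
  baseline-relative summed-SUVmax multipliers plus new-lesion counts;
  follow-up lesion values are scaled uniformly so the requested summed
  change is exact. A plan demanding CR while uptake or new lesions remain
  is rejected. The 14-patient preset encodes nine finally-stable patients,
  two progressors (one via new lesions despite decreasing sums) and three
  partial responders, including the four multi-follow-up trajectories
  (PD,PD,PD; SD,SD,PR; PD,PR,SD; PD,SD). Patient physiology is sampled
  from plausible adult ranges, ki67 from a truncated normal (7 ± 6.25%,
  clipped to [0,100]) independently of every SUV draw — so ki67–SUV
  correlations are null by construction — and marker positivity from
  Bernoulli rates (CGA 85.7%, SYN 92.9%, NSE 21.4%, CD56 14.3%). Per-scan
  lesion counts are not reported anywhere, so presets default to 4 (the
  generator accepts 2–8).
* **Phantom.** Six hot spheres (10–37 mm diameters on a 114-mm ring);
  measured concentration = true × (1 + δ), δ ~ Uniform(−d, d) per sphere
  with d defaulting to 0.05 — which forces every accuracy ≥ 100(1−d)% by
  construction.

What the generator does **not** emulate: collimator blur and
partial-volume effects, attenuation/scatter residuals, correlated
reconstruction noise, lesion heterogeneity beyond two compartments, and
anatomical context. Passing recovery tests therefore demonstrates the
correctness of the measurement chain under the stated lesion model, not
clinical accuracy on real reconstructions.

## Statistics

Summaries are mean ± sample SD (n−1); lesions, not patients, are the unit
for uptake tables (lesions are pooled across scans). The paired t-test and
Pearson correlation come from scipy (`ttest_rel`, `pearsonr`), wrapped
with explicit degenerate-input handling: fewer than three pairs, unequal
lengths and zero variance are errors — except all-zero paired differences,
which return t = 0, p = 1 (identical samples carry no evidence of a
difference rather than being ill-posed). p-values display to three
decimals, with values below 0.0005 rendered "0.000". Significance is
p < 0.05; no multiple-testing correction is applied. Tests back each
statistic with a closed-form small-n oracle; no bit-compatibility with any
commercial package is claimed.

In the cohort-statistics driver the TL/N column pairs each lesion with an
independent healthy-reference draw; for sites whose reference mean is
close to zero (vertebra, 0.66 ± 0.37) the resulting ratio distribution is
heavy-tailed and its mean exceeds typical reported site ratios. The
calibrated TL/N recovery path samples the per-lesion ratio distribution
directly and does not have this artifact.

## Numerical conventions and edge cases

* Ties in target selection: lexicographic lesion id; documented and tested
  by enumeration.
* Kernel means near the grid edge: out-of-grid voxels are dropped from the
  average (NaN-padding), not zero-filled.
* `suv_peak` errors out if the kernel diameter exceeds any grid extent;
  VOIs must contain at least one voxel center.
* Activities are stored in MBq and converted to Bq inside the SUV formula;
  timestamps are datetimes (plain numbers are accepted as hours).
* All randomness flows through `numpy.random.Generator` seeded from
  user-supplied integers; fixed seeds give bitwise-reproducible volumes,
  phantoms and cohorts. The one internal fixed seed (bivariate location
  calibration) is part of the deterministic definition of the calibrated
  distribution, not a user-facing random stream.

## Known limitations

* No segmentation: VOIs are supplied (spheres or external masks), matching
  a workflow where delineation happens upstream.
* Voxel-center membership underestimates small-sphere volumes; VOI
  statistics are exact for the stated discrete geometry but not for
  continuous spheres.
* SUVmax of uniform noisy plateaus is biased upward by the max-order
  statistic; SUVpeak is the robust alternative and the reason it is
  reported alongside.
* Only lean-body-mass SUV is implemented (no body-weight/BSA variants, no
  SUVmean).
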